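gene	snp_name	ratio	aa_annotation	sift_score
GhSus1At	GhSus1At-A918G	0.612	No
GhSus1At	GhSus1At-G1783C	0.342	No
GhSus1At	GhSus1At-A2940T	0.338	T678=
GhSus1Dt	GhSus1Dt-T650C	0.089	No
GhSus1Dt	GhSus1Dt-G751A	0.089	V153I	0
GhSus1Dt	GhSus1Dt-G2709C	0.107	E601Q	0.12
GhSus3At	GhSus3At-T881A	0.072	No
GhSus3At	GhSus3At-T1320C	0.072	No
GhSus3At	GhSus3At-G1327A	0.072	No
GhSus3At	GhSus3At-T2294C	0.018	L504S	0
GhSus3At	GhSus3At-A2472C	0.018	No
GhSus4Dt	GhSus4Dt-A1886T	0.025	No
GhSus4Dt	GhSus4Dt-T2167C	0.025	E388=
GhSus5Dt	GhSus5Dt-G491T	0.029	L108F	1
GhSus5Dt	GhSus5Dt-C2648G	0.025	P660A	1
GhSus6At	GhSus6At-G3143T	0.159	No
GhSus6At	GhSus6At-C4655T	0.209	No
GhSus6At	GhSus6At-G4697A	0.209	W755=
GhSus6At	GhSus6At-G5005A	0.209	No
GhSus7Dt	GhSus7Dt-T192C	0.755	T64=
GhSus7Dt	GhSus7Dt-C404T	0.755	D109=
GhSus7Dt	GhSus7Dt-T407C	0.755	E110=
GhSus8Dt	GhSus8Dt-C577T	0.09	No
GhSus8Dt	GhSus8Dt-T1334C	0.069	G298=
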