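gene	tag	members
GhSus1Dt	GhSus1Dt-G751A	GhSus1Dt-T650C,GhSus1Dt-G751A
GhSus3At	GhSus3At-T881A	GhSus3At-T881A,GhSus3At-T1320C,GhSus3At-G1327A
GhSus3At	GhSus3At-T2294C	GhSus3At-T2294C,GhSus3At-A2472C
GhSus4Dt	GhSus4Dt-A1886T	GhSus4Dt-A1886T,GhSus4Dt-T2167C
GhSus6At	GhSus6At-C4655T	GhSus6At-C4655T,GhSus6At-G4697A,GhSus6At-G5005A
GhSus7Dt	GhSus7Dt-T192C	GhSus7Dt-T192C,GhSus7Dt-C404T,GhSus7Dt-T407C
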