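# Methods

## Scope and data model

eamkit covers the statistics downstream of an EcoTILLING candidate-gene
screen on an inbred association panel: a catalog of natural SNPs per gene
amplicon, genotype calls for each accession at those SNPs, multi-environment
trait records, and a population-structure Q matrix estimated elsewhere
(e.g. STRUCTURE at k = 2). Wet-lab steps (CEL I digestion, PAGE, primer
design), SIFT score computation, and structure inference itself are inputs,
not computations.

Coordinates are 1-based within each gene's reference sequence; SNP names
follow `<gene>-<ref><position><alt>` with the subgenome encoded in the gene
identifier (At/Dt). Genotype calls are coded 0/1/2/NA for ref-hom, het,
alt-hom, missing; inbred panels carry no hets, and every dominance-bearing
model block is then empty and pruned (the pruning is logged so an analysis
is auditable).

## Haplotype statistics

Inbred accessions are effectively phased, so a gene's haplotype is the
string of its allele calls. Haplotype diversity is Nei's unbiased gene
diversity over haplotype classes,

    Hd = n/(n−1) · (1 − Σᵢ pᵢ²),

the estimator DnaSP reports. Two loci are in complete LD when their call
columns agree exactly, or are exactly complementary (allele labels swapped;
r² = 1 either way), over jointly observed accessions; grouping is the
transitive closure of this pairwise relation, restricted to within-gene
pairs. A group is only emitted when every pair was observed in ≥ 90% of
accessions, guarding against spurious grouping on sparse data, and
monomorphic loci are excluded (r² undefined). The tag representing a group
is its smallest-position member by default; groups read from a file may
carry any member as tag, since published analyses sometimes prefer the
nonsynonymous member as the group's name.

## The association model

For one trait, with observations stacked over accessions × environments and
sorted by (accession, environment) so results are invariant to input order:

    y = X_p β_P + X_E β_E + Σ_j Z_j γ_j + ε,  ε ~ N(0, σ²_e I)

Fixed effects: intercept, k−1 structure covariates, E−1 environment
indicators. Random-effect blocks, each with prior γ_j ~ N(0, σ²_j I):

- per tag SNP: additive code x ∈ {−1, 0, +1} (and dominance z = 1[het]
  when hets exist);
- per tag SNP: additive-by-environment contrasts, x centered times E−1
  centered environment indicators;
- per pair: additive-by-additive products of centered codes (plus ad/da/dd
  with hets) — 105 pairs for 15 tags.

### Why centered interaction codes

Raw products x₁x₂ are nearly collinear with their parent mains when variant
frequencies are extreme — corr(x₁x₂, x₁) → E[x₂], which is −0.95 at a
carrier frequency of 0.025, and exactly −1-linear when a rare pair has no
co-carriers (then x₁x₂ = −1 − x₁ − x₂ identically). Likewise the E raw
x·indicator columns sum exactly to the main column. Either degeneracy lets a
main effect leak into interaction blocks and back, which destroys per-block
evidence and effect recovery. Products of centered codes (Cockerham-style
orthogonal coding) remove both degeneracies while leaving the interaction
coefficient itself unchanged whenever mains are in the model, so effect
sizes remain in trait units and directly comparable with a generating model
that plants the same convention.

### Empirical-Bayes estimation

All blocks are estimated jointly (a single multi-QTN model, not
one-at-a-time tests) by EM on the marginal likelihood:

- E-step: posterior mean and covariance of all active γ given current
  variances. With Z the concatenated active columns (m of them) and D the
  expanded prior-variance diagonal, the posterior mean is
  γ̂ = (ZᵀZ + σ²_e D⁻¹)⁻¹ Zᵀ(y − Xβ) and the posterior covariance
  σ²_e (ZᵀZ + σ²_e D⁻¹)⁻¹ — only m×m systems are ever solved (Woodbury),
  with ZᵀZ, ZᵀX, Zᵀy cached once.
- Fixed effects by GLS at the current variances each iteration.
- M-step: σ²_j = (‖γ̂_j‖² + tr Σ̂_j + ω)/(q_j + τ + 2) with the diffuse
  hyperprior (τ, ω) = (−2, 0), i.e. the plain EM update; residual
  σ²_e = (E‖y − Xβ − Zγ‖²)/n.

Initialization is deterministic — σ²_j = σ²_e = Var(y)/(B+1) for B blocks —
and the fit contains no randomness. Convergence: relative change of all
active variance components < 1e−8, cap 1000 iterations (the fit reports
`converged` and the final change either way). The marginal log-likelihood is
recorded every iteration; with freezing disabled it is provably
non-decreasing and the test suite checks this.

EM decay of a null block's variance toward zero is sublinear (harmonic), so
waiting for a numerical floor is hopeless. A block whose Wald statistic
W_j = γ̂_jᵀ Σ̂_j⁻¹ γ̂_j stays below 1 for two consecutive iterations while
its variance shrinks is frozen at zero and leaves the active set. W = 1 is
two orders of magnitude below the declaration threshold (LOD 3 ⇔ W = 13.8),
so freezing cannot remove a declarable effect; it is what makes a
250-column scan run in under a second. Setting `freeze_wald = 0` in
`EamControl` recovers pure EM.

### Evidence, significance, variance explained

Per block: LOD = W/(2 ln 10) with W the posterior Wald statistic, df = block
size (for multi-df blocks the per-df alternative can be derived from the
same W), p = Pr(χ²_df ≥ 2 ln(10)·LOD). LOD ≥ 3 declares a QTN — at df = 1
this reproduces the p ≈ 2×10⁻⁴ calibration — and no multiplicity adjustment
is applied beyond the fixed threshold. PVE is r² = 100·Var(Z_j γ̂_j)/Var(y)
over the stacked observations. The joint fit means shared signal between
correlated blocks is resolved by the shrinkage priors rather than double-
counted; consequently the per-block "EB norm ≤ OLS norm" bound, a theorem
for a single random block (ridge), need not hold per block in the joint fit
on correlated designs, and is checked in the single-block regime.

### Allele effects

For each declared QTN the stacked phenotype is residualized on the fitted
fixed part (structure + environment) and the carrier class mean is compared
with the non-carrier mean — for epistatic QTNs each joint two-locus
combination against all other combinations ("carrier mean − grand mean" is
available behind a flag). The favorable allele is the class whose effect
moves the trait in its registered desirable direction (fiber micronaire
improves downward, the other standard cotton traits upward); exact ties are
flagged indeterminate, never silently resolved. Epistatic gene-pair signals
can additionally be confirmed at the haplotype level with a two-way ANOVA
(Type-III sums of squares, sum-to-zero contrasts) on the interaction term.

## Synthetic panel generator

The generator is the package's test bed and emulates the reference study
conditions as defaults:

- 277 accessions, admixture proportions from a symmetric Dirichlet(0.2) at
  k = 2 (near-pure memberships with an admixed fringe);
- 15 tag loci with variant frequencies spanning the catalogued range
  0.018–0.755, each differentiated ±0.08 between subpopulations so structure
  confounding is realistically present, plus two extra loci copying the
  0.755 tag to plant a 3-locus complete-LD group;
- a 3 × 3 year-by-location environment grid with distinct fixed means
  (variance ≈ 0.094 trait-units²), residual SD 1, structure effect 0.5;
- planted effects: 4 additive QTNs at 3.0/2.5/2.0/2.0% target PVE and 2
  additive-by-additive pairs at 2.0/1.5% — inside the 0.4–3.6% per-QTN range
  reported for such panels. Effect sizes are derived in closed form from the
  target PVEs (for inbred ±1 coding, Var(x) = 4p(1−p) and
  Var(x₁ᶜx₂ᶜ) = 16p₁q₁p₂q₂), with the total variance solved
  self-consistently from the background (environment + structure +
  residual) variance;
- no G×E planted by default (a `gxe_effects` list can add it); epistasis is
  planted with the same centered-product convention the model fits.

Every stage draws from its own seeded substream, so outputs are bit-identical
given (scenario, seed) and regenerating one output does not depend on
another stage's draw count. What the generator does *not* emulate: linkage
short of complete LD, non-normal residuals, unbalanced or missing trial
data, genotyping error. Passing tests therefore demonstrate correctness of
the machinery and calibration under the assumed generative model, not
robustness to real-data pathologies.

## Numerical and reporting choices

- Published-table comparisons round to 3 decimals, half away from zero; full
  precision is kept internally.
- Missing genotype calls are mean-imputed per locus (count logged); missing
  phenotype records simply drop their rows.
- Constant design columns are pruned and logged; a block with no columns
  left is recorded as dropped and raises on query.
- Singular posterior covariances fall back to a pseudo-inverse with a
  warning; a singular fixed-effect design is an error.
- A zero-variance response returns the degenerate fit (all γ̂ = 0, all
  σ²_j = 0) rather than iterating.

## Test problem sizes

The simulation-based checks run the full reference conditions — 277
accessions × 9 environments, 15 tags, 105 pairs — with 20 replicates for the
null false-positive rate and power checks and 50 for effect-recovery bias
and PVE calibration; one scan takes well under a second, so the whole suite
stays in the low minutes.

## Known limitations

- Complete LD is assessed on the full panel; the behaviour under heavy
  missingness is governed by the 90% pair-coverage guard, not modeled LD.
- Multi-haplotype amplicon diversity requires per-accession genotypes; only
  two-haplotype amplicons are reproducible from a catalog's ratio column
  alone.
- LOD for multi-df blocks uses the block's df; published single-number LOD
  thresholds are calibrated at df = 1, so multi-df declarations are
  conservative in p but not recalibrated.
- The empirical-Bayes variant is one concrete choice (diffuse hyperprior,
  GLS fixed effects, joint fit); other variants of the same family differ in
  detail and `EamControl` exposes (τ, ω), tolerances and the freeze rule.
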