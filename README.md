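# eamkit

Candidate-gene association mapping for inbred crop panels, built around the
downstream statistics of an EcoTILLING study: a natural-variation SNP catalog
for a gene family screened across a germplasm collection, complete-linkage-
disequilibrium tag-SNP collapsing, haplotype diversity, an empirical-Bayes
epistatic association model, and favorable-allele effect estimation. The
reference data model is a panel of 277 inbred upland-cotton accessions
screened for 24 SNPs in eight sucrose-synthase (*GhSus*) genes and phenotyped
for fiber and seed traits in nine environments (3 years × 3 locations).

## Who this is for

Breeders and quantitative geneticists working with candidate-gene panels on
inbred varieties: a handful of amplicon-resequenced loci, a
population-structure Q matrix from STRUCTURE, multi-environment trial
phenotypes, and the question of which alleles (and allele pairs) move a trait
and in which direction.

## The model

For one trait, stacked over accessions × environments:

```
y = X_p β_P + X_E β_E + Z_G γ_G + Z_GE γ_GE + Z_GG γ_GG + ε
```

- `X_p` — structure covariates (Q matrix, one column dropped), fixed;
- `X_E` — intercept + environment indicators, fixed;
- `Z_G` — per tag-SNP additive (−1/0/+1) and, when heterozygotes exist,
  dominance codes;
- `Z_GE` — QTN-by-environment interaction contrasts;
- `Z_GG` — all pairwise epistasis blocks (aa, and ad/da/dd with hets),
  built from centered codes so interactions stay orthogonal to mains;
- each random block `γ_j ~ N(0, σ²_j I)` with its variance estimated from the
  data by an EM algorithm on the marginal likelihood (empirical Bayes, diffuse
  scaled-inverse-χ² hyperprior (τ, ω) = (−2, 0)), which shrinks null blocks
  to zero while leaving strong effects nearly unshrunk.

Evidence per block is a Wald statistic on the posterior reported as
`LOD = W / (2 ln 10)`, with `p = Pr(χ²_df ≥ 2 ln(10)·LOD)`; the default
declaration threshold LOD ≥ 3 corresponds to p ≈ 2×10⁻⁴ at df = 1. Each
declared QTN is reported with its phenotypic variance explained
`r² = 100 · Var(Z_j γ̂_j) / Var(y)` and, after residualizing on the fixed
effects, the allele (or two-locus allele combination) whose carrier-class
mean moves the trait in its agronomically desirable direction.

Haplotype diversity is the Nei/DnaSP unbiased estimator
`Hd = n/(n−1) · (1 − Σ pᵢ²)`, and two loci are collapsed into one tag when
their genotype columns are identical or exactly complementary across the
panel (pairwise r² = 1, transitively closed within each gene).

## Worked example

Everything below runs offline from the seeded synthetic generator, which
emulates the reference study conditions (277 admixed inbred accessions, 15
tag loci spanning variant frequencies 0.018–0.755, one planted 3-locus
complete-LD group, 3×3 environment grid, 4 main + 2 epistatic planted QTNs):

```bash
eamkit run-all --simulate --seed 13 --out-dir demo
```

`demo/qtn_results.tsv` then contains exactly the six planted QTNs and
nothing else:

```
term       qtn                              effect_type  lod      p          r2_percent  effect    favorable_allele
main       SimG03At-A102G                   a            24.7951  1.187e-26  3.408       0.21981   SimG03At-102G
main       SimG12At-A111G                   a            17.2264  5.254e-19  2.214       0.205107  SimG12At-111G
main       SimG01At-A100G                   a            16.9512  9.98e-19   2.364       0.176775  SimG01At-100G
main       SimG13At-A112G                   a            15.2229  5.626e-17  1.988       0.182816  SimG13At-112G
epistatic  SimG02At-A101G x SimG11At-A110G  aa           11.3864  4.444e-13  1.616       0.222827  SimG02At-101G x SimG11At-110G
epistatic  SimG05At-A104G x SimG14At-A113G  aa           10.3798  4.719e-12  1.622       0.342912  SimG05At-104G x SimG14At-113G
```

Reading the first row: the additive effect of locus `SimG03At-A102G` reaches
LOD 24.8 (p ≈ 10⁻²⁶), explains 3.4% of phenotypic variance, and substituting
the G allele raises the trait by ≈ 0.22 units — the generating truth for that
locus was an additive effect of 0.19 at a configured 2.5% PVE
(`demo/truth.yaml`). The run directory also holds the simulated genotypes
(CSV and VCF), phenotypes, Q matrix, detected complete-LD groups
(`ld_groups.tsv`: the planted 3-locus group, 17 SNPs → 15 tags), per-gene
haplotype diversity, and a run log with every pruned design block.

The bundled GhSus catalog is queried the same way:

```bash
eamkit catalog-stats
```

prints 24 SNPs, 12 coding (7 synonymous + 5 nonsynonymous), 2
SIFT-damaging (< 0.05), and variant ratios 0.018–0.755 with mean 0.214.

The same operations are available as a library:

```python
import eamkit as ek

catalog = ek.load_bundled_catalog()
tags = ek.collapse_ld(catalog.snp_names(), ek.load_bundled_ld_groups())  # 24 -> 15

scenario = ek.default_scenario(seed=13)
q, panel, pheno, truth = ek.simulate_all(scenario)
result = ek.scan(panel, pheno, scenario.trait_name, q, scenario.tag_loci())
for r in result.qtns:
    print(r.name, round(r.lod, 1), round(r.pve, 2))
```

## Layout

| module | contents |
| --- | --- |
| `eamkit.snp_catalog` | SNP naming convention, region/synonymy classes, SIFT filter, catalog summaries |
| `eamkit.haplotypes` | complete-LD detection, tag collapsing, haplotype tables, Hd |
| `eamkit.eam_model` | design construction, empirical-Bayes EM, LOD/p/PVE, the scan |
| `eamkit.allele_effects` | allele effects, favorable-allele calls, haplotype-interaction ANOVA |
| `eamkit.synthetic_data` | seeded panel generator and canned scenarios |
| `eamkit.io_cli` / `eamkit.cli` | file formats, pipeline orchestration, CLI |

See `docs/methods.md` for the statistical details and design choices.
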