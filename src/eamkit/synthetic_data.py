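"""Seeded generator of an admixed inbred association panel.

The generator emulates the kind of data an EcoTILLING candidate-gene study
produces: a few hundred inbred accessions drawn from an admixed two-
subpopulation panel, a dozen-odd biallelic loci whose variant frequencies
span the catalogued range (0.018-0.755) with subpopulation differentiation,
planted complete-LD groups, and multi-environment phenotypes generated from
the same structure + environment + additive + epistatic (+ optional GxE)
model the association scan assumes, with i.i.d. normal noise.

Everything is a deterministic function of (scenario, seed): each stage draws
from its own seeded substream, so regenerating any one output never depends
on how many draws another stage consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from eamkit.eam_model import GenotypePanel, PhenotypeTable, QMatrix
from eamkit.snp_catalog import parse_snp_name

#: variant frequencies of the 15 effective tag loci in the default panel,
#: spanning the observed catalog range 0.018-0.755
_DEFAULT_TAG_FREQS = (
    0.612, 0.342, 0.338, 0.089, 0.107, 0.072, 0.018, 0.025,
    0.029, 0.025, 0.159, 0.209, 0.755, 0.09, 0.069,
)

_YEARS = ("Y1", "Y2", "Y3")
_LOCATIONS = ("LocA", "LocB", "LocC")

#: distinct per-environment means for the default 3x3 year-by-location grid
_DEFAULT_ENV_EFFECTS = (0.0, 0.25, -0.25, 0.5, -0.5, 0.3, -0.3, 0.15, -0.15)


@dataclass(frozen=True)
class LocusSpec:
    """One biallelic locus: per-subpopulation variant frequencies.

    A locus with `ld_copy_of` set replicates its seed locus's allele pattern
    exactly, planting a complete-LD group.
    """

    name: str
    freqs: tuple[float, ...]
    ld_copy_of: Optional[str] = None

    def __post_init__(self) -> None:
        parse_snp_name(self.name)  # must follow the naming convention
        if any(not 0.0 <= f <= 1.0 for f in self.freqs):
            raise ValueError(f"frequencies of {self.name} outside [0, 1]: {self.freqs}")


@dataclass(frozen=True)
class PlantedEffect:
    """A true QTN: one locus (additive, 'a') or a pair (additive-by-additive, 'aa')."""

    qtns: tuple[str, ...]
    effect_type: str  # 'a' | 'aa'
    size: float       # trait units

    def __post_init__(self) -> None:
        if self.effect_type == "a" and len(self.qtns) != 1:
            raise ValueError("additive effect takes exactly one locus")
        if self.effect_type == "aa" and len(self.qtns) != 2:
            raise ValueError("aa epistasis takes exactly two loci")
        if self.effect_type not in ("a", "aa"):
            raise ValueError(f"unsupported planted effect type {self.effect_type!r}")


@dataclass
class SimScenario:
    """Study conditions for one synthetic panel; the seed is mandatory."""

    seed: int
    n_accessions: int = 277
    k_subpops: int = 2
    admixture_concentration: float = 0.2
    loci: list[LocusSpec] = field(default_factory=list)
    environments: list[str] = field(
        default_factory=lambda: [f"{y}:{l}" for y in _YEARS for l in _LOCATIONS]
    )
    env_effects: list[float] = field(default_factory=lambda: list(_DEFAULT_ENV_EFFECTS))
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    gxe_effects: list[tuple[str, str, float]] = field(default_factory=list)
    structure_effect: float = 0.5
    residual_sd: float = 1.0
    intercept: float = 0.0
    trait_name: str = "SYN"
    inbred: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.residual_sd <= 0:
            raise ValueError("residual SD must be > 0")
        if len(self.env_effects) != len(self.environments):
            raise ValueError("need one environment effect per environment")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        for l in self.loci:
            if len(l.freqs) != self.k_subpops:
                raise ValueError(f"locus {l.name} needs {self.k_subpops} frequencies")
            if l.ld_copy_of is not None and l.ld_copy_of not in names:
                raise ValueError(f"LD group of {l.name} references unknown locus {l.ld_copy_of!r}")
        for pe in self.planted_effects:
            for qtn in pe.qtns:
                if qtn not in names:
                    raise ValueError(f"planted QTN {qtn!r} is not a declared locus")

    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def tag_loci(self) -> list[str]:
        """Loci that survive complete-LD collapsing (LD copies removed)."""
        return [l.name for l in self.loci if l.ld_copy_of is None]

    @property
    def env_variance(self) -> float:
        return float(np.var(np.asarray(self.env_effects)))


@dataclass
class SimTruth:
    """Generating values realized for one simulated panel."""

    q: QMatrix
    subpops: np.ndarray
    panel: GenotypePanel
    effects: list[PlantedEffect]
    true_pve: dict[str, float]       # per planted effect, percent of realized Var(y)
    env_effects: dict[str, float]
    residual_sd: float


def _rng(scenario: SimScenario, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, scenario.seed])


def simulate_population(scenario: SimScenario) -> tuple[QMatrix, np.ndarray]:
    """Draw admixture proportions from a symmetric Dirichlet.

    Small concentration gives near-pure memberships with a thin admixed
    fringe, like a STRUCTURE Q matrix at k=2 for a germplasm collection.
    Subpopulation assignment is the argmax membership.
    """
    if scenario.k_subpops < 1:
        raise ValueError("k_subpops must be >= 1")
    rng = _rng(scenario, 1)
    if scenario.k_subpops == 1:
        values = np.ones((scenario.n_accessions, 1))
    else:
        alpha = np.full(scenario.k_subpops, scenario.admixture_concentration)
        values = rng.dirichlet(alpha, size=scenario.n_accessions)
    accessions = [f"acc{i + 1:03d}" for i in range(scenario.n_accessions)]
    q = QMatrix(accessions=accessions, values=values)
    return q, values.argmax(axis=1)


def simulate_genotypes(scenario: SimScenario, q: QMatrix) -> GenotypePanel:
    """Draw inbred (homozygous) calls; LD copies replicate their seed column."""
    rng = _rng(scenario, 2)
    n = scenario.n_accessions
    names = scenario.locus_names()
    calls = np.zeros((n, len(names)))
    u = rng.random((n, len(names)))
    u2 = rng.random((n, len(names)))  # second gamete, used in outcrossing mode
    col = {nm: j for j, nm in enumerate(names)}
    for j, spec in enumerate(scenario.loci):
        if spec.ld_copy_of is not None:
            continue
        p = q.values @ np.asarray(spec.freqs)  # per-accession variant probability
        if scenario.inbred:
            calls[:, j] = np.where(u[:, j] < p, 2.0, 0.0)
        else:
            calls[:, j] = (u[:, j] < p).astype(float) + (u2[:, j] < p).astype(float)
    for j, spec in enumerate(scenario.loci):
        if spec.ld_copy_of is not None:
            calls[:, j] = calls[:, col[spec.ld_copy_of]]
    return GenotypePanel(accessions=list(q.accessions), loci=names, calls=calls)


def _effect_column(scenario: SimScenario, panel: GenotypePanel, q: QMatrix,
                   effect: PlantedEffect) -> np.ndarray:
    """Design column of one planted effect.

    Additive: raw -1/+1 code. Epistasis: product of CENTERED additive codes,
    (x1 - m1)(x2 - m2) with m the population expectation 2 p-bar - 1 — the
    same orthogonal convention the association model fits, so a planted aa
    effect induces no marginal main effects at its parent loci.
    """
    x = panel.calls - 1.0
    if effect.effect_type == "a":
        return x[:, panel.locus_index(effect.qtns[0])]
    spec_of = {l.name: l for l in scenario.loci}
    cols = []
    for s in effect.qtns:
        pbar = float(np.mean(q.values @ np.asarray(spec_of[s].freqs)))
        cols.append(x[:, panel.locus_index(s)] - (2.0 * pbar - 1.0))
    return cols[0] * cols[1]


def simulate_phenotypes(
    scenario: SimScenario, panel: GenotypePanel, q: QMatrix
) -> tuple[PhenotypeTable, SimTruth]:
    """Generate stacked accession-by-environment phenotypes.

    y_ie = intercept + b_P q_i + env_e + sum_k size_k col_k(i) (+ GxE) + e_ie,
    e ~ N(0, residual_sd^2) i.i.d. The returned truth records each planted
    effect's realized PVE: 100 * Var(size * column, stacked) / Var(y).
    """
    if panel.loci != scenario.locus_names() or panel.n_accessions != scenario.n_accessions:
        raise ValueError("panel does not match the scenario")
    rng = _rng(scenario, 3)
    n, envs = scenario.n_accessions, scenario.environments
    n_env = len(envs)

    structure = scenario.structure_effect * q.values[:, 0] if q.k > 1 else np.zeros(n)
    genetic = np.zeros(n)
    per_effect_acc: dict[str, np.ndarray] = {}
    for pe in scenario.planted_effects:
        contrib = pe.size * _effect_column(scenario, panel, q, pe)
        per_effect_acc[" x ".join(pe.qtns) + f":{pe.effect_type}"] = contrib
        genetic = genetic + contrib

    env_arr = np.asarray(scenario.env_effects)
    base = scenario.intercept + structure + genetic          # per accession
    y = base[:, None] + env_arr[None, :]                     # accession x env
    for qtn, env, size in scenario.gxe_effects:
        x = panel.calls[:, panel.locus_index(qtn)] - 1.0
        y[:, envs.index(env)] += size * x
    y = y + rng.normal(0.0, scenario.residual_sd, size=(n, n_env))

    obs = pd.DataFrame({
        "accession": np.repeat(panel.accessions, n_env),
        "environment": list(envs) * n,
        "trait": scenario.trait_name,
        "value": y.ravel(),
    })
    table = PhenotypeTable(observations=obs, environments=list(envs))

    var_y = float(np.var(y))
    true_pve = {
        name: 100.0 * float(np.var(np.repeat(contrib, n_env))) / var_y
        for name, contrib in per_effect_acc.items()
    }
    truth = SimTruth(
        q=q,
        subpops=q.values.argmax(axis=1),
        panel=panel,
        effects=list(scenario.planted_effects),
        true_pve=true_pve,
        env_effects=dict(zip(envs, scenario.env_effects)),
        residual_sd=scenario.residual_sd,
    )
    return table, truth


def simulate_all(scenario: SimScenario) -> tuple[QMatrix, GenotypePanel, PhenotypeTable, SimTruth]:
    q, _ = simulate_population(scenario)
    panel = simulate_genotypes(scenario, q)
    pheno, truth = simulate_phenotypes(scenario, panel, q)
    return q, panel, pheno, truth


# --------------------------------------------------------------------------
# effect-size calibration and canned scenarios

def additive_effect_for_pve(
    target_pve_percent: float, mean_freq: float, total_variance: float
) -> float:
    """Additive effect size giving the target PVE at a given variant frequency.

    For inbred -1/+1 coding Var(x) = 4 p (1 - p), so
    a = sqrt(pve/100 * total_variance / (4 p (1 - p))).
    """
    vx = 4.0 * mean_freq * (1.0 - mean_freq)
    if vx <= 0:
        raise ValueError("monomorphic locus cannot carry a target PVE")
    return math.sqrt(target_pve_percent / 100.0 * total_variance / vx)


def _total_variance(scenario_bg_var: float, pve_fractions: Sequence[float]) -> float:
    # T = background / (1 - sum of PVE fractions): the planted genetic
    # variance is itself part of the total
    s = sum(pve_fractions)
    if s >= 1.0:
        raise ValueError("planted PVEs must sum below 100%")
    return scenario_bg_var / (1.0 - s)


def _default_loci(k: int, fst_gap: float = 0.08) -> list[LocusSpec]:
    """15 tag loci (catalog-spanning frequencies, subpop differentiation)
    plus two LD copies planted on the 13th tag, forming a 3-locus group."""
    loci: list[LocusSpec] = []
    for i, p in enumerate(_DEFAULT_TAG_FREQS):
        lo = max(p - fst_gap, 0.005)
        hi = min(p + fst_gap, 0.995)
        freqs = tuple([lo, hi][j % 2] for j in range(k)) if k > 1 else (p,)
        gene = f"SimG{i + 1:02d}At"
        loci.append(LocusSpec(name=f"{gene}-A{100 + i}G", freqs=freqs))
    seed_locus = loci[12]  # the 0.755 tag; its gene gets two complete-LD copies
    gene = parse_snp_name(seed_locus.name)[0]
    for extra, pos in enumerate((300, 400)):
        loci.append(LocusSpec(
            name=f"{gene}-C{pos}T",
            freqs=seed_locus.freqs,
            ld_copy_of=seed_locus.name,
        ))
    return loci


def default_scenario(seed: int, **overrides) -> SimScenario:
    """The reference study conditions: 277 admixed inbred accessions, 17 loci
    (15 tags + one planted 3-locus complete-LD group), a 3x3 year-by-location
    grid, 4 main + 2 epistatic planted QTNs totalling ~13% PVE."""
    loci = _default_loci(overrides.get("k_subpops", 2))
    names = [l.name for l in loci]
    tmp = SimScenario(seed=seed, loci=loci, planted_effects=[],
                      **{k: v for k, v in overrides.items() if k != "planted_effects"})
    # background variance: environment spread + structure + residual
    struct_var = tmp.structure_effect ** 2 / (4.0 * (2.0 * tmp.admixture_concentration + 1.0))
    bg = tmp.env_variance + struct_var + tmp.residual_sd ** 2
    pves = [3.0, 2.5, 2.0, 2.0, 2.0, 1.5]
    total = _total_variance(bg, [p / 100.0 for p in pves])

    main_idx = [0, 2, 11, 12]           # freqs 0.612, 0.338, 0.209, 0.755
    effects: list[PlantedEffect] = []
    for pve, li in zip(pves[:4], main_idx):
        a = additive_effect_for_pve(pve, _DEFAULT_TAG_FREQS[li], total)
        effects.append(PlantedEffect(qtns=(names[li],), effect_type="a", size=a))
    for pve, (li, lj) in zip(pves[4:], [(1, 10), (4, 13)]):
        p1, p2 = _DEFAULT_TAG_FREQS[li], _DEFAULT_TAG_FREQS[lj]
        # centered-product variance for independent inbred loci:
        # Var(x1c x2c) = Var(x1) Var(x2) = 16 p1 q1 p2 q2
        vx = 16.0 * p1 * (1 - p1) * p2 * (1 - p2)
        size = math.sqrt(pve / 100.0 * total / vx)
        effects.append(PlantedEffect(qtns=(names[li], names[lj]), effect_type="aa", size=size))
    overrides.pop("planted_effects", None)
    return SimScenario(seed=seed, loci=loci, planted_effects=effects, **overrides)


def single_qtn_scenario(seed: int, pve_percent: float = 10.0, freq: float = 0.5,
                        **overrides) -> SimScenario:
    """One planted additive QTN at a structure-neutral locus (equal subpop
    frequencies) with an effect sized to the target PVE; no other effects."""
    k = overrides.get("k_subpops", 2)
    loci = [LocusSpec(name="SimG01At-A100G", freqs=tuple([freq] * max(k, 1)))]
    tmp = SimScenario(seed=seed, loci=loci, **overrides)
    struct_var = tmp.structure_effect ** 2 / (4.0 * (2.0 * tmp.admixture_concentration + 1.0)) if k > 1 else 0.0
    bg = tmp.env_variance + struct_var + tmp.residual_sd ** 2
    total = _total_variance(bg, [pve_percent / 100.0])
    a = additive_effect_for_pve(pve_percent, freq, total)
    return SimScenario(
        seed=seed, loci=loci,
        planted_effects=[PlantedEffect(qtns=(loci[0].name,), effect_type="a", size=a)],
        **overrides,
    )


def null_scenario(seed: int, **overrides) -> SimScenario:
    """The default panel with no planted genetic effects (pure-noise trait)."""
    sc = default_scenario(seed, **overrides)
    sc.planted_effects = []
    return sc


def power_scenario(seed: int, pve_percent: float = 10.0, **overrides) -> SimScenario:
    """The default panel with a single planted additive QTN at the target PVE."""
    loci = _default_loci(overrides.get("k_subpops", 2))
    names = [l.name for l in loci]
    tmp = SimScenario(seed=seed, loci=loci,
                      **{k: v for k, v in overrides.items() if k != "planted_effects"})
    struct_var = tmp.structure_effect ** 2 / (4.0 * (2.0 * tmp.admixture_concentration + 1.0))
    bg = tmp.env_variance + struct_var + tmp.residual_sd ** 2
    total = _total_variance(bg, [pve_percent / 100.0])
    a = additive_effect_for_pve(pve_percent, _DEFAULT_TAG_FREQS[0], total)
    overrides.pop("planted_effects", None)
    return SimScenario(
        seed=seed, loci=loci,
        planted_effects=[PlantedEffect(qtns=(names[0],), effect_type="a", size=a)],
        **overrides,
    )
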