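"""Favorable-allele identification and phenotypic effect estimation.

A declared QTN only becomes breeding-relevant once we know which allele (or,
for an epistatic QTN, which two-locus allele combination) moves the trait in
the agronomically desirable direction, and by how much in trait units. The
effect of an allele class is the difference of structure- and environment-
adjusted phenotype means between its carriers and all other accessions.
An alternative "carrier mean minus grand mean" mode is available.

The module also provides the two-way ANOVA used to confirm an epistatic
gene-pair signal at the haplotype level (Type-III sums of squares, so
unbalanced panels are handled by model comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

DIRECTION_HIGHER = "higher"
DIRECTION_LOWER = "lower"


@dataclass(frozen=True)
class TraitDirection:
    """Which way a trait should move to be agronomically better."""

    trait: str
    desirable: str  # 'higher' | 'lower'

    def __post_init__(self) -> None:
        if self.desirable not in (DIRECTION_HIGHER, DIRECTION_LOWER):
            raise ValueError(f"desirable must be 'higher' or 'lower', got {self.desirable!r}")


#: Default registry for the upland-cotton trait panel: fiber length/strength/
#: uniformity, lint percentage, boll weight and number, seed index, protein
#: and oil content all improve upward; fiber micronaire improves downward.
TRAIT_DIRECTIONS: dict[str, TraitDirection] = {
    t: TraitDirection(t, DIRECTION_HIGHER)
    for t in ("FL", "FS", "FU", "LP", "BW", "BN", "SI", "PC", "OC")
}
TRAIT_DIRECTIONS["FM"] = TraitDirection("FM", DIRECTION_LOWER)


@dataclass(frozen=True)
class AlleleEffect:
    """Effect of one allele (or allele combination) on one trait."""

    qtns: tuple[str, ...]
    allele: str
    trait: str
    effect: float          # signed, trait units
    favorable: bool
    carrier_count: int
    indeterminate: bool = False

    def __post_init__(self) -> None:
        if self.carrier_count < 1:
            raise ValueError("carrier count must be >= 1")


class EmptyClassError(ValueError):
    """Raised when a carrier or non-carrier class has no accessions."""


def allele_effect(
    pheno_adjusted: np.ndarray,
    carrier_mask: np.ndarray,
    mode: str = "difference",
) -> float:
    """Carrier-class effect on the adjusted phenotype.

    ``difference`` (default): mean(carriers) - mean(non-carriers).
    ``vs_grand``: mean(carriers) - grand mean.
    `pheno_adjusted` should be residualized on the fixed (structure +
    environment) part of the association model beforehand.
    """
    y = np.asarray(pheno_adjusted, dtype=float)
    mask = np.asarray(carrier_mask, dtype=bool)
    if y.shape != mask.shape:
        raise ValueError("phenotype vector and carrier mask differ in shape")
    if not mask.any():
        raise EmptyClassError("carrier class is empty")
    if mode == "vs_grand":
        return float(y[mask].mean() - y.mean())
    if mode != "difference":
        raise ValueError(f"unknown mode {mode!r}")
    if mask.all():
        raise EmptyClassError("non-carrier class is empty")
    return float(y[mask].mean() - y[~mask].mean())


def favorable_allele(
    qtns: tuple[str, ...],
    trait: str,
    effects: Mapping[str, float],
    carrier_counts: Mapping[str, int],
    direction: Optional[TraitDirection] = None,
) -> AlleleEffect:
    """Pick the allele/combination whose effect moves the trait the right way.

    `effects` maps each allele label (e.g. ``"A"``/``"G"``, or a joint label
    ``"G x C"`` for an epistatic QTN) to its signed effect. The winner is the
    label with the best effect in the desirable direction; its magnitude is
    reported with the direction noted by the sign of `effect`. An exact tie
    is flagged indeterminate rather than silently resolved.
    """
    if direction is None:
        if trait not in TRAIT_DIRECTIONS:
            raise KeyError(f"trait {trait!r} has no declared desirable direction")
        direction = TRAIT_DIRECTIONS[trait]
    if len(effects) < 2:
        raise ValueError("need effects for at least two alleles/combinations")
    sign = 1.0 if direction.desirable == DIRECTION_HIGHER else -1.0
    scored = sorted(effects.items(), key=lambda kv: -sign * kv[1])
    best, runner = scored[0], scored[1]
    tie = sign * best[1] == sign * runner[1]
    return AlleleEffect(
        qtns=qtns,
        allele=best[0],
        trait=trait,
        effect=best[1],
        favorable=True,
        carrier_count=carrier_counts[best[0]],
        indeterminate=tie,
    )


def adjusted_phenotype(y: np.ndarray, X_fixed: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Residualize stacked phenotypes on the fitted fixed effects."""
    return np.asarray(y, dtype=float) - np.asarray(X_fixed) @ np.asarray(beta)


def haplotype_interaction_anova(
    pheno: np.ndarray,
    hap_a: Sequence[str],
    hap_b: Sequence[str],
) -> tuple[float, float]:
    """F and p for the A x B interaction of a two-factor linear model.

    Type-III sums of squares with sum-to-zero contrasts, so the test is the
    model-comparison test of the interaction in unbalanced designs.
    """
    a = pd.Categorical(hap_a)
    b = pd.Categorical(hap_b)
    if len(a.categories) < 2 or len(b.categories) < 2:
        raise ValueError("both haplotype factors need >= 2 observed levels")
    df = pd.DataFrame({"y": np.asarray(pheno, dtype=float), "a": a, "b": b})
    fit = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    with warnings.catch_warnings():
        # a zero-residual, zero-interaction fit yields 0/0 -> NaN F below
        warnings.simplefilter("ignore")
        table = anova_lm(fit, typ=3)
    row = [ix for ix in table.index if ":" in str(ix)]
    if not row:
        raise RuntimeError("interaction row missing from the ANOVA table")
    f = float(table.loc[row[0], "F"])
    p = float(table.loc[row[0], "PR(>F)"])
    if np.isnan(f):  # zero residual variance with zero interaction SS
        f, p = 0.0, 1.0
    return f, p
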