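"""Empirical-Bayes epistatic association mapping for multi-environment trials.

The model for one trait over an inbred association panel grown in E
environments is

    y = X_p b_P + X_E b_E + Z_G g_G + Z_GE g_GE + Z_GG g_GG + e

where y stacks all accession-by-environment phenotype records, X_p holds the
population-structure covariates (STRUCTURE Q matrix, one column dropped),
X_E the environment design (intercept + E-1 indicators), and the Z blocks
hold the random QTN effects: main additive/dominance per tag SNP, QTN-by-
environment interactions, and all pairwise QTN-by-QTN (aa/ad/da/dd)
epistasis terms. Additive genotype code x is -1/0/+1 for ref-hom/het/alt-hom
and dominance code z is 1 for het else 0; on a fully inbred panel every
dominance-bearing block is identically zero and is pruned.

Every random-effect block g_j has its own prior g_j ~ N(0, s2_j I) whose
variance is estimated from the data (empirical Bayes) by an EM algorithm on
the marginal likelihood, with a diffuse scaled-inverse-chi-square hyperprior
(tau, omega) = (-2, 0) so the M-step is s2_j = (|g_j|^2 + tr S_j) / q_j.
Blocks whose variance collapses to the numerical floor are frozen at zero
(an absorbing EM fixed point) and leave the active set, which is what makes
a 200+-column scan affordable. Evidence per block is a Wald statistic on the
posterior, reported on the LOD scale: LOD = W / (2 ln 10), with
p = Pr(chi2_df >= 2 ln(10) LOD), so LOD 3 with df = 1 corresponds to
p = 2e-4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from eamkit._util import log
from eamkit.snp_catalog import parse_snp_name

TWO_LN_10 = 2.0 * math.log(10.0)

CALL_REF = 0.0
CALL_HET = 1.0
CALL_ALT = 2.0


# --------------------------------------------------------------------------
# containers

@dataclass
class GenotypePanel:
    """Accessions x loci call matrix, coded 0/1/2 (ref-hom/het/alt-hom), NaN missing."""

    accessions: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.accessions), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.loci)} loci"
            )
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[tuple(bad)]!r} at "
                f"accession {self.accessions[bad[0]]!r}, locus {self.loci[bad[1]]!r}"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession identifiers")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def has_hets(self) -> bool:
        return bool(np.any(self.calls == CALL_HET))

    def locus_index(self, name: str) -> int:
        try:
            return self.loci.index(name)
        except ValueError:
            raise KeyError(f"locus {name!r} not in panel") from None

    def gene_of(self, name: str) -> str:
        return parse_snp_name(name)[0]

    def imputed_calls(self) -> np.ndarray:
        """Calls with missing entries replaced by the locus mean (logged)."""
        out = self.calls.copy()
        n_missing = int(np.isnan(out).sum())
        if n_missing:
            log.info("mean-imputing %d missing genotype calls", n_missing)
            means = np.nanmean(out, axis=0)
            means = np.where(np.isnan(means), 0.0, means)
            idx = np.where(np.isnan(out))
            out[idx] = means[idx[1]]
        return out


@dataclass
class PhenotypeTable:
    """Long-format (accession, environment, trait, value) observations."""

    observations: pd.DataFrame
    environments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        req = ["accession", "environment", "trait", "value"]
        missing = [c for c in req if c not in self.observations.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        obs = self.observations[req].copy()
        obs["value"] = obs["value"].astype(float)
        dup = obs.duplicated(subset=["accession", "environment", "trait"])
        if dup.any():
            first = obs[dup].iloc[0]
            raise ValueError(
                "duplicate phenotype record for "
                f"({first['accession']}, {first['environment']}, {first['trait']})"
            )
        self.observations = obs
        declared = list(self.environments)
        seen = list(dict.fromkeys(obs["environment"]))
        if declared:
            extra = [e for e in seen if e not in declared]
            if extra:
                raise ValueError(f"environments {extra} not in the declared grid {declared}")
        else:
            self.environments = sorted(seen)

    @property
    def traits(self) -> list[str]:
        return sorted(self.observations["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        sub = self.observations[self.observations["trait"] == trait]
        if sub.empty:
            raise KeyError(f"trait {trait!r} absent from phenotype table")
        return sub.sort_values(["accession", "environment"], kind="mergesort").reset_index(drop=True)


@dataclass
class QMatrix:
    """Accession x subpopulation membership fractions (rows sum to one)."""

    accessions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.accessions):
            raise ValueError("Q matrix rows do not match accessions")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("Q memberships must lie in [0, 1]")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q matrix rows must sum to 1")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def rows_for(self, accessions: Sequence[str]) -> np.ndarray:
        index = {a: i for i, a in enumerate(self.accessions)}
        try:
            sel = [index[a] for a in accessions]
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} missing from Q matrix") from None
        return self.values[sel]


@dataclass(frozen=True)
class EffectBlock:
    """One random-effect block: its model term, the QTN(s), and design columns."""

    name: str
    term: str               # 'main' | 'gxe' | 'epistatic'
    qtns: tuple[str, ...]
    effect_type: str        # a, d, axE, dxE, aa, ad, da, dd
    cols: tuple[int, ...]   # column indices into Z


@dataclass
class EamDesign:
    """Response plus fixed and random design for one trait."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    blocks: list[EffectBlock]
    dropped: list[str]
    row_accessions: list[str]
    row_environments: list[str]
    trait: str

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("design row counts disagree with y")

    @property
    def n(self) -> int:
        return len(self.y)

    def block(self, name: str) -> EffectBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        if name in self.dropped:
            raise KeyError(f"block {name!r} was pruned from the design (degenerate columns)")
        raise KeyError(f"no block named {name!r}")

    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]


@dataclass
class EamControl:
    """Fit controls; defaults give the deterministic reference behaviour."""

    max_iter: int = 1000
    tol: float = 1e-8
    tau: float = -2.0
    omega: float = 0.0
    var_floor_rel: float = 1e-10
    #: a shrinking block whose Wald statistic stays below this for
    #: `freeze_patience` iterations is frozen at zero (EM decay toward a
    #: zero variance is sublinear, so waiting for the floor is hopeless;
    #: W < 1 is two orders of magnitude below the declaration threshold
    #: W = 2 ln(10) * 3 = 13.8)
    freeze_wald: float = 1.0
    freeze_patience: int = 2
    fixed_variances: dict[str, float] = field(default_factory=dict)


@dataclass
class EamFit:
    beta: np.ndarray
    gamma: dict[str, np.ndarray]
    post_cov: dict[str, np.ndarray]
    sigma2: dict[str, float]
    sigma2_e: float
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    final_change: float

    def fitted_fixed(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta


@dataclass(frozen=True)
class QtnResult:
    term: str
    qtns: tuple[str, ...]
    effect_type: str
    lod: float
    p: float
    pve: float
    effect: float
    favorable_allele: Optional[str] = None

    @property
    def name(self) -> str:
        return " x ".join(self.qtns) + f":{self.effect_type}"


@dataclass
class ScanResult:
    """Declared QTNs plus scan-level bookkeeping."""

    qtns: list[QtnResult]
    all_blocks: list[QtnResult]
    no_gxe_significant: bool
    design: EamDesign
    fit: EamFit

    def __iter__(self):
        return iter(self.qtns)

    def __len__(self) -> int:
        return len(self.qtns)


# --------------------------------------------------------------------------
# design construction

def _additive(codes: np.ndarray) -> np.ndarray:
    return codes - 1.0


def _dominance(codes: np.ndarray) -> np.ndarray:
    return (codes == CALL_HET).astype(float)


def build_design(
    panel: GenotypePanel,
    pheno: PhenotypeTable,
    trait: str,
    q: QMatrix,
    tag_snps: Sequence[str],
    include_gxe: bool = True,
    include_epistasis: bool = True,
) -> EamDesign:
    """Assemble the stacked multi-environment design for one trait.

    Rows are phenotype observations sorted by (accession, environment), so
    the design is invariant to input row order. Fixed part: intercept,
    k-1 structure covariates, E-1 environment indicators. Random blocks:
    per-SNP additive (and dominance when hets exist), per-SNP additive-by-
    environment (E columns), and per-pair aa (ad/da/dd with hets) epistasis.
    Constant columns are pruned and the owning block recorded in `dropped`
    when nothing of it remains.
    """
    # Interaction columns are built from CENTERED additive/dominance codes
    # (Cockerham-style orthogonal epistasis coding) and environment-indicator
    # CONTRASTS. With variant frequencies far from 0.5 the raw product
    # x1*x2 is nearly collinear with its parent main columns
    # (corr(x1*x2, x1) -> E[x2]), and the E raw x*indicator columns sum to
    # the main column exactly; either collinearity lets a main effect leak
    # into interaction blocks and back. Centering removes both while leaving
    # the interaction coefficients themselves unchanged (the product
    # coefficient is invariant to centering when mains are in the model).
    obs = pheno.for_trait(trait)
    obs = obs[~obs["value"].isna()].reset_index(drop=True)
    if obs.empty:
        raise ValueError(f"no non-missing observations for trait {trait!r}")
    envs = pheno.environments
    if include_gxe and len(envs) < 2:
        raise ValueError("QTN-by-environment effects need at least 2 environments")

    panel_index = {a: i for i, a in enumerate(panel.accessions)}
    missing_acc = sorted(set(obs["accession"]) - set(panel_index))
    if missing_acc:
        raise KeyError(f"accessions {missing_acc[:5]} have phenotypes but no genotypes")

    tag_snps = list(tag_snps)
    locus_cols = [panel.locus_index(s) for s in tag_snps]
    imputed = panel.imputed_calls()[:, locus_cols]          # accession x tag
    acc_rows = np.array([panel_index[a] for a in obs["accession"]])
    codes = imputed[acc_rows]                               # obs x tag
    x = _additive(codes)
    z = _dominance(codes)
    any_het = bool((z != 0).any(axis=0).any())

    env_of_row = pd.Categorical(obs["environment"], categories=envs)
    env_idx = np.asarray(env_of_row.codes)
    env_ind = np.zeros((len(obs), len(envs)))
    env_ind[np.arange(len(obs)), env_idx] = 1.0

    y = obs["value"].to_numpy(dtype=float)
    q_rows = q.rows_for(list(obs["accession"]))
    X_parts = [np.ones((len(obs), 1))]
    if q.k > 1:
        X_parts.append(q_rows[:, : q.k - 1])
    if len(envs) > 1:
        X_parts.append(env_ind[:, 1:])
    X = np.hstack(X_parts)

    z_cols: list[np.ndarray] = []
    blocks: list[EffectBlock] = []
    dropped: list[str] = []

    def add_block(name: str, term: str, qtns: tuple[str, ...], etype: str,
                  cols: np.ndarray) -> None:
        cols = np.atleast_2d(cols.T).T if cols.ndim == 1 else cols
        keep = [j for j in range(cols.shape[1]) if np.ptp(cols[:, j]) > 0]
        if not keep:
            dropped.append(name)
            log.info("pruned degenerate block %s", name)
            return
        if len(keep) < cols.shape[1]:
            log.info("pruned %d constant columns from block %s", cols.shape[1] - len(keep), name)
        start = sum(c.shape[1] for c in z_cols)
        z_cols.append(cols[:, keep])
        blocks.append(EffectBlock(
            name=name, term=term, qtns=qtns, effect_type=etype,
            cols=tuple(range(start, start + len(keep))),
        ))

    xc = x - x.mean(axis=0, keepdims=True)
    zc = z - z.mean(axis=0, keepdims=True)
    env_contrast = env_ind[:, 1:] - env_ind[:, 1:].mean(axis=0, keepdims=True)

    for t, snp in enumerate(tag_snps):
        add_block(f"{snp}:a", "main", (snp,), "a", x[:, [t]])
    if any_het:
        for t, snp in enumerate(tag_snps):
            add_block(f"{snp}:d", "main", (snp,), "d", z[:, [t]])
    if include_gxe:
        for t, snp in enumerate(tag_snps):
            add_block(f"{snp}:axE", "gxe", (snp,), "axE", xc[:, [t]] * env_contrast)
        if any_het:
            for t, snp in enumerate(tag_snps):
                add_block(f"{snp}:dxE", "gxe", (snp,), "dxE", zc[:, [t]] * env_contrast)
    if include_epistasis:
        for i in range(len(tag_snps)):
            for j in range(i + 1, len(tag_snps)):
                pair = (tag_snps[i], tag_snps[j])
                label = f"{pair[0]} x {pair[1]}"
                add_block(f"{label}:aa", "epistatic", pair, "aa", xc[:, [i]] * xc[:, [j]])
                if any_het:
                    add_block(f"{label}:ad", "epistatic", pair, "ad", xc[:, [i]] * zc[:, [j]])
                    add_block(f"{label}:da", "epistatic", pair, "da", zc[:, [i]] * xc[:, [j]])
                    add_block(f"{label}:dd", "epistatic", pair, "dd", zc[:, [i]] * zc[:, [j]])

    Z = np.hstack(z_cols) if z_cols else np.zeros((len(obs), 0))
    return EamDesign(
        y=y, X=X, Z=Z, blocks=blocks, dropped=dropped,
        row_accessions=list(obs["accession"]),
        row_environments=list(obs["environment"]),
        trait=trait,
    )


# --------------------------------------------------------------------------
# empirical-Bayes EM

def _marginal_loglik(n: int, s: float, d: np.ndarray, chol_K: np.ndarray,
                     rtr: float, Ztr: np.ndarray, A_Ztr: np.ndarray) -> float:
    # |V| = s^(n-m) |s D^-1 + G| |D|  via the Woodbury determinant identity
    logdet_K = 2.0 * float(np.sum(np.log(np.diag(chol_K))))
    logdet_V = (n - len(d)) * math.log(s) + logdet_K + float(np.sum(np.log(d)))
    quad = (rtr - float(Ztr @ A_Ztr)) / s
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet_V + quad)


def empirical_bayes_fit(design: EamDesign, control: Optional[EamControl] = None) -> EamFit:
    """EM fit of the hierarchical model on the marginal likelihood.

    E-step: posterior mean/covariance of each effect block given the current
    variances (all blocks jointly, through the Woodbury identity so only
    m x m systems are solved). M-step: s2_j from the posterior second
    moment, residual variance from the expected residual sum of squares;
    fixed effects re-estimated by GLS every iteration. Deterministic: no
    randomness anywhere in the fit.
    """
    control = control or EamControl()
    y, X, Z = design.y, design.X, design.Z
    n, m = len(y), Z.shape[1]
    n_blocks = len(design.blocks)
    var_y = float(np.var(y))

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effect design matrix")

    if var_y == 0.0 or m == 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s_e = max(float(resid @ resid) / max(n - X.shape[1], 1), 1e-300)
        return EamFit(
            beta=beta,
            gamma={b.name: np.zeros(len(b.cols)) for b in design.blocks},
            post_cov={b.name: np.zeros((len(b.cols), len(b.cols))) for b in design.blocks},
            sigma2={b.name: 0.0 for b in design.blocks},
            sigma2_e=s_e,
            loglik_trace=[],
            converged=True,
            n_iter=0,
            final_change=0.0,
        )

    # precomputed cross-products; everything after this is m- or p-dimensional
    G = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    floor = control.var_floor_rel * var_y
    init = var_y / (n_blocks + 1)
    sigma2 = np.full(n_blocks, init)
    fixed_mask = np.zeros(n_blocks, dtype=bool)
    for bi, b in enumerate(design.blocks):
        if b.name in control.fixed_variances:
            v = control.fixed_variances[b.name]
            sigma2[bi] = min(v, 1e12)  # cap +inf at a huge ridge-free value
            fixed_mask[bi] = True
    s = init
    active = [bi for bi in range(n_blocks) if sigma2[bi] > 0 or fixed_mask[bi]]
    block_cols = [np.asarray(b.cols) for b in design.blocks]
    q_sizes = np.array([len(c) for c in block_cols])

    loglik_trace: list[float] = []
    converged = False
    change = np.inf
    it = 0

    def e_step(active_now: list[int], sigma2_now: np.ndarray, s_now: float) -> dict:
        """Posterior of gamma and GLS beta at the given variances (Woodbury)."""
        cols = (np.concatenate([block_cols[bi] for bi in active_now])
                if active_now else np.array([], int))
        d = (np.concatenate([np.full(q_sizes[bi], sigma2_now[bi]) for bi in active_now])
             if active_now else np.array([]))
        Ga = G[np.ix_(cols, cols)]
        ZtXa = ZtX[cols]
        Ztya = Zty[cols]
        K = Ga + np.diag(s_now / d) if len(d) else np.zeros((0, 0))
        try:
            chol = np.linalg.cholesky(K) if len(d) else np.zeros((0, 0))
        except np.linalg.LinAlgError:
            K = K + 1e-10 * max(s_now, 1.0) * np.eye(len(d))
            chol = np.linalg.cholesky(K)

        def K_solve(B: np.ndarray) -> np.ndarray:
            if len(d) == 0:
                return np.zeros_like(B)
            z1 = sla.solve_triangular(chol, B, lower=True)
            return sla.solve_triangular(chol.T, z1, lower=False)

        XtVX = (XtX - ZtXa.T @ K_solve(ZtXa)) / s_now
        XtVy = (Xty - ZtXa.T @ K_solve(Ztya)) / s_now
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError("singular fixed-effect GLS system") from e
        Ztr = Ztya - ZtXa @ beta
        rtr = yty - 2.0 * float(beta @ Xty) + float(beta @ XtX @ beta)
        gamma_a = K_solve(Ztr)                       # posterior mean
        A = K_solve(np.eye(len(d))) if len(d) else np.zeros((0, 0))
        ll = _marginal_loglik(n, s_now, d, chol, rtr, Ztr, gamma_a)
        return {"cols": cols, "Ga": Ga, "Ztr": Ztr, "rtr": rtr,
                "gamma_a": gamma_a, "A": A, "beta": beta, "loglik": ll}

    low_wald_count = np.zeros(n_blocks, dtype=int)
    st = e_step(active, sigma2, s)
    for it in range(1, control.max_iter + 1):
        loglik_trace.append(st["loglik"])
        gamma_a, A, Ga, Ztr, rtr = st["gamma_a"], st["A"], st["Ga"], st["Ztr"], st["rtr"]

        new_sigma2 = sigma2.copy()
        wald = np.full(n_blocks, np.inf)
        offset = 0
        for bi in active:
            qj = q_sizes[bi]
            sl = slice(offset, offset + qj)
            offset += qj
            g = gamma_a[sl]
            S = s * A[sl, sl]
            try:
                wald[bi] = float(g @ np.linalg.solve(S, g))
            except np.linalg.LinAlgError:
                wald[bi] = float(g @ np.linalg.pinv(S) @ g)
            if fixed_mask[bi]:
                continue
            tr_post = s * float(np.trace(A[sl, sl]))
            new_sigma2[bi] = (float(g @ g) + tr_post + control.omega) / (qj + control.tau + 2.0)

        ete = rtr - 2.0 * float(gamma_a @ Ztr) + float(gamma_a @ Ga @ gamma_a)
        new_s = (ete + s * float(np.sum(Ga * A))) / n
        new_s = max(new_s, 1e-12 * var_y)

        prev = np.append(sigma2[active], s) if active else np.array([s])
        curr = np.append(new_sigma2[active], new_s) if active else np.array([new_s])
        denom = np.maximum(np.abs(prev), floor)
        change = float(np.max(np.abs(curr - prev) / denom)) if len(prev) else 0.0

        shrinking = new_sigma2 < sigma2
        sigma2 = new_sigma2
        s = new_s
        for bi in active:
            if not fixed_mask[bi] and shrinking[bi] and wald[bi] < control.freeze_wald:
                low_wald_count[bi] += 1
            else:
                low_wald_count[bi] = 0
        newly_frozen = {
            bi for bi in active
            if not fixed_mask[bi]
            and (sigma2[bi] < floor or low_wald_count[bi] >= control.freeze_patience)
        }
        if newly_frozen:
            for bi in newly_frozen:
                sigma2[bi] = 0.0
            active = [bi for bi in active if bi not in newly_frozen]

        st = e_step(active, sigma2, s)
        if change < control.tol:
            converged = True
            break

    if not converged:
        log.warning("EM did not converge in %d iterations (last change %.3g)", it, change)

    # posterior per block at the final variances (st is consistent with them)
    beta = st["beta"]
    A = st["A"]
    gamma_full = np.zeros(m)
    gamma_full[st["cols"]] = st["gamma_a"]
    gamma = {}
    post_cov = {}
    col_offsets = {}
    pos = 0
    for bi in active:
        col_offsets[bi] = pos
        pos += q_sizes[bi]
    active_set = set(active)
    for bi, b in enumerate(design.blocks):
        qj = q_sizes[bi]
        if bi in active_set:
            o = col_offsets[bi]
            gamma[b.name] = gamma_full[block_cols[bi]].copy()
            post_cov[b.name] = s * A[o:o + qj, o:o + qj]
        else:
            gamma[b.name] = np.zeros(qj)
            post_cov[b.name] = np.zeros((qj, qj))

    return EamFit(
        beta=beta,
        gamma=gamma,
        post_cov=post_cov,
        sigma2={b.name: float(sigma2[bi]) for bi, b in enumerate(design.blocks)},
        sigma2_e=float(s),
        loglik_trace=loglik_trace,
        converged=converged,
        n_iter=it,
        final_change=float(change),
    )


# --------------------------------------------------------------------------
# evidence and variance explained

def compute_lod(fit: EamFit, block: str) -> tuple[float, int]:
    """Wald evidence for one block on the LOD scale: W / (2 ln 10), df = block size."""
    if block not in fit.gamma:
        raise KeyError(f"block {block!r} not present in the fit")
    g = fit.gamma[block]
    df = len(g)
    if not np.any(g):
        return 0.0, df
    S = fit.post_cov[block]
    try:
        w = float(g @ np.linalg.solve(S, g))
    except np.linalg.LinAlgError:
        log.warning("singular posterior covariance for block %s; using pseudo-inverse", block)
        w = float(g @ np.linalg.pinv(S) @ g)
    return max(w, 0.0) / TWO_LN_10, df


def lod_to_pvalue(lod: float, df: int) -> float:
    """p = Pr(chi2_df >= 2 ln(10) * lod); LOD 3, df 1 gives p ~ 2e-4."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if lod < 0:
        raise ValueError(f"LOD must be >= 0, got {lod}")
    return float(stats.chi2.sf(TWO_LN_10 * lod, df))


def compute_pve(design: EamDesign, fit: EamFit, block: str) -> float:
    """Percent phenotypic variance explained: 100 Var(Z_j g_j) / Var(y)."""
    b = design.block(block)
    var_y = float(np.var(design.y))
    if var_y == 0.0:
        raise ValueError("Var(y) is zero; PVE undefined")
    contrib = design.Z[:, list(b.cols)] @ fit.gamma[block]
    return 100.0 * float(np.var(contrib)) / var_y


# --------------------------------------------------------------------------
# the scan

def scan(
    panel: GenotypePanel,
    pheno: PhenotypeTable,
    trait: str,
    q: QMatrix,
    tag_snps: Sequence[str],
    control: Optional[EamControl] = None,
    lod_threshold: float = 3.0,
    include_gxe: bool = True,
    include_epistasis: bool = True,
) -> ScanResult:
    """Fit the full joint model for one trait and declare QTNs at LOD >= threshold.

    All main, QTN-by-environment and pairwise epistasis blocks are estimated
    simultaneously (a single multi-QTN model, not one-at-a-time tests).
    Declared QTNs are sorted by LOD descending. Whether any QTN-by-
    environment block passed is recorded on the result.
    """
    design = build_design(
        panel, pheno, trait, q, tag_snps,
        include_gxe=include_gxe, include_epistasis=include_epistasis,
    )
    fit = empirical_bayes_fit(design, control)

    all_results: list[QtnResult] = []
    for b in design.blocks:
        lod, df = compute_lod(fit, b.name)
        p = lod_to_pvalue(lod, df)
        pve = compute_pve(design, fit, b.name)
        g = fit.gamma[b.name]
        effect = float(g[0]) if len(g) == 1 else float(np.sqrt(np.mean(g ** 2)))
        all_results.append(QtnResult(
            term=b.term, qtns=b.qtns, effect_type=b.effect_type,
            lod=lod, p=p, pve=pve, effect=effect,
        ))

    declared = sorted(
        (r for r in all_results if r.lod >= lod_threshold),
        key=lambda r: -r.lod,
    )
    no_gxe = not any(r.term == "gxe" for r in declared)
    if no_gxe and include_gxe:
        log.info("no QTN-by-environment block reached LOD >= %.3g", lod_threshold)
    return ScanResult(
        qtns=declared, all_blocks=all_results,
        no_gxe_significant=no_gxe, design=design, fit=fit,
    )
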