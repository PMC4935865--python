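"""Design construction, empirical-Bayes EM, LOD/p/PVE."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eamkit as ek
from eamkit.eam_model import (
    EamControl,
    GenotypePanel,
    PhenotypeTable,
    QMatrix,
    build_design,
    compute_lod,
    compute_pve,
    empirical_bayes_fit,
    lod_to_pvalue,
)

from conftest import make_inbred_panel


def toy_inputs(n=4, loci=2, envs=2, seed=0, hets=False):
    rng = np.random.default_rng(seed)
    codes = [0.0, 2.0] if not hets else [0.0, 1.0, 2.0]
    panel = make_inbred_panel(rng.choice(codes, size=(n, loci)))
    env_names = [f"E{e}" for e in range(envs)]
    obs = pd.DataFrame({
        "accession": np.repeat(panel.accessions, envs),
        "environment": env_names * n,
        "trait": "SYN",
        "value": rng.normal(size=n * envs),
    })
    pheno = PhenotypeTable(observations=obs, environments=env_names)
    qv = rng.dirichlet([1, 1], size=n)
    q = QMatrix(accessions=panel.accessions, values=qv)
    return panel, pheno, q


class TestBuildDesign:
    def test_toy_dimensions(self):
        panel, pheno, q = toy_inputs(n=4, loci=2, envs=2)
        d = build_design(panel, pheno, "SYN", q, panel.loci,
                         include_gxe=False, include_epistasis=False)
        assert d.n == 8
        # intercept + 1 structure column + 1 environment indicator
        assert d.X.shape == (8, 3)

    def test_inbred_panel_prunes_all_dominance_blocks(self):
        panel, pheno, q = toy_inputs(n=20, loci=3, envs=2)
        d = build_design(panel, pheno, "SYN", q, panel.loci)
        assert not any(b.effect_type in ("d", "dd", "ad", "da", "dxE") for b in d.blocks)

    def test_het_panel_gets_dominance_blocks(self):
        panel, pheno, q = toy_inputs(n=30, loci=2, envs=2, hets=True)
        d = build_design(panel, pheno, "SYN", q, panel.loci)
        types = {b.effect_type for b in d.blocks}
        assert {"a", "d", "aa", "ad", "da", "dd"} <= types

    def test_15_tags_enumerate_105_epistatic_pairs(self, default_sim):
        scenario, q, panel, pheno, _ = default_sim
        d = build_design(panel, pheno, scenario.trait_name, q, scenario.tag_loci())
        n_epi = sum(b.term == "epistatic" for b in d.blocks)
        n_epi += sum(":aa" in name for name in d.dropped)
        assert n_epi == 15 * 14 // 2

    def test_single_environment_rejects_gxe(self):
        panel, pheno, q = toy_inputs(n=4, loci=2, envs=1)
        with pytest.raises(ValueError):
            build_design(panel, pheno, "SYN", q, panel.loci, include_gxe=True)

    def test_missing_trait_raises(self):
        panel, pheno, q = toy_inputs()
        with pytest.raises(KeyError):
            build_design(panel, pheno, "NOPE", q, panel.loci)

    def test_accession_mismatch_raises(self):
        panel, pheno, q = toy_inputs()
        q2 = QMatrix(accessions=["other"], values=np.array([[0.5, 0.5]]))
        with pytest.raises(KeyError):
            build_design(panel, pheno, "SYN", q2, panel.loci)


class TestEmpiricalBayesFit:
    def test_zero_variance_response_gives_null_fit(self):
        panel, pheno, q = toy_inputs(n=10, loci=2, envs=2)
        pheno.observations["value"] = 3.14
        d = build_design(panel, pheno, "SYN", q, panel.loci, include_gxe=False)
        fit = empirical_bayes_fit(d)
        assert all(np.all(g == 0) for g in fit.gamma.values())
        assert all(v == 0 for v in fit.sigma2.values())
        assert fit.sigma2_e > 0

    def test_fixed_huge_variance_reproduces_ols(self):
        sc = ek.single_qtn_scenario(5)
        q, panel, pheno, _ = ek.simulate_all(sc)
        d = build_design(panel, pheno, sc.trait_name, q, sc.tag_loci(),
                         include_gxe=False, include_epistasis=False)
        fit = empirical_bayes_fit(
            d, EamControl(fixed_variances={"SimG01At-A100G:a": float("inf")}))
        W = np.hstack([d.X, d.Z])
        coef, *_ = np.linalg.lstsq(W, d.y, rcond=None)
        assert fit.gamma["SimG01At-A100G:a"][0] == pytest.approx(coef[-1], rel=1e-6)

    def test_em_loglik_monotone_without_freezing(self, default_sim):
        scenario, q, panel, pheno, _ = default_sim
        d = build_design(panel, pheno, scenario.trait_name, q, scenario.tag_loci())
        fit = empirical_bayes_fit(
            d, EamControl(freeze_wald=0.0, var_floor_rel=0.0, max_iter=60))
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs > -1e-8)

    def test_parameter_recovery_single_planted_qtn(self):
        sc = ek.single_qtn_scenario(7, pve_percent=10.0)
        q, panel, pheno, truth = ek.simulate_all(sc)
        d = build_design(panel, pheno, sc.trait_name, q, sc.tag_loci(),
                         include_gxe=False, include_epistasis=False)
        fit = empirical_bayes_fit(d)
        a_true = sc.planted_effects[0].size
        a_hat = fit.gamma["SimG01At-A100G:a"][0]
        sd = math.sqrt(fit.post_cov["SimG01At-A100G:a"][0, 0])
        assert abs(a_hat - a_true) < 3 * sd

    def test_singular_fixed_design_raises(self):
        panel, pheno, q = toy_inputs(n=10, loci=2, envs=2)
        d = build_design(panel, pheno, "SYN", q, panel.loci, include_gxe=False)
        d.X = np.hstack([d.X, d.X[:, :1]])  # duplicate intercept
        with pytest.raises(np.linalg.LinAlgError):
            empirical_bayes_fit(d)

    def test_permuting_accessions_leaves_statistics_unchanged(self, default_sim):
        scenario, q, panel, pheno, _ = default_sim
        perm = np.random.default_rng(0).permutation(panel.n_accessions)
        panel2 = GenotypePanel(
            accessions=[panel.accessions[i] for i in perm],
            loci=panel.loci, calls=panel.calls[perm])
        r1 = ek.scan(panel, pheno, scenario.trait_name, q, scenario.tag_loci(),
                     include_gxe=False)
        r2 = ek.scan(panel2, pheno, scenario.trait_name, q, scenario.tag_loci(),
                     include_gxe=False)
        s1 = {r.name: (r.lod, r.p, r.pve) for r in r1.all_blocks}
        s2 = {r.name: (r.lod, r.p, r.pve) for r in r2.all_blocks}
        for name in s1:
            assert s1[name] == pytest.approx(s2[name], abs=1e-9)


class TestLodAndPvalue:
    def test_zero_gamma_gives_zero_lod(self, default_scan):
        _, _, result = default_scan
        frozen = [b for b in result.design.block_names()
                  if not np.any(result.fit.gamma[b])]
        assert frozen
        lod, _ = compute_lod(result.fit, frozen[0])
        assert lod == 0.0

    def test_scalar_wald_arithmetic(self):
        # W = 13.8155 on 1 df sits exactly at LOD 3.000
        assert 13.8155 / (2 * math.log(10)) == pytest.approx(3.000, abs=5e-4)

    def test_missing_block_raises(self, default_scan):
        _, _, result = default_scan
        with pytest.raises(KeyError):
            compute_lod(result.fit, "not-a-block")

    def test_dropped_block_query_raises(self, default_sim):
        scenario, q, panel, pheno, _ = default_sim
        d = build_design(panel, pheno, scenario.trait_name, q, scenario.tag_loci())
        if d.dropped:
            with pytest.raises(KeyError):
                d.block(d.dropped[0])

    def test_lod3_df1_is_two_e_minus_4(self):
        assert lod_to_pvalue(3.0, 1) == pytest.approx(2e-4, rel=0.05)
        # full precision from the chi-square survival function at 13.8155
        assert lod_to_pvalue(3.0, 1) == pytest.approx(2.01666e-4, rel=1e-4)

    def test_lod_zero_is_p_one(self):
        assert lod_to_pvalue(0.0, 1) == 1.0

    def test_strictly_decreasing_in_lod(self):
        lods = np.linspace(0, 10, 50)
        ps = [lod_to_pvalue(l, 1) for l in lods]
        assert np.all(np.diff(ps) < 0)

    def test_roundtrip_with_chi2_quantile(self):
        for lod in (0.5, 3.0, 7.7):
            for df in (1, 4, 9):
                p = lod_to_pvalue(lod, df)
                back = stats.chi2.isf(p, df) / (2 * math.log(10))
                assert back == pytest.approx(lod, abs=1e-9)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            lod_to_pvalue(3.0, 0)


class TestComputePve:
    def test_zero_gamma_zero_pve(self, default_scan):
        _, _, result = default_scan
        frozen = [b for b in result.design.block_names()
                  if not np.any(result.fit.gamma[b])]
        assert compute_pve(result.design, result.fit, frozen[0]) == 0.0

    def test_pve_recovery_mean_over_replicates(self):
        # single planted QTN built to explain 10% of variance
        r2 = []
        for seed in range(50):
            sc = ek.single_qtn_scenario(1000 + seed, pve_percent=10.0)
            q, panel, pheno, _ = ek.simulate_all(sc)
            d = build_design(panel, pheno, sc.trait_name, q, sc.tag_loci(),
                             include_gxe=False, include_epistasis=False)
            fit = empirical_bayes_fit(d)
            r2.append(compute_pve(d, fit, "SimG01At-A100G:a"))
        assert np.mean(r2) == pytest.approx(10.0, abs=3.0)

    def test_block_pves_sum_below_total(self, default_scan):
        _, _, result = default_scan
        total = sum(compute_pve(result.design, result.fit, b)
                    for b in result.design.block_names())
        assert total <= 100.0


class TestScan:
    def test_planted_epistasis_recovered(self):
        sc = ek.default_scenario(29)
        q, panel, pheno, _ = ek.simulate_all(sc)
        result = ek.scan(panel, pheno, sc.trait_name, q, sc.tag_loci())
        declared = {r.name for r in result.qtns}
        assert "SimG02At-A101G x SimG11At-A110G:aa" in declared

    def test_results_sorted_by_lod(self, default_scan):
        _, _, result = default_scan
        lods = [r.lod for r in result.qtns]
        assert lods == sorted(lods, reverse=True)

    def test_no_gxe_flag_recorded(self, default_scan):
        _, _, result = default_scan
        assert result.no_gxe_significant == (
            not any(r.term == "gxe" for r in result.qtns))

    def test_threshold_monotonicity(self, default_scan):
        scenario, _, result = default_scan
        at3 = len(result.qtns)
        at10 = sum(r.lod >= 10 for r in result.all_blocks)
        assert at10 <= at3
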