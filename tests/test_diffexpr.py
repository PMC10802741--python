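"""Moderated differential expression: consensus correlation, variance
prior recovery, GLS oracle agreement, signatures, ratio score and GSEA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lnresponse import diffexpr
from lnresponse import simulate as sim
from lnresponse.clinical import wilcoxon_test


def _null_cohort(seed, n_pat=50, visits=3, n_genes=500, sigma_p=0.5):
    cfg = sim.BulkSimConfig(n_patients_per_arm=n_pat // 2,
                            visits_per_patient=visits, n_genes=n_genes,
                            n_up=0, n_down=0, effect_size=0.0,
                            patient_sd=sigma_p, noise_sd=0.5,
                            drugs=("MMF",), seed=seed)
    return sim.generate_bulk_cohort(cfg)


class TestConsensusCorrelation:
    def test_recovers_icc_half(self):
        """sigma_p = sigma_e gives intra-patient correlation 0.5."""
        expr, cohort, _ = _null_cohort(seed=3)
        design = diffexpr.build_design(cohort)
        rho = diffexpr.estimate_consensus_correlation(
            expr, cohort["patient_id"], design)
        assert rho == pytest.approx(0.5, abs=0.1)

    def test_independence_limit(self):
        expr, cohort, _ = _null_cohort(seed=4, sigma_p=0.0)
        design = diffexpr.build_design(cohort)
        rho = diffexpr.estimate_consensus_correlation(
            expr, cohort["patient_id"], design)
        assert abs(rho) < 0.05

    def test_singleton_blocks_return_zero_with_warning(self):
        expr, cohort, _ = _null_cohort(seed=5, visits=1)
        design = diffexpr.build_design(cohort)
        with pytest.warns(UserWarning):
            rho = diffexpr.estimate_consensus_correlation(
                expr, cohort["patient_id"], design)
        assert rho == 0.0


class TestVariancePrior:
    def test_hyperparameter_recovery(self):
        """(d0, s0^2) recovered from variances drawn from the prior."""
        rng = np.random.default_rng(0)
        d0, s02 = 4.0, 2.0
        s2 = s02 * d0 / rng.chisquare(d0, 2000)
        d0_hat, s02_hat = diffexpr.estimate_variance_prior(s2, np.inf)
        assert d0_hat == pytest.approx(d0, abs=1.0)
        assert s02_hat == pytest.approx(s02, abs=0.3)

    def test_recovery_with_finite_residual_dof(self):
        rng = np.random.default_rng(1)
        d0, s02, df = 4.0, 2.0, 30
        sigma2 = s02 * d0 / rng.chisquare(d0, 2000)
        s2 = sigma2 * rng.chisquare(df, 2000) / df
        d0_hat, s02_hat = diffexpr.estimate_variance_prior(s2, df)
        assert d0_hat == pytest.approx(d0, abs=1.0)
        assert s02_hat == pytest.approx(s02, abs=0.3)

    def test_identical_variances_give_infinity_sentinel(self):
        d0, s02 = diffexpr.estimate_variance_prior(np.full(100, 1.7), 10)
        assert np.isinf(d0)
        assert s02 == pytest.approx(1.7, rel=1e-12)


def _two_group_data(seed, n=10, n_genes=40):
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(rng.normal(5, 1, (n_genes, 2 * n)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{i}" for i in range(2 * n)])
    design = pd.DataFrame({"intercept": 1.0,
                           "response": [0.0] * n + [1.0] * n},
                          index=expr.columns)
    return expr, design


class TestModeratedDE:
    def test_matches_two_sample_regression_oracle(self):
        """rho=0, no covariates: moderated t with shrinkage off equals a
        from-scratch per-gene OLS oracle."""
        expr, design = _two_group_data(seed=2)
        res = diffexpr.moderated_de(expr, design, rho=0.0, prior_df=0)
        X = design.to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        for g in expr.index:
            y = expr.loc[g].to_numpy()
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (len(y) - 2)
            t_oracle = beta[1] / np.sqrt(s2 * XtX_inv[1, 1])
            assert res.table.loc[g, "t"] == pytest.approx(t_oracle,
                                                          abs=1e-8)
            p_oracle = 2 * scipy.stats.t.sf(abs(t_oracle), len(y) - 2)
            assert res.table.loc[g, "p"] == pytest.approx(p_oracle,
                                                          abs=1e-10)

    def test_zero_prior_df_equals_unmoderated(self):
        expr, design = _two_group_data(seed=3)
        plain = diffexpr.moderated_de(expr, design, prior_df=0)
        assert np.allclose(plain.table["s2_post"], plain.table["s2"])

    def test_shrinkage_between_gene_and_prior_variance(self):
        expr, design = _two_group_data(seed=4, n_genes=100)
        res = diffexpr.moderated_de(expr, design)
        t = res.table
        lo = np.minimum(t["s2"], res.s02)
        hi = np.maximum(t["s2"], res.s02)
        assert ((t["s2_post"] >= lo - 1e-12)
                & (t["s2_post"] <= hi + 1e-12)).all()
        # |moderated t| lies between |raw t| and the prior-variance t
        se_unscaled = t["logFC"] / t["t"] / np.sqrt(t["s2_post"])
        t_raw = t["logFC"] / (se_unscaled * np.sqrt(t["s2"]))
        t_prior = t["logFC"] / (se_unscaled * np.sqrt(res.s02))
        lo_t = np.minimum(np.abs(t_raw), np.abs(t_prior))
        hi_t = np.maximum(np.abs(t_raw), np.abs(t_prior))
        assert ((np.abs(t["t"]) >= lo_t - 1e-9)
                & (np.abs(t["t"]) <= hi_t + 1e-9)).all()

    def test_constant_genes_flagged(self):
        expr, design = _two_group_data(seed=5)
        expr.iloc[0] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            res = diffexpr.moderated_de(expr, design, prior_df=0)
        assert not res.table["valid"].iloc[0]
        assert np.isnan(res.table["p"].iloc[0])

    def test_type_one_error_calibrated(self):
        """Null cohorts: raw p < 0.05 for roughly 5% of genes."""
        fracs = []
        for seed in range(10):
            expr, cohort, _ = _null_cohort(seed=100 + seed, n_pat=20,
                                           visits=2, n_genes=200)
            res = diffexpr.ModeratedLinearModel.from_cohort(
                expr, cohort).fit()
            fracs.append((res.table["p"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_planted_signature_recovery(self):
        """delta=1, sigma_e=0.5, 30 samples/arm: sensitivity >= 0.9 with
        no Bonferroni false positives."""
        hits = 0
        for seed in range(3):
            cfg = sim.BulkSimConfig(
                n_patients_per_arm=30, visits_per_patient=1, n_genes=500,
                effect_size=1.0, patient_sd=0.0, noise_sd=0.5,
                drugs=("MMF",), seed=200 + seed)
            expr, cohort, truth = sim.generate_bulk_cohort(cfg)
            res = diffexpr.ModeratedLinearModel.from_cohort(
                expr, cohort).fit()
            sig = res.signatures("MMF")
            up = set(truth.planted_up["MMF"])
            down = set(truth.planted_down["MMF"])
            found = len(set(sig.up) & up) + len(set(sig.down) & down)
            fp = len((set(sig.up) | set(sig.down)) - up - down)
            if found / (len(up) + len(down)) >= 0.9 and fp == 0:
                hits += 1
        assert hits >= 2


class TestSignatures:
    def test_bonferroni_arithmetic(self):
        table = pd.DataFrame({
            "gene": [f"g{i}" for i in range(100)],
            "logFC": np.ones(100),
            "p": [4e-4] + [0.5] * 99,
            "valid": True}).set_index("gene", drop=False)
        table["p_bonferroni"] = np.minimum(1.0, table["p"] * 100)
        sig = diffexpr.bonferroni_signatures(table, drug="X")
        assert sig.up == ["g0"]
        assert table.loc["g0", "p_bonferroni"] == pytest.approx(0.04)

    def test_boundary_is_strict(self):
        table = pd.DataFrame({
            "gene": ["g0", "g1"], "logFC": [1.0, -1.0],
            "p": [0.025, 0.5], "valid": True}).set_index("gene", drop=False)
        table["p_bonferroni"] = np.minimum(1.0, table["p"] * 2)
        sig = diffexpr.bonferroni_signatures(table, alpha=0.05)
        assert sig.up == [] and sig.down == []

    def test_all_null_gives_empty_valid_signature(self):
        table = pd.DataFrame({
            "gene": ["a", "b"], "logFC": [1.0, -1.0], "p": [1.0, 1.0],
            "p_bonferroni": [1.0, 1.0], "valid": True}
        ).set_index("gene", drop=False)
        sig = diffexpr.bonferroni_signatures(table)
        assert sig.up == [] and sig.down == []

    def test_overlapping_signature_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.SignatureSet("X", ["a"], ["a"])


class TestRatioScore:
    def test_arithmetic(self):
        expr = pd.DataFrame({"s1": [4.0, 6.0, 2.0, 3.0]},
                            index=["u1", "u2", "d1", "d2"])
        sig = diffexpr.SignatureSet("X", ["u1", "u2"], ["d1", "d2"])
        assert diffexpr.ratio_score(expr, sig)["s1"] == pytest.approx(2.0)

    def test_equal_means_give_one(self):
        sig = diffexpr.SignatureSet("X", ["a"], ["b"])
        s = diffexpr.ratio_score(
            pd.DataFrame({"s1": [5.0, 5.0]}, index=["a", "b"]), sig)
        assert s["s1"] == pytest.approx(1.0)

    def test_nonpositive_down_mean_instructs_offset(self):
        expr = pd.DataFrame({"s1": [4.0, -2.0]}, index=["u", "d"])
        sig = diffexpr.SignatureSet("X", ["u"], ["d"])
        with pytest.raises(ValueError, match="offset"):
            diffexpr.ratio_score(expr, sig)
        assert diffexpr.ratio_score(expr, sig, offset=4.0)["s1"] == \
            pytest.approx(8.0 / 2.0)

    def test_separates_arms_on_planted_cohort(self, bulk_small):
        _, expr, cohort, truth = bulk_small
        sig = diffexpr.SignatureSet("MMF", truth.planted_up["MMF"],
                                    truth.planted_down["MMF"])
        scores = diffexpr.ratio_score(expr, sig)
        resp = scores[(cohort["response"] == "responder").to_numpy()]
        nonresp = scores[(cohort["response"] == "non-responder").to_numpy()]
        assert wilcoxon_test(resp, nonresp) < 0.01


def gsea_oracle_es(is_hit):
    """Unweighted running-sum enrichment score by direct enumeration."""
    n, nh = len(is_hit), sum(is_hit)
    run, best = 0.0, 0.0
    for h in is_hit:
        run += 1.0 / nh if h else -1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    def test_top_set_scores_one(self):
        ranked = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        res = diffexpr.gsea_compare(ranked, ["g0", "g1", "g2"],
                                    weight_exponent=0, n_perm=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_bottom_set_scores_minus_one(self):
        ranked = pd.Series(np.arange(10, 0, -1, dtype=float),
                           index=[f"g{i}" for i in range(10)])
        res = diffexpr.gsea_compare(ranked, ["g7", "g8", "g9"],
                                    weight_exponent=0, n_perm=50, seed=0)
        assert res.es == pytest.approx(-1.0)

    def test_six_gene_toy_matches_oracle(self):
        ranked = pd.Series([3.0, 2.0, 1.5, 1.0, 0.5, 0.1],
                           index=list("abcdef"))
        res = diffexpr.gsea_compare(ranked, ["a", "d", "e"],
                                    weight_exponent=0, n_perm=50, seed=0)
        assert res.es == pytest.approx(
            gsea_oracle_es([1, 0, 0, 1, 1, 0]))

    def test_reflection_symmetry(self, rng):
        """ES of a set equals -ES of the set under a reversed ranking."""
        for _ in range(10):
            n = int(rng.integers(5, 12))
            w = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            hit = list(rng.choice(genes, k, replace=False))
            es = diffexpr.gsea_compare(
                pd.Series(w, index=genes), hit,
                weight_exponent=0, n_perm=10, seed=0).es
            es_rev = diffexpr.gsea_compare(
                pd.Series(w, index=genes[::-1]), hit,
                weight_exponent=0, n_perm=10, seed=0).es
            assert es == pytest.approx(-es_rev, abs=1e-12)

    def test_permutation_p_in_unit_interval(self):
        ranked = pd.Series(np.linspace(3, -3, 30),
                           index=[f"g{i}" for i in range(30)])
        res = diffexpr.gsea_compare(ranked, [f"g{i}" for i in range(5)],
                                    n_perm=200, seed=1)
        assert 0.0 < res.p <= 1.0
        assert abs(res.es) <= 1.0

    def test_degenerate_sets_rejected(self):
        ranked = pd.Series([2.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            diffexpr.gsea_compare(ranked, [])
        with pytest.raises(ValueError):
            diffexpr.gsea_compare(ranked, ["a", "b"])
        with pytest.raises(ValueError):
            diffexpr.gsea_compare(ranked, ["z"])
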