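"""Per-study estimators: closed-form oracles, cross-checks, calibration."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from targetmr import association as assoc
from targetmr import simulate as sim
from targetmr.types import (
    ConfigError,
    DegenerateDataError,
    SeparationError,
    VariantSpec,
)


class TestRecoding:
    def test_correct_orientation_unchanged(self):
        g = np.array([0, 1, 2, 1])
        coded, flipped = assoc.recode_to_ldl_lowering(g, VariantSpec("s", 0.3, -0.1))
        assert not flipped and np.array_equal(coded, g)

    def test_raising_allele_flipped(self):
        coded, flipped = assoc.recode_to_ldl_lowering(np.array([0, 1, 2]), +0.1)
        assert flipped and np.array_equal(coded, [2, 1, 0])

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ConfigError, match="dosage"):
            assoc.recode_to_ldl_lowering(np.array([0, 3.0]), -0.1)

    def test_flip_negates_beta_keeps_se(self, rng):
        g = rng.integers(0, 3, 500).astype(float)
        y = 0.3 * g + rng.normal(0, 1, 500)
        a = assoc.fit_linear_additive(g, y)
        b = assoc.fit_linear_additive(2 - g, y)
        assert a.beta == pytest.approx(-b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestLinearFit:
    def test_three_point_oracle(self):
        # hand-solved normal equations: g=(0,1,2), y=(0,1,3) -> slope 1.5
        est = assoc.fit_linear_additive(np.array([0, 1, 2]), np.array([0.0, 1.0, 3.0]))
        assert est.beta == pytest.approx(1.5, rel=1e-12)

    def test_noiseless_line_flags_zero_residual(self):
        g = np.array([0, 1, 2, 1, 0], dtype=float)
        est = assoc.fit_linear_additive(g, 2.0 * g)
        assert est.beta == pytest.approx(2.0, rel=1e-10)
        assert "zero_residual_variance" in est.flags

    def test_constant_dosage_rejected(self):
        with pytest.raises(DegenerateDataError, match="constant"):
            assoc.fit_linear_additive(np.ones(10), np.arange(10.0))

    def test_available_case_equals_manual_deletion(self, rng):
        g = rng.integers(0, 3, 300).astype(float)
        y = 0.2 * g + rng.normal(0, 1, 300)
        y[rng.random(300) < 0.2] = np.nan
        g[rng.random(300) < 0.1] = np.nan
        keep = np.isfinite(g) & np.isfinite(y)
        a = assoc.fit_linear_additive(g, y)
        b = assoc.fit_linear_additive(g[keep], y[keep])
        assert (a.beta, a.se, a.n) == (b.beta, b.se, b.n)

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm

        g = rng.integers(0, 3, 150).astype(float)
        y = 0.4 * g + rng.normal(0, 1.3, 150)
        est = assoc.fit_linear_additive(g, y)
        ref = sm.OLS(y, sm.add_constant(g)).fit()
        assert est.beta == pytest.approx(ref.params[1], rel=1e-9)
        assert est.se == pytest.approx(ref.bse[1], rel=1e-9)


class TestLogisticFit:
    def test_two_by_two_collapse_equals_odds_ratio(self):
        # saturated fit on a 2x2 table: beta = ln((20*90)/(80*10)) = ln 2.25
        g = np.repeat([0.0, 1.0], 100)
        y = np.concatenate([np.ones(10), np.zeros(90), np.ones(20), np.zeros(80)])
        est = assoc.fit_logistic_additive(g, y)
        assert est.beta == pytest.approx(math.log(2.25), rel=1e-8)

    def test_flip_negates_beta(self):
        g = np.repeat([0.0, 1.0, 2.0], 80)
        rng = np.random.default_rng(4)
        y = (rng.random(240) < 1 / (1 + np.exp(-(-1 + 0.4 * g)))).astype(float)
        a = assoc.fit_logistic_additive(g, y)
        b = assoc.fit_logistic_additive(2 - g, y)
        assert a.beta == pytest.approx(-b.beta, rel=1e-7)

    def test_null_association(self, rng):
        g = rng.integers(0, 3, 20_000).astype(float)
        y = (rng.random(20_000) < 0.1).astype(float)
        est = assoc.fit_logistic_additive(g, y)
        assert abs(est.beta) < 3 * est.se

    def test_separation_detected(self):
        g = np.repeat([0.0, 1.0, 2.0], 20)
        y = (g > 0.5).astype(float)
        with pytest.raises(SeparationError):
            assoc.fit_logistic_additive(g, y)

    def test_sparse_cell_flagged(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.02, 400).astype(float)
        y = (rng.random(400) < 0.3).astype(float)
        if np.ptp(g) > 0 and len(np.unique(y)) == 2:
            est = assoc.fit_logistic_additive(g, y)
            assert "sparse_cells" in est.flags

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm

        g = rng.integers(0, 3, 200).astype(float)
        y = (rng.random(200) < 1 / (1 + np.exp(-(-1.0 + 0.5 * g)))).astype(float)
        est = assoc.fit_logistic_additive(g, y)
        ref = sm.Logit(y, sm.add_constant(g)).fit(disp=0)
        assert est.beta == pytest.approx(ref.params[1], rel=1e-7)
        assert est.se == pytest.approx(ref.bse[1], rel=1e-7)

    def test_agrees_with_brute_force_optimiser(self, rng):
        # independent oracle: Nelder-Mead on the negative log-likelihood
        g = rng.integers(0, 3, 180).astype(float)
        y = (rng.random(180) < 1 / (1 + np.exp(-(-0.8 + 0.4 * g)))).astype(float)

        def nll(par):
            eta = par[0] + par[1] * g
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        ref = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12}).x
        est = assoc.fit_logistic_additive(g, y)
        assert est.beta == pytest.approx(ref[1], rel=1e-6)


class TestHWE:
    def test_exact_proportions_give_zero(self):
        res = assoc.hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_heterozygote_deficit_oracle(self):
        # (30,40,30) vs expected (25,50,25): chi2 = 4, p ~ 0.0455
        res = assoc.hwe_test((30, 40, 30))
        assert res.chi2 == pytest.approx(4.0, rel=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)

    def test_monomorphic_skipped_with_reason(self):
        with pytest.raises(DegenerateDataError, match="monomorphic"):
            assoc.hwe_test((100, 0, 0))


class TestAdditivityLRT:
    def test_stat_nonnegative_and_null_calibrated(self, rng):
        ps = []
        for _ in range(200):
            g = rng.integers(0, 3, 300).astype(float)
            y = 0.2 * g + rng.normal(0, 1, 300)
            res = assoc.additivity_lrt(g, y, "gaussian")
            assert res.stat >= 0 and res.df == 1
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_dominant_effect_detected(self, rng):
        g = rng.integers(0, 3, 20_000).astype(float)
        y = 0.5 * (g > 0) + rng.normal(0, 1, 20_000)  # pure dominance
        res = assoc.additivity_lrt(g, y, "gaussian")
        assert res.p < 0.001

    def test_missing_genotype_class_skipped(self):
        g = np.repeat([0.0, 1.0], 50)
        with pytest.raises(DegenerateDataError, match="class 2"):
            assoc.additivity_lrt(g, np.random.default_rng(0).normal(size=100), "gaussian")


class TestMultivariable:
    def test_orthogonal_predictors_match_univariable(self, rng):
        variants = [VariantSpec("a", 0.3, -0.2), VariantSpec("b", 0.4, -0.1)]
        G = sim.sample_genotypes(variants, np.eye(2), 20_000, 0.0, rng).astype(float)
        y = 0.2 * G[:, 0] + 0.1 * G[:, 1] + rng.normal(0, 1, 20_000)
        multi = assoc.fit_multivariable(G, y, "gaussian", snp_ids=["a", "b"])
        for j, sid in enumerate(["a", "b"]):
            uni = assoc.fit_linear_additive(G[:, j], y)
            assert multi[j].beta == pytest.approx(uni.beta, abs=3 * uni.se)
            assert multi[j].model == "multivariable"

    def test_duplicated_snp_raises_rank_error(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        G = np.column_stack([g, g])
        with pytest.raises(DegenerateDataError, match="collinear"):
            assoc.fit_multivariable(G, rng.normal(size=100), "gaussian",
                                    snp_ids=["a", "a_dup"])


class TestPairwiseR2:
    def test_self_correlation_is_one(self, rng):
        g = rng.integers(0, 3, (500, 2)).astype(float)
        r2 = assoc.pairwise_r2(g)
        assert r2[0, 0] == 1.0 and r2[1, 1] == 1.0

    def test_independent_columns_near_zero(self, rng):
        g = rng.integers(0, 3, (50_000, 2)).astype(float)
        assert assoc.pairwise_r2(g)[0, 1] < 0.005

    def test_constant_column_undefined_not_zero(self, rng):
        g = np.column_stack([np.ones(100), rng.integers(0, 3, 100)])
        r2 = assoc.pairwise_r2(g)
        assert np.isnan(r2[0, 1]) and np.isnan(r2[0, 0])


class TestEstimatorConsistency:
    """Empirical SD of beta over replicates matches the reported se."""

    def test_linear_family(self, rng):
        betas, ses = [], []
        for _ in range(500):
            g = rng.binomial(2, 0.3, 1000).astype(float)
            y = 0.1 * g + rng.normal(0, 1, 1000)
            est = assoc.fit_linear_additive(g, y)
            betas.append(est.beta)
            ses.append(est.se)
        assert np.std(betas) == pytest.approx(np.mean(ses), rel=0.10)

    def test_logistic_family(self, rng):
        betas, ses = [], []
        for _ in range(500):
            g = rng.binomial(2, 0.3, 1000).astype(float)
            p = 1 / (1 + np.exp(-(-2.0 + 0.2 * g)))
            y = (rng.random(1000) < p).astype(float)
            est = assoc.fit_logistic_additive(g, y)
            betas.append(est.beta)
            ses.append(est.se)
        assert np.std(betas) == pytest.approx(np.mean(ses), rel=0.10)
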