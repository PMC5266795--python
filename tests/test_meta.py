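"""Meta-analysis layer: worked oracles, boundary cases, pooling algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from targetmr import meta
from targetmr.types import (
    AssociationEstimate,
    ConfigError,
    HWEResult,
    SummaryStatRecord,
)


def est(beta, se, study="s", snp="snp", trait="t"):
    return AssociationEstimate(study, snp, trait, beta, se, 100)


class TestIVWFixed:
    def test_worked_example(self):
        # w = (400, 100): beta = 0.12, se = 1/sqrt(500)
        p = meta.ivw_fixed([(0.10, 0.05), (0.20, 0.10)])
        assert p.beta == pytest.approx(0.12, rel=1e-12)
        assert p.se == pytest.approx(0.04472136, rel=1e-6)
        assert p.ci_low == pytest.approx(0.12 - 1.959964 * p.se, rel=1e-9)

    def test_single_estimate_identity(self):
        p = meta.ivw_fixed([(0.3, 0.07)])
        assert (p.beta, p.se, p.k) == (0.3, 0.07, 1)
        assert p.Q is None and p.I2 is None

    def test_pooled_se_not_larger_than_smallest_input(self):
        p = meta.ivw_fixed([(0.1, 0.05), (0.2, 0.08), (0.0, 0.2)])
        assert p.se <= 0.05

    def test_invalid_se_rejected_but_pooling_continues(self):
        p = meta.ivw_fixed([(0.1, 0.05), (0.2, -1.0)])
        assert p.k == 1
        with pytest.raises(ConfigError):
            meta.ivw_fixed([(0.2, -1.0)])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.01, 3)),
                    min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, estimates, rnd):
        a = meta.ivw_fixed(estimates)
        shuffled = list(estimates)
        rnd.shuffle(shuffled)
        b = meta.ivw_fixed(shuffled)
        assert a.beta == pytest.approx(b.beta, rel=1e-9, abs=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.01, 3)),
                    min_size=2, max_size=10),
           st.integers(1, 9))
    def test_split_pool_associativity(self, estimates, cut):
        # fixed-effect pooling of sub-pool results equals one-shot pooling
        cut = min(cut, len(estimates) - 1)
        direct = meta.ivw_fixed(estimates)
        a = meta.ivw_fixed(estimates[:cut])
        b = meta.ivw_fixed(estimates[cut:])
        merged = meta.ivw_fixed([(a.beta, a.se), (b.beta, b.se)])
        assert merged.beta == pytest.approx(direct.beta, rel=1e-9, abs=1e-12)
        assert merged.se == pytest.approx(direct.se, rel=1e-9)


class TestHeterogeneity:
    def test_q_worked_example(self):
        Q, p = meta.cochran_q([(0.10, 0.05), (0.20, 0.10)])
        assert Q == pytest.approx(0.8, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(0.8, 1), rel=1e-12)

    def test_identical_estimates_homogeneous(self):
        Q, p = meta.cochran_q([(0.1, 0.05)] * 4)
        assert Q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_i2_direct_substitution(self):
        I2, upper = meta.i_squared(4.0, 2)
        assert I2 == pytest.approx(75.0, rel=1e-12)
        assert upper is not None and upper >= I2

    def test_i2_zero_floor(self):
        I2, _ = meta.i_squared(0.5, 5)
        assert I2 == 0.0

    def test_i2_upper_undefined_k2_small_q(self):
        I2, upper = meta.i_squared(1.0, 2)
        assert upper is None

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 200.0), st.integers(2, 30))
    def test_upper_bound_ordering(self, Q, k):
        I2, upper = meta.i_squared(Q, k)
        assert 0 <= I2 < 100
        if upper is not None:
            assert upper >= I2 - 1e-9


class TestRandomEffects:
    def test_dl_worked_example(self):
        # betas (0,1), ses (0.1,0.1): Q=50, C=100, tau2=0.49, se=0.5
        p = meta.dl_random([(0.0, 0.1), (1.0, 0.1)])
        assert p.tau2 == pytest.approx(0.49, rel=1e-12)
        assert p.beta == pytest.approx(0.5, rel=1e-12)
        assert p.se == pytest.approx(0.5, rel=1e-12)

    def test_homogeneous_reduces_to_fixed(self):
        ests = [(0.10, 0.05), (0.11, 0.06), (0.09, 0.05)]
        f, r = meta.ivw_fixed(ests), meta.dl_random(ests)
        if r.Q <= r.k - 1:
            assert r.beta == pytest.approx(f.beta, rel=1e-12)
            assert r.se == pytest.approx(f.se, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-3, 3), st.floats(0.05, 2)),
                    min_size=2, max_size=10))
    def test_random_se_never_below_fixed(self, estimates):
        f = meta.ivw_fixed(estimates)
        r = meta.dl_random(estimates)
        assert r.se >= f.se - 1e-12
        assert r.tau2 >= 0


class TestFisher:
    def test_worked_example(self):
        X, df, p = meta.fisher_combine([0.01, 0.04])
        assert X == pytest.approx(15.6481, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(stats.chi2.sf(X, 4), rel=1e-12)
        assert p == pytest.approx(0.0035, abs=5e-4)

    def test_no_evidence(self):
        X, df, p = meta.fisher_combine([1.0, 1.0, 1.0])
        assert X == 0.0 and p == pytest.approx(1.0)

    def test_single_p_identity(self):
        _, _, p = meta.fisher_combine([0.2])
        assert p == pytest.approx(0.2, rel=1e-9)

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            X, _, p = meta.fisher_combine([0.0, 0.5])
        assert np.isfinite(X) and 0 <= p <= 1


class FixtureStudies:
    """Five-study fixture with one consortium source subsuming S1, S2."""

    def build(self):
        studies = [est(0.1 + 0.01 * i, 0.1, study=f"S{i}") for i in range(5)]
        consort = [SummaryStatRecord("GLGC", "snp", "t", "minor", 0.12, 0.03, 10_000)]
        return studies, consort


class TestMergeSources(FixtureStudies):
    def test_no_overlap_pools_everything(self):
        studies, consort = self.build()
        merged, log = meta.merge_sources(studies, consort, {})
        assert len(merged[("snp", "t")]) == 6 and not log

    def test_subsumed_studies_dropped(self):
        studies, consort = self.build()
        merged, log = meta.merge_sources(studies, consort, {"GLGC": {"S1", "S2"}})
        assert len(merged[("snp", "t")]) == (5 - 2) + 1
        assert {e["study_id"] for e in log} == {"S1", "S2"}

    def test_exclusion_map_ignored_when_source_absent(self):
        studies, _ = self.build()
        merged, log = meta.merge_sources(studies, [], {"GLGC": {"S1"}})
        assert len(merged[("snp", "t")]) == 5 and not log

    def test_ambiguous_provenance_rejected(self):
        studies, consort = self.build()
        consort.append(SummaryStatRecord("MAGIC", "snp", "t", "minor", 0.1, 0.05, 500))
        with pytest.raises(ConfigError, match="ambiguous"):
            meta.merge_sources(studies, consort,
                               {"GLGC": {"S1"}, "MAGIC": {"S1"}})

    def test_removing_mean_study_preserves_beta_increases_se(self):
        studies, _ = self.build()
        pooled_all = meta.ivw_fixed(studies)
        at_mean = est(pooled_all.beta, 0.1, study="S9")
        with_extra = meta.ivw_fixed(studies + [at_mean])
        assert with_extra.beta == pytest.approx(pooled_all.beta, rel=1e-9)
        assert pooled_all.se > with_extra.se


class TestHWEFilter:
    def _hwe(self, study, snp, p):
        return HWEResult(study, snp, (10, 20, 10), 1.0, p)

    def test_all_in_hwe_noop(self):
        ests = [est(0.1, 0.1, study=f"S{i}") for i in range(3)]
        hwe = [self._hwe(f"S{i}", "snp", 0.5) for i in range(3)]
        kept, log = meta.hwe_filter(ests, hwe, 1e-6)
        assert kept == ests and not log

    def test_violating_pair_removed_for_all_traits(self):
        ests = [est(0.1, 0.1, study="S0", trait="ldl"),
                est(0.2, 0.1, study="S0", trait="glucose"),
                est(0.1, 0.1, study="S1", trait="ldl")]
        hwe = [self._hwe("S0", "snp", 1e-9), self._hwe("S1", "snp", 0.4)]
        kept, log = meta.hwe_filter(ests, hwe, 1e-6)
        assert [e.study_id for e in kept] == ["S1"]
        assert len(log) == 2 and all(l["rule"].startswith("hwe_p<") for l in log)

    def test_strict_mode_errors_on_missing_result(self):
        with pytest.raises(ConfigError, match="no HWE result"):
            meta.hwe_filter([est(0.1, 0.1)], [], 1e-6, strict=True)
        kept, log = meta.hwe_filter([est(0.1, 0.1)], [], 1e-6, strict=False)
        assert len(kept) == 1 and log[0]["rule"] == "hwe_missing_kept"

    def test_threshold_one_excludes_everything_with_warning(self):
        ests = [est(0.1, 0.1, study="S0")]
        hwe = [self._hwe("S0", "snp", 0.5)]
        with pytest.warns(RuntimeWarning):
            kept, log = meta.hwe_filter(ests, hwe, 1.0)
        assert not kept and len(log) == 1

    def test_inbred_study_excluded_end_to_end(self, rng):
        # F = 0.2 at n = 5000: heterozygote deficit far beyond the threshold
        from targetmr import simulate as sim
        from targetmr.association import hwe_test
        from targetmr.types import VariantSpec

        v = [VariantSpec("s", 0.3, -0.1)]
        g = sim.sample_genotypes(v, np.eye(1), 5000, 0.2, rng)
        counts = np.bincount(g[:, 0], minlength=3)
        res = hwe_test(counts, "S_bad", "s")
        kept, log = meta.hwe_filter([est(0.1, 0.1, study="S_bad", snp="s")],
                                    [res], 1e-6)
        assert not kept and log[0]["study_id"] == "S_bad"
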