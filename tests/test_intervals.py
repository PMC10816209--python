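"""Confidence-interval arithmetic and the union-CI construction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sumherit import (Interval, SEResult, bootstrap_bias, build_ci_suite,
                      normal_ci, percentile_ci, union_ci)


class TestNormalCI:
    def test_level_95_multiplier(self):
        iv = normal_ci(0.2, 0.05, 0.95)
        assert iv.lower == pytest.approx(0.10200, abs=5e-6)
        assert iv.upper == pytest.approx(0.29800, abs=5e-6)

    def test_zero_se_degenerate(self):
        iv = normal_ci(0.3, 0.0)
        assert iv.lower == iv.upper == 0.3

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            normal_ci(0.1, -0.01)

    def test_empirical_coverage(self):
        # known sampling SD 0.1: the 95% normal CI should cover ~95% of draws
        rng = np.random.default_rng(314)
        mu, se, trials = 0.5, 0.1, 10_000
        xbar = rng.normal(mu, se, trials)
        z = 1.959963984540054
        covered = np.mean((xbar - z * se <= mu) & (mu <= xbar + z * se))
        assert 0.94 <= covered <= 0.96


class TestBootstrapBias:
    def test_direct_arithmetic(self):
        bias, corrected = bootstrap_bias(0.20, [0.25, 0.25])
        assert bias == pytest.approx(0.05)
        assert corrected == pytest.approx(0.15)

    def test_zero_bias_identity(self):
        bias, corrected = bootstrap_bias(0.10, [0.08, 0.12])
        assert bias == pytest.approx(0.0, abs=1e-15)
        assert corrected == pytest.approx(0.10)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            bootstrap_bias(0.1, [0.1])


class TestPercentileCI:
    def _reps(self):
        # 201 evenly spaced replicates: quantiles are exact order statistics
        return np.linspace(0.1, 0.35, 201)

    def test_uncorrected_reads_quantiles(self):
        iv = percentile_ci(0.2, self._reps(), bias_correct=False)
        assert iv.lower == pytest.approx(np.quantile(self._reps(), 0.025))
        assert iv.upper == pytest.approx(np.quantile(self._reps(), 0.975))

    def test_corrected_is_reflection(self):
        reps = self._reps()
        est = 0.2
        unc = percentile_ci(est, reps, bias_correct=False)
        cor = percentile_ci(est, reps, bias_correct=True)
        assert cor.lower + unc.upper == pytest.approx(2 * est, abs=1e-12)
        assert cor.upper + unc.lower == pytest.approx(2 * est, abs=1e-12)

    def test_formula_example(self):
        # replicates built so that q_{0.025}=0.1 and q_{0.975}=0.35 exactly;
        # reflection about estimate 0.2 gives (0.05, 0.30)
        width = 0.25 / 0.95
        reps = np.linspace(0.1 - width * 0.025, 0.35 + width * 0.025, 201)
        iv = percentile_ci(0.2, reps, bias_correct=True)
        assert iv.lower == pytest.approx(0.05, abs=1e-12)
        assert iv.upper == pytest.approx(0.30, abs=1e-12)

    def test_symmetric_replicates_corrected_equals_uncorrected(self):
        reps = 0.2 + np.concatenate([-np.linspace(0, 0.1, 100),
                                     np.linspace(0, 0.1, 100)])
        unc = percentile_ci(0.2, reps, bias_correct=False)
        cor = percentile_ci(0.2, reps, bias_correct=True)
        assert cor.lower == pytest.approx(unc.lower, abs=1e-9)
        assert cor.upper == pytest.approx(unc.upper, abs=1e-9)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            percentile_ci(0.2, np.linspace(0, 1, 39))


class TestUnionCI:
    def test_min_lower_max_upper(self):
        u = union_ci([Interval(0.1, 0.3), Interval(0.05, 0.25)])
        assert (u.lower, u.upper) == (0.05, 0.30)

    def test_single_member_identity(self):
        iv = Interval(0.07, 0.4)
        u = union_ci([iv])
        assert (u.lower, u.upper) == (iv.lower, iv.upper)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            union_ci([])

    @given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0, 1)),
                    min_size=1, max_size=8))
    def test_contains_every_member(self, bounds):
        members = [Interval(lo, lo + w) for lo, w in bounds]
        u = union_ci(members)
        for m in members:
            assert u.lower <= m.lower and u.upper >= m.upper


class TestSuite:
    def _se_results(self, reps_by_method=None):
        rng = np.random.default_rng(0)
        out = {"jack_del_d": SEResult("jack_del_d", 0.02,
                                      rng.normal(0.2, 0.02, 200), 200, 0, d=40)}
        for name in ("paraboot", "fdrboot1", "fdrboot2"):
            reps = (reps_by_method[name] if reps_by_method
                    else rng.normal(0.2, 0.015, 200))
            out[name] = SEResult(name, float(np.std(reps, ddof=1)), reps, 200, 0)
        return out

    def test_suite_sizes(self):
        suite = build_ci_suite(0.2, self._se_results())
        assert len(suite.standard) == 4
        assert len(suite.percentile) == 6
        assert suite.bias_estimates.size == 3

    def test_missing_method_named_in_error(self):
        partial = self._se_results()
        del partial["fdrboot2"]
        with pytest.raises(ValueError, match="fdrboot2"):
            build_ci_suite(0.2, partial)

    def test_unions_nest(self):
        suite = build_ci_suite(0.2, self._se_results())
        for member in suite.standard:
            assert suite.union_standard.lower <= member.lower
            assert suite.union_standard.upper >= member.upper
        for member in suite.percentile:
            assert suite.union_percentile.lower <= member.lower
            assert suite.union_percentile.upper >= member.upper
        assert suite.union_all.lower == min(suite.union_standard.lower,
                                            suite.union_percentile.lower)
        assert suite.union_all.upper == max(suite.union_standard.upper,
                                            suite.union_percentile.upper)

    def test_zero_bias_collapses_standard_union(self):
        est = 0.2
        sym = est + np.concatenate([-np.linspace(0, 0.05, 100),
                                    np.linspace(0, 0.05, 100)])
        reps = {m: sym for m in ("paraboot", "fdrboot1", "fdrboot2")}
        suite = build_ci_suite(est, self._se_results(reps))
        base = suite.standard[0]
        assert suite.union_standard.lower == pytest.approx(base.lower, abs=1e-12)
        assert suite.union_standard.upper == pytest.approx(base.upper, abs=1e-12)

    def test_clip_limits_bounds(self):
        results = self._se_results()
        results["jack_del_d"].se = 0.5  # force a negative lower bound
        suite = build_ci_suite(0.2, results, clip=True)
        assert suite.union_all.lower >= 0.0
        assert suite.union_all.upper <= 1.0
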