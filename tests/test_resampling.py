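"""Resampling SE estimators against closed-form and enumeration oracles."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import kstest

from sumherit import (CorrectionConfig, ZPanel, jackknife_delete1,
                      jackknife_delete_d, make_estimator, parametric_bootstrap,
                      run_correction)
from sumherit.correction import CorrectionResult
from sumherit.resampling import estimate_se


def mean_estimator(panel: ZPanel) -> float:
    return float(panel.z.mean())


def panel_of(values) -> ZPanel:
    return ZPanel(z=np.asarray(values, dtype=float), n=1000)


class TestDelete1:
    def test_jackknife_of_mean_is_sd_over_sqrt_n(self):
        data = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = jackknife_delete1(panel_of(data), mean_estimator)
        expected = np.std(data, ddof=1) / np.sqrt(5)
        assert r.se == pytest.approx(expected, abs=1e-10)
        assert r.se == pytest.approx(0.70711, abs=5e-6)

    def test_constant_data_zero_se(self):
        r = jackknife_delete1(panel_of(np.full(8, 3.3)), mean_estimator)
        assert r.se == 0.0

    def test_full_subsample_equals_exact(self):
        data = np.arange(6.0)
        exact = jackknife_delete1(panel_of(data), mean_estimator, m=6)
        default = jackknife_delete1(panel_of(data), mean_estimator)
        assert np.array_equal(exact.replicates, default.replicates)
        assert exact.se == default.se

    def test_subsampled_plugin_close_to_exact(self, rng):
        data = rng.normal(0, 1, 400)
        exact = jackknife_delete1(panel_of(data), mean_estimator)
        sub = jackknife_delete1(panel_of(data), mean_estimator, m=200, seed=1)
        assert sub.se == pytest.approx(exact.se, rel=0.25)

    def test_m_exceeding_k_rejected(self):
        with pytest.raises(ValueError):
            jackknife_delete1(panel_of([1.0, 2.0]), mean_estimator, m=3)


class TestDeleteD:
    def test_enumeration_oracle_k4_d2(self):
        data = np.array([1.0, 2.0, 3.0, 4.0])
        r = jackknife_delete_d(panel_of(data), mean_estimator, d=2, exhaustive=True)
        # all C(4,2)=6 retained-pair means: mean 2.5, sum sq dev 2.5
        assert r.se == pytest.approx(np.sqrt(2 / (2 * 6) * 2.5), abs=1e-12)
        assert r.se == pytest.approx(0.64550, abs=5e-6)

    @pytest.mark.parametrize("k,d", [(5, 2), (6, 3), (8, 2)])
    def test_enumeration_matches_independent_oracle(self, k, d, rng):
        data = rng.normal(0, 1, k)
        r = jackknife_delete_d(panel_of(data), mean_estimator, d=d, exhaustive=True)
        means = np.array([np.mean(np.delete(data, list(c)))
                          for c in combinations(range(k), d)])
        oracle = np.sqrt((k - d) / (d * means.size)
                         * np.sum((means - means.mean()) ** 2))
        assert r.se == pytest.approx(oracle, abs=1e-10)

    def test_constant_data_zero_se(self):
        r = jackknife_delete_d(panel_of(np.full(10, 1.0)), mean_estimator,
                               d=2, m=20)
        assert r.se == 0.0

    def test_seed_determinism(self):
        data = np.arange(30.0)
        a = jackknife_delete_d(panel_of(data), mean_estimator, d=6, m=25, seed=9)
        b = jackknife_delete_d(panel_of(data), mean_estimator, d=6, m=25, seed=9)
        assert np.array_equal(a.replicates, b.replicates) and a.se == b.se

    def test_default_d_is_k_over_5(self):
        r = jackknife_delete_d(panel_of(np.arange(50.0)), mean_estimator, m=5)
        assert r.d == 10

    def test_d_out_of_range(self):
        with pytest.raises(ValueError):
            jackknife_delete_d(panel_of([1.0, 2.0]), mean_estimator, d=2)


class TestParametricBootstrap:
    def _correction(self, delta, fdr):
        delta = np.asarray(delta, float)
        fdr = np.asarray(fdr, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            h1 = np.where(fdr < 1, delta / (1 - fdr), np.nan)
        return CorrectionResult(delta_hat=delta, fdr=fdr, delta_hat_h1=h1)

    def test_mean_estimator_sampling_distribution(self, rng):
        # replicate means are N(mean(delta), 1/k): se ~ 1/sqrt(k) = 0.1
        k = 100
        delta = rng.normal(0, 1, k)
        panel = ZPanel(z=delta, n=1000)
        corr = self._correction(delta, np.zeros(k))
        r = parametric_bootstrap(panel, corr, mean_estimator, "paraboot",
                                 B=2000, seed=3)
        assert r.se == pytest.approx(0.1, rel=0.15)

    def test_fdrboot1_all_null_is_standard_normal(self):
        k, B = 500, 40
        panel = ZPanel(z=np.linspace(-5, 5, k), n=1000)
        corr = self._correction(np.linspace(-5, 5, k), np.ones(k))
        pooled = []
        grab = lambda p: (pooled.append(p.z), float(p.z.mean()))[1]
        parametric_bootstrap(panel, corr, grab, "fdrboot1", B=B, seed=4)
        stat = kstest(np.concatenate(pooled), "norm")
        assert stat.pvalue > 0.01  # observed z forgotten entirely when fdr = 1

    def test_fdrboot2_collapses_to_paraboot_at_zero_fdr(self, rng):
        k = 300
        delta = rng.normal(0, 1.5, k)
        panel = ZPanel(z=delta, n=1000)
        corr = self._correction(delta, np.zeros(k))
        a = parametric_bootstrap(panel, corr, mean_estimator, "paraboot",
                                 B=15, seed=11)
        b = parametric_bootstrap(panel, corr, mean_estimator, "fdrboot2",
                                 B=15, seed=11)
        assert np.array_equal(a.replicates, b.replicates)

    def test_seed_determinism_and_nonnegative_se(self, rng):
        k = 200
        delta = rng.normal(0, 1, k)
        panel = ZPanel(z=delta, n=1000)
        corr = self._correction(delta, np.full(k, 0.3))
        for variant in ("paraboot", "fdrboot1", "fdrboot2"):
            a = parametric_bootstrap(panel, corr, mean_estimator, variant,
                                     B=25, seed=7)
            b = parametric_bootstrap(panel, corr, mean_estimator, variant,
                                     B=25, seed=7)
            assert np.array_equal(a.replicates, b.replicates)
            assert a.se >= 0.0

    def test_bad_inputs(self, rng):
        panel = ZPanel(z=rng.normal(size=10), n=1000)
        corr = self._correction(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            parametric_bootstrap(panel, corr, mean_estimator, "notamethod", B=5)
        with pytest.raises(ValueError):
            parametric_bootstrap(panel, corr, mean_estimator, "paraboot", B=1)


class TestSEResultContract:
    def test_recompute_matches_stored_se(self, rng):
        data = rng.normal(0, 1, 60)
        p = panel_of(data)
        r1 = jackknife_delete1(p, mean_estimator, m=30, seed=2)
        assert r1.recompute_se(k=60) == pytest.approx(r1.se, abs=1e-12)
        rd = jackknife_delete_d(p, mean_estimator, d=12, m=30, seed=2)
        assert rd.recompute_se(k=60) == pytest.approx(rd.se, abs=1e-12)

    def test_dispatch_by_name_full_pipeline(self, small_panel, binned_config):
        est = make_estimator(binned_config)
        corr = run_correction(small_panel, binned_config)
        r = estimate_se(small_panel, "paraboot", estimator=est,
                        correction=corr, reps=10, seed=1)
        assert r.method == "paraboot" and r.replicates.size == 10
        assert r.se >= 0.0
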