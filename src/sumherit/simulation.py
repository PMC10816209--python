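"""Synthetic GWAS panels and the full simulation study.

The generator emulates a quantitative-trait GWAS over k independent
(LD-pruned) SNPs of which a fraction p_nonnull carry signal.  Per-SNP
variance explained for the non-null SNPs is drawn from a gamma
distribution and rescaled so the panel's true total heritability hits the
target exactly; each variance is converted to a standardised effect
delta = sqrt(vg * (n-2)/(1-vg)) with a random sign, and observed
statistics are z ~ N(delta, 1) (null SNPs: delta = 0).

Study drivers:

* :func:`run_point_estimation` -- the "true" sampling distribution of the
  estimator: mean estimate and empirical SD over n_outer replicates;
* :func:`run_se_study` -- bias / variance / RMSE of each resampling SE
  against that true SD (population-variance convention, so
  rmse^2 = bias^2 + variance holds exactly);
* :func:`run_coverage_study` -- empirical coverage of the union CIs.

All randomness flows from the scenario seed through named SeedSequence
substreams, so every report is reproducible and independent of execution
order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .correction import CorrectionConfig, run_correction
from .heritability import delta_from_vg, total_vg
from .intervals import build_ci_suite
from .io import ZPanel
from .resampling import (BOOTSTRAP_VARIANTS, METHODS, jackknife_delete1,
                         jackknife_delete_d, make_estimator,
                         parametric_bootstrap)

logger = logging.getLogger(__name__)

CI_SCHEMES = ("standard", "percentile", "standard+percentile")


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design."""

    vg_target: float
    n: int
    k: int = 100_000
    p_nonnull: float = 0.005
    gamma_shape: float = 0.5
    n_outer: int = 100
    resample_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.vg_target < 1.0):
            raise ValueError("vg_target must lie in (0, 1)")
        if round(self.k * self.p_nonnull) < 1:
            raise ValueError("scenario has no non-null SNPs")


@dataclass
class MethodStats:
    mean_se: float
    bias: float
    variance: float
    rmse: float


@dataclass
class SimulationReport:
    scenario: SimulationScenario
    mean_est: float
    true_se: float
    per_method: dict[str, MethodStats] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)


def simulate_panel(scenario: SimulationScenario, rep_seed) -> tuple[ZPanel, np.ndarray, float]:
    """Draw one synthetic z-panel; returns (panel, true_delta, true_vg).

    ``rep_seed`` may be an int or a SeedSequence; identical inputs yield
    identical panels.
    """
    rng = np.random.default_rng(rep_seed)
    k, n = scenario.k, scenario.n
    n_nonnull = int(round(k * scenario.p_nonnull))
    for attempt in range(100):
        raw = rng.gamma(scenario.gamma_shape, 1.0, size=n_nonnull)
        vg_i = raw / raw.sum() * scenario.vg_target
        if np.all(vg_i < 1.0):
            break
        logger.info("simulate_panel: rescaled per-SNP Vg >= 1, redrawing")
    else:
        raise RuntimeError("could not draw per-SNP variances below 1")
    signs = rng.choice([-1.0, 1.0], size=n_nonnull)
    delta = np.zeros(k)
    delta[:n_nonnull] = signs * delta_from_vg(vg_i, n)
    z = delta + rng.standard_normal(k)
    panel = ZPanel(z=z, n=n, trait_type="continuous")
    return panel, delta, scenario.vg_target


def _outer_streams(scenario: SimulationScenario, purpose: str, n_outer: int):
    # crc32 is stable across processes (str hash() is salted per run)
    tag = zlib.crc32(purpose.encode()) % 2**31
    root = np.random.SeedSequence(entropy=scenario.seed, spawn_key=(tag,))
    return root.spawn(n_outer)


@dataclass
class PointEstimation:
    mean_est: float
    true_se: float
    estimates: np.ndarray

    def __iter__(self):
        return iter((self.mean_est, self.true_se))


def run_point_estimation(scenario: SimulationScenario,
                         n_outer: int | None = None,
                         config: CorrectionConfig | None = None) -> PointEstimation:
    """Mean estimate and empirical ("true") SE over outer replicates."""
    n_outer = scenario.n_outer if n_outer is None else int(n_outer)
    if n_outer < 2:
        raise ValueError("need at least 2 outer replicates")
    estimator = make_estimator(config)
    streams = _outer_streams(scenario, "point", n_outer)
    ests = np.empty(n_outer)
    for i in range(n_outer):
        panel, _, _ = simulate_panel(scenario, streams[i])
        ests[i] = estimator(panel)
    return PointEstimation(mean_est=float(ests.mean()),
                           true_se=float(ests.std(ddof=1)), estimates=ests)


def run_se_study(scenario: SimulationScenario, methods=METHODS,
                 n_outer: int | None = None, true_se: float | None = None,
                 config: CorrectionConfig | None = None,
                 point_outer: int | None = None) -> SimulationReport:
    """Bias / variance / RMSE of the resampling SE estimators.

    ``true_se`` defaults to the empirical SD from
    :func:`run_point_estimation` (over ``point_outer`` or the scenario's
    n_outer replicates).  Variance uses the population convention so that
    rmse^2 = bias^2 + variance is an identity.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    n_outer = scenario.n_outer if n_outer is None else int(n_outer)
    config = config or CorrectionConfig()
    point = None
    if true_se is None:
        point = run_point_estimation(scenario, point_outer, config)
        true_se = point.true_se
    estimator = make_estimator(config)
    streams = _outer_streams(scenario, "se_study", n_outer)
    ses: dict[str, list[float]] = {m: [] for m in methods}
    for i in range(n_outer):
        panel_ss, method_ss = streams[i].spawn(2)
        panel, _, _ = simulate_panel(scenario, panel_ss)
        correction = run_correction(panel, config)
        sub = {m: s for m, s in zip(METHODS, method_ss.spawn(len(METHODS)))}
        for m in methods:
            seed = int(sub[m].generate_state(1)[0] % 2**31)
            if m == "jack_del_1":
                r = jackknife_delete1(panel, estimator,
                                      m=min(scenario.resample_reps, panel.k),
                                      seed=seed)
            elif m == "jack_del_d":
                r = jackknife_delete_d(panel, estimator,
                                       m=scenario.resample_reps, seed=seed)
            else:
                r = parametric_bootstrap(panel, correction, estimator, variant=m,
                                         B=scenario.resample_reps, seed=seed)
            ses[m].append(r.se)
    report = SimulationReport(
        scenario=scenario,
        mean_est=float("nan") if point is None else point.mean_est,
        true_se=float(true_se))
    for m in methods:
        arr = np.asarray(ses[m])
        bias = float(arr.mean() - true_se)
        variance = float(arr.var())  # population form
        rmse = float(np.sqrt(np.mean((arr - true_se) ** 2)))
        report.per_method[m] = MethodStats(mean_se=float(arr.mean()), bias=bias,
                                           variance=variance, rmse=rmse)
    return report


def run_coverage_study(scenario: SimulationScenario, ci_schemes=CI_SCHEMES,
                       n_outer: int | None = None, level: float = 0.95,
                       config: CorrectionConfig | None = None) -> SimulationReport:
    """Empirical coverage of the union CIs for the true total Vg."""
    for s in ci_schemes:
        if s not in CI_SCHEMES:
            raise ValueError(f"unknown CI scheme {s!r}")
    n_outer = scenario.n_outer if n_outer is None else int(n_outer)
    config = config or CorrectionConfig()
    estimator = make_estimator(config)
    streams = _outer_streams(scenario, "coverage", n_outer)
    hits = {s: 0 for s in ci_schemes}
    ests = np.empty(n_outer)
    for i in range(n_outer):
        panel_ss, method_ss = streams[i].spawn(2)
        panel, _, true_vg = simulate_panel(scenario, panel_ss)
        correction = run_correction(panel, config)
        est = total_vg(panel, correction).vg_total
        ests[i] = est
        sub = method_ss.spawn(4)
        se_results = {"jack_del_d": jackknife_delete_d(
            panel, estimator, m=scenario.resample_reps,
            seed=int(sub[0].generate_state(1)[0] % 2**31))}
        for j, name in enumerate(BOOTSTRAP_VARIANTS, start=1):
            se_results[name] = parametric_bootstrap(
                panel, correction, estimator, variant=name,
                B=scenario.resample_reps,
                seed=int(sub[j].generate_state(1)[0] % 2**31))
        suite = build_ci_suite(est, se_results, level=level)
        by_scheme = {"standard": suite.union_standard,
                     "percentile": suite.union_percentile,
                     "standard+percentile": suite.union_all}
        for s in ci_schemes:
            hits[s] += int(by_scheme[s].contains(true_vg))
    report = SimulationReport(scenario=scenario, mean_est=float(ests.mean()),
                              true_se=float(ests.std(ddof=1)))
    report.coverage = {s: hits[s] / n_outer for s in ci_schemes}
    return report


def scaled_scenario(scenario: SimulationScenario, factor: float) -> SimulationScenario:
    """Shrink a scenario's panel while preserving per-SNP signal strength.

    k and vg_target are multiplied by ``factor`` so each non-null SNP
    keeps the same expected delta^2; useful for desk-scale coverage runs.
    """
    return replace(scenario, k=int(round(scenario.k * factor)),
                   vg_target=scenario.vg_target * factor)
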