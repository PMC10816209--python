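"""Confidence intervals for total heritability, including union CIs.

Four families are assembled for a 95% (configurable) level:

* standard normal-approximation CI, estimate +/- z_{0.975} * SE, using the
  delete-d jackknife SE; one uncorrected and three bootstrap bias-corrected
  variants (bias = mean of bootstrap replicates - estimate);
* percentile CIs from the bootstrap replicate quantiles (linear
  interpolation between order statistics, the common "type 7" rule), with
  and without bias correction (the corrected interval is the reflection of
  the quantiles about the estimate, 2*theta - q);
* union CIs: the minimum lower bound and maximum upper bound across a
  family -- robustness at the price of width.

Bounds are not truncated to [0, 1] by default; ``clip=True`` offers that
for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .resampling import BOOTSTRAP_VARIANTS, SEResult


@dataclass
class Interval:
    lower: float
    upper: float
    level: float = 0.95
    method_label: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class IntervalSuite:
    """All candidate CIs plus their unions."""

    standard: list[Interval]
    percentile: list[Interval]
    union_standard: Interval
    union_percentile: Interval
    union_all: Interval
    bias_estimates: np.ndarray = field(default_factory=lambda: np.empty(0))


def normal_ci(estimate: float, se: float, level: float = 0.95,
              label: str = "normal") -> Interval:
    """Normal-approximation CI: estimate +/- Phi^-1(1-(1-level)/2) * se."""
    if se < 0:
        raise ValueError("se must be non-negative")
    zq = norm.ppf(1.0 - (1.0 - level) / 2.0)
    return Interval(lower=estimate - zq * se, upper=estimate + zq * se,
                    level=level, method_label=label)


def bootstrap_bias(estimate: float, boot_replicates) -> tuple[float, float]:
    """Bootstrap bias and bias-corrected estimate.

    bias = mean(replicates) - estimate; corrected = estimate - bias.
    """
    reps = np.asarray(boot_replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    bias = float(reps.mean()) - estimate
    return bias, estimate - bias


def percentile_ci(estimate: float, boot_replicates, level: float = 0.95,
                  bias_correct: bool = False, label: str = "percentile") -> Interval:
    """Percentile CI of the bootstrap replicates, optionally reflected.

    Uncorrected: (q_alpha/2, q_1-alpha/2).  Corrected: (2*theta - q_1-alpha/2,
    2*theta - q_alpha/2), the reflection of the quantiles about the estimate.
    """
    reps = np.asarray(boot_replicates, dtype=float)
    if reps.size < 40:
        raise ValueError("need at least 40 replicates for stable quantiles")
    import logging
    if reps.size < 200:
        logging.getLogger(__name__).warning(
            "percentile CI from only %d replicates; quantiles may be unstable",
            reps.size)
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    if bias_correct:
        return Interval(lower=2.0 * estimate - q_hi, upper=2.0 * estimate - q_lo,
                        level=level, method_label=label + "+bias")
    return Interval(lower=float(q_lo), upper=float(q_hi), level=level,
                    method_label=label)


def union_ci(members: list[Interval], label: str = "union") -> Interval:
    """(min lower, max upper) across member intervals of equal level."""
    if not members:
        raise ValueError("union of an empty interval list")
    levels = {m.level for m in members}
    if len(levels) > 1:
        raise ValueError("union members must share a confidence level")
    return Interval(lower=min(m.lower for m in members),
                    upper=max(m.upper for m in members),
                    level=members[0].level, method_label=label)


def build_ci_suite(estimate: float, se_results: dict[str, SEResult],
                   level: float = 0.95, clip: bool = False) -> IntervalSuite:
    """Assemble the full CI suite from the point estimate and SE results.

    Requires ``jack_del_d`` (the standard CIs use its SE) and the three
    bootstrap methods (their replicates feed the bias corrections and
    percentiles): 4 standard members, 6 percentile members, 3 unions.
    """
    required = ("jack_del_d",) + BOOTSTRAP_VARIANTS
    for name in required:
        if name not in se_results:
            raise ValueError(f"build_ci_suite: missing SE result {name!r}")
    se_jackd = se_results["jack_del_d"].se

    standard = [normal_ci(estimate, se_jackd, level, label="standard")]
    biases = []
    for name in BOOTSTRAP_VARIANTS:
        bias, corrected = bootstrap_bias(estimate, se_results[name].replicates)
        biases.append(bias)
        standard.append(normal_ci(corrected, se_jackd, level,
                                  label=f"standard+bias[{name}]"))
    percentile = []
    for name in BOOTSTRAP_VARIANTS:
        reps = se_results[name].replicates
        percentile.append(percentile_ci(estimate, reps, level, False,
                                        label=f"percentile[{name}]"))
    for name in BOOTSTRAP_VARIANTS:
        reps = se_results[name].replicates
        percentile.append(percentile_ci(estimate, reps, level, True,
                                        label=f"percentile[{name}]"))

    union_standard = union_ci(standard, "union[standard]")
    union_percentile = union_ci(percentile, "union[percentile]")
    union_all = union_ci([union_standard, union_percentile], "union[all]")

    suite = IntervalSuite(standard=standard, percentile=percentile,
                          union_standard=union_standard,
                          union_percentile=union_percentile,
                          union_all=union_all,
                          bias_estimates=np.asarray(biases))
    if clip:
        for iv in (suite.standard + suite.percentile
                   + [suite.union_standard, suite.union_percentile, suite.union_all]):
            iv.lower = max(0.0, min(1.0, iv.lower))
            iv.upper = max(0.0, min(1.0, iv.upper))
    return suite
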