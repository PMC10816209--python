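"""Resampling standard errors for the total-heritability estimate.

Five SNP-level schemes, each re-running the *full* estimation pipeline
(density fit, correction, conversion) on every replicate so that the SE
captures density-estimation variability:

``jack_del_1``
    Delete-one jackknife.  Exact when m = k; by default m = 200 deletion
    indices are subsampled and the same plug-in formula is applied (the
    exact enumeration of 10^5 leave-one-out refits is rarely worth it).

``jack_del_d``
    Delete-d jackknife with m random deletion sets; consistent for
    non-smooth statistics where delete-one fails.  Default d = k/5.

``paraboot``
    Parametric bootstrap: z* ~ N(delta_hat, 1) per SNP.

``fdrboot1`` / ``fdrboot2``
    fdr-weighted mixtures: each SNP is redrawn from N(mean, 1) with
    probability 1 - fdr (mean = observed z for fdrboot1, corrected
    delta_hat for fdrboot2) and from the null N(0, 1) otherwise.

Every replicate uses a deterministic child stream of the method seed, so
results do not depend on evaluation order; noise and mixture-membership
draws use separate streams, which makes fdrboot2 with fdr == 0 reproduce
paraboot exactly under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .correction import CorrectionConfig, CorrectionResult, run_correction
from .heritability import total_vg
from .io import ZPanel

METHODS = ("jack_del_1", "jack_del_d", "paraboot", "fdrboot1", "fdrboot2")
BOOTSTRAP_VARIANTS = ("paraboot", "fdrboot1", "fdrboot2")

Estimator = Callable[[ZPanel], float]


@dataclass
class SEResult:
    """One resampling method's SE with its replicate estimates."""

    method: str
    se: float
    replicates: np.ndarray
    m_or_B: int
    seed: int
    d: int | None = None

    def recompute_se(self, k: int | None = None) -> float:
        """Re-apply the method's formula to the stored replicates."""
        reps = np.asarray(self.replicates, dtype=float)
        if self.method == "jack_del_1":
            return float(np.sqrt((k - 1) * np.mean((reps - reps.mean()) ** 2)))
        if self.method == "jack_del_d":
            return float(np.sqrt((k - self.d) / (self.d * reps.size)
                                 * np.sum((reps - reps.mean()) ** 2)))
        return float(np.std(reps, ddof=1))


def make_estimator(config: CorrectionConfig | None = None,
                   estimator: str = "unconditional") -> Estimator:
    """Bundle the full pipeline (correction + conversion) into a callable.

    The unconditional path skips the local-fdr fit, which the estimator
    does not consume; the conditional path runs the full correction.
    """
    config = config or CorrectionConfig()

    if estimator == "unconditional":
        from .correction import correct_z
        from .density import fit_density
        from .heritability import _per_snp_vg

        def pipeline(panel: ZPanel) -> float:
            model = fit_density(panel.z, bandwidth_rule=config.bandwidth_rule,
                                mode=config.mode, grid_size=config.grid_size,
                                bandwidth=config.bandwidth,
                                exact_threshold=config.exact_threshold)
            delta_hat = correct_z(panel.z, model, config.density_floor)
            return float(np.sum(_per_snp_vg(panel, delta_hat)))
    else:
        def pipeline(panel: ZPanel) -> float:
            return total_vg(panel, run_correction(panel, config), estimator).vg_total

    return pipeline


def jackknife_delete1(panel: ZPanel, estimator: Estimator,
                      m: int | None = None, seed: int = 0) -> SEResult:
    """Delete-one jackknife SE (exact when m = k, subsampled otherwise)."""
    k = panel.k
    m = k if m is None else int(m)
    if m > k or m < 2:
        raise ValueError(f"m must lie in [2, k={k}]")
    if m == k:
        drop = np.arange(k)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        drop = rng.choice(k, size=m, replace=False)
    mask = np.ones(k, dtype=bool)
    reps = np.empty(m)
    for v, i in enumerate(drop):
        mask[i] = False
        reps[v] = estimator(panel.subset(np.flatnonzero(mask)))
        mask[i] = True
    se = float(np.sqrt((k - 1) * np.mean((reps - reps.mean()) ** 2)))
    return SEResult(method="jack_del_1", se=se, replicates=reps, m_or_B=m, seed=seed)


def jackknife_delete_d(panel: ZPanel, estimator: Estimator,
                       d: int | None = None, m: int = 200,
                       seed: int = 0, exhaustive: bool = False) -> SEResult:
    """Delete-d jackknife SE from m random deletion sets of size d.

    ``exhaustive=True`` enumerates all C(k, d) deletion sets instead
    (small panels only); m is then ignored.
    """
    k = panel.k
    d = max(1, k // 5) if d is None else int(d)
    if not (1 <= d < k):
        raise ValueError(f"d must lie in [1, k-1], got {d} with k={k}")
    if exhaustive:
        from itertools import combinations
        from math import comb
        m = comb(k, d)
        if m > 100_000:
            raise ValueError(f"refusing to enumerate {m} deletion sets")
        drops = combinations(range(k), d)
    else:
        if m < 2:
            raise ValueError("need at least 2 deletion sets")
        children = np.random.SeedSequence(seed).spawn(m)
        drops = (np.random.default_rng(children[v]).choice(k, size=d, replace=False)
                 for v in range(m))
    reps = np.empty(m)
    for v, drop in enumerate(drops):
        mask = np.ones(k, dtype=bool)
        mask[list(drop)] = False
        reps[v] = estimator(panel.subset(np.flatnonzero(mask)))
    se = float(np.sqrt((k - d) / (d * m) * np.sum((reps - reps.mean()) ** 2)))
    return SEResult(method="jack_del_d", se=se, replicates=reps, m_or_B=m,
                    seed=seed, d=d)


def parametric_bootstrap(panel: ZPanel, correction: CorrectionResult,
                         estimator: Estimator, variant: str = "paraboot",
                         B: int = 200, seed: int = 0) -> SEResult:
    """Parametric / fdr-weighted bootstrap SE of the total-Vg estimate.

    The fdr values are those of the original fit (not refitted per
    replicate); mixture membership is redrawn independently per SNP per
    replicate.  The SE is the sample SD (denominator B-1) of the
    replicate estimates.
    """
    if variant not in BOOTSTRAP_VARIANTS:
        raise ValueError(f"unknown bootstrap variant {variant!r}")
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if correction.delta_hat.shape != panel.z.shape:
        raise ValueError("correction is not aligned with the panel")
    if variant == "paraboot":
        means = correction.delta_hat
    elif variant == "fdrboot1":
        means = panel.z
    else:  # fdrboot2
        means = correction.delta_hat
    fdr = correction.fdr if variant != "paraboot" else None
    k = panel.k
    children = np.random.SeedSequence(seed).spawn(B)
    reps = np.empty(B)
    for b in range(B):
        noise_ss, mask_ss = children[b].spawn(2)
        z_star = means + np.random.default_rng(noise_ss).standard_normal(k)
        if fdr is not None:
            null_member = np.random.default_rng(mask_ss).random(k) < fdr
            if null_member.any():
                z_star = np.where(null_member, z_star - means, z_star)
        reps[b] = estimator(panel.with_z(z_star))
    se = float(np.std(reps, ddof=1))
    return SEResult(method=variant, se=se, replicates=reps, m_or_B=B, seed=seed)


def estimate_se(panel: ZPanel, method: str, estimator: Estimator | None = None,
                config: CorrectionConfig | None = None,
                correction: CorrectionResult | None = None,
                reps: int = 200, d: int | None = None, seed: int = 0) -> SEResult:
    """Dispatch a single resampling method by name."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    estimator = estimator or make_estimator(config)
    if method == "jack_del_1":
        return jackknife_delete1(panel, estimator, m=min(reps, panel.k), seed=seed)
    if method == "jack_del_d":
        return jackknife_delete_d(panel, estimator, d=d, m=reps, seed=seed)
    if correction is None:
        correction = run_correction(panel, config or CorrectionConfig())
    return parametric_bootstrap(panel, correction, estimator, variant=method,
                                B=reps, seed=seed)
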