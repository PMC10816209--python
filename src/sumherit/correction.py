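"""Empirical-Bayes (Tweedie) correction of GWAS z-statistics.

Observed z-statistics overstate the true standardised effects of the most
extreme SNPs (winner's curse): z_i ~ N(delta_i, 1) with delta_i drawn from
an arbitrary prior.  Tweedie's formula gives the posterior mean without
ever specifying that prior:

    E[delta | z] = z + f'(z) / f(z),

where f is the *marginal* density of the observed z.  f and f' come from
the kernel density machinery in :mod:`sumherit.density`.

The module also estimates the per-SNP local false discovery rate
fdr(z) = pi0 * f0(z) / f(z) (posterior probability of a null effect) and
the conditional effect E[delta | z, H1] = E[delta | z] / (1 - fdr(z)),
used by the opt-in conditional heritability estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .density import DensityModel, fit_density
from .io import ZPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionConfig:
    """Settings for density fitting, correction and local-fdr estimation."""

    bandwidth_rule: str = "silverman"
    bandwidth: float | None = None      # used when bandwidth_rule == "fixed"
    grid_size: int = 2**14
    mode: str = "auto"                  # exact | binned | auto
    exact_threshold: int = 5000
    null: str = "theoretical"           # theoretical | empirical
    pi0_method: str = "central_match"   # central_match | fixed
    pi0: float | None = None
    fdr_floor: float = 1e-6
    density_floor: float = 1e-12

    def asdict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class CorrectionResult:
    """Per-SNP corrected effects and local false discovery rates.

    ``delta_hat_h1`` is NaN (flagged undefined) wherever fdr == 1.
    """

    delta_hat: np.ndarray
    fdr: np.ndarray
    delta_hat_h1: np.ndarray
    model: DensityModel | None = field(default=None, repr=False)
    config: CorrectionConfig | None = None


def correct_z(z: np.ndarray, model: DensityModel,
              density_floor: float = 1e-12) -> np.ndarray:
    """Apply Tweedie's formula: delta_hat = z + f'(z)/f(z).

    The density is floored before division; floored evaluations (z far in
    the tails of the fitted support) are counted and logged.
    """
    z = np.asarray(z, dtype=float)
    f, fp = model.evaluate(z)
    floored = int(np.sum(f < density_floor))
    if floored:
        logger.info("correct_z: %d density evaluations floored at %.0e",
                    floored, density_floor)
    return z + fp / np.maximum(f, density_floor)


def _empirical_null(z: np.ndarray) -> tuple[float, float]:
    """Location/scale of the null from the central half of the sample."""
    q25, q75 = np.percentile(z, [25.0, 75.0])
    mu = float(np.median(z))
    # IQR of the central-matched normal: sigma = IQR / (2 * Phi^-1(0.75))
    sigma = float((q75 - q25) / (2.0 * norm.ppf(0.75)))
    if sigma <= 0.0:
        raise ValueError("degenerate sample: empirical null scale is zero")
    return mu, sigma


def estimate_local_fdr(z: np.ndarray, model: DensityModel,
                       null: str = "theoretical",
                       pi0_method: str = "central_match",
                       pi0: float | None = None,
                       fdr_floor: float = 1e-6,
                       density_floor: float = 1e-12) -> np.ndarray:
    """Local false discovery rate fdr(z) = clamp(pi0 * f0(z)/f(z), floor, 1).

    ``null="theoretical"`` uses f0 = N(0,1); ``"empirical"`` matches a
    normal null to the centre of the sample (median location, IQR scale).
    pi0 defaults to central matching at zero, pi0 = min(1, f(0)/f0(0)).
    """
    z = np.asarray(z, dtype=float)
    if null == "theoretical":
        mu0, s0 = 0.0, 1.0
    elif null == "empirical":
        mu0, s0 = _empirical_null(z)
    else:
        raise ValueError(f"unknown null type {null!r}")

    if pi0_method == "fixed":
        if pi0 is None or not (0.0 <= pi0 <= 1.0):
            raise ValueError("pi0_method='fixed' requires pi0 in [0, 1]")
        pi0_hat = float(pi0)
    elif pi0_method == "central_match":
        if z.size < 100:
            raise ValueError("data-driven pi0 needs at least 100 z values")
        f_at_mode = float(model.evaluate(np.array([mu0]))[0][0])
        pi0_hat = min(1.0, f_at_mode / float(norm.pdf(0.0, scale=1.0) / s0))
        if pi0_hat <= 0.0:
            raise ValueError("estimated pi0 <= 0: degenerate input")
    else:
        raise ValueError(f"unknown pi0 method {pi0_method!r}")

    f, _ = model.evaluate(z)
    f0 = norm.pdf(z, loc=mu0, scale=s0)
    raw = pi0_hat * f0 / np.maximum(f, density_floor)
    return np.clip(raw, fdr_floor, 1.0)


def run_correction(panel: ZPanel, config: CorrectionConfig | None = None) -> CorrectionResult:
    """Fit the density and compute corrected effects, fdr and E[delta|z,H1]."""
    config = config or CorrectionConfig()
    model = fit_density(panel.z, bandwidth_rule=config.bandwidth_rule,
                        mode=config.mode, grid_size=config.grid_size,
                        bandwidth=config.bandwidth,
                        exact_threshold=config.exact_threshold)
    delta_hat = correct_z(panel.z, model, config.density_floor)
    pi0_method, pi0 = config.pi0_method, config.pi0
    if pi0_method == "central_match" and panel.k < 100:
        logger.warning("panel too small (%d SNPs) for data-driven pi0; "
                       "assuming pi0 = 1", panel.k)
        pi0_method, pi0 = "fixed", 1.0
    fdr = estimate_local_fdr(panel.z, model, null=config.null,
                             pi0_method=pi0_method, pi0=pi0,
                             fdr_floor=config.fdr_floor,
                             density_floor=config.density_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = np.where(fdr < 1.0, delta_hat / (1.0 - fdr), np.nan)
    n_undef = int(np.sum(fdr >= 1.0))
    if n_undef:
        logger.info("run_correction: E[delta|z,H1] undefined for %d SNPs (fdr = 1)",
                    n_undef)
    return CorrectionResult(delta_hat=delta_hat, fdr=fdr, delta_hat_h1=h1,
                            model=model, config=config)
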