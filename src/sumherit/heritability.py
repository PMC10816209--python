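"""Conversion of (corrected) standardised effects to variance explained.

For a continuous trait the per-SNP variance explained follows from the
ANOVA identity for simple regression: a SNP with standardised effect
delta (true beta over its standard error) explains

    Vg = delta^2 / (n - 2 + delta^2)

of the phenotypic variance, where n is the GWAS sample size.  Total
SNP-based heritability is the sum over (approximately independent,
LD-pruned) SNPs.

For a binary trait, logistic log-odds are first mapped to the liability
scale (variance 1) through a probit approximation using the population
prevalence K, then standardised by the SD of the allele count,
sqrt(2 * MAF * (1 - MAF)); the squared standardised coefficients sum to
the liability-scale heritability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .correction import CorrectionResult
from .io import ZPanel

logger = logging.getLogger(__name__)


@dataclass
class HeritabilityEstimate:
    """Total and per-SNP variance explained."""

    vg_total: float
    vg_per_snp: np.ndarray
    estimator: str
    n_snps: int
    n: int


@dataclass
class BinaryConversionParams:
    """Inputs for the logistic-to-liability conversion."""

    prevalence: float
    maf: np.ndarray
    beta: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        self.maf = np.asarray(self.maf, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (self.maf.shape == self.beta.shape == self.se.shape):
            raise ValueError("maf, beta and se must have equal length")
        if np.any(self.se <= 0):
            raise ValueError("se must be > 0")


def vg_continuous(delta, n: int):
    """Variance explained by a standardised effect: delta^2/(n-2+delta^2)."""
    if n < 3:
        raise ValueError("sample size n must be >= 3")
    delta = np.asarray(delta, dtype=float)
    out = delta**2 / (n - 2 + delta**2)
    return float(out) if out.ndim == 0 else out


def delta_from_vg(vg, n: int):
    """Inverse of :func:`vg_continuous`: the delta explaining a given Vg."""
    if n < 3:
        raise ValueError("sample size n must be >= 3")
    vg = np.asarray(vg, dtype=float)
    if np.any(vg < 0) or np.any(vg >= 1):
        raise ValueError("vg must lie in [0, 1)")
    out = np.sqrt(vg * (n - 2) / (1.0 - vg))
    return float(out) if out.ndim == 0 else out


def liability_scale_coefficient(beta_logit, prevalence: float):
    """Map logistic log-odds to a liability-scale coefficient (tau_1).

    Probit-approximation path: the log-odds beta approximates a change in
    case probability of beta * K(1-K) per allele; under the threshold
    model with unit-variance liability, a liability shift of tau_1 changes
    the case probability by phi(t) * tau_1, where t = Phi^-1(1-K) is the
    liability threshold.  Hence tau_1 = beta * K(1-K) / phi(t).
    """
    k = prevalence
    t = norm.ppf(1.0 - k)
    return np.asarray(beta_logit, dtype=float) * k * (1.0 - k) / norm.pdf(t)


def vg_binary(params: BinaryConversionParams, delta_scale: np.ndarray) -> np.ndarray:
    """Per-SNP liability-scale variance explained for a binary trait.

    ``delta_scale`` are (corrected) standardised effects; they are mapped
    back to the log-odds scale through the per-SNP standard errors, then
    to the liability scale, standardised by the allele-count SD
    sqrt(2*MAF*(1-MAF)), and squared.
    """
    delta_scale = np.asarray(delta_scale, dtype=float)
    if delta_scale.shape != params.beta.shape:
        raise ValueError("delta_scale not aligned with conversion parameters")
    beta_corrected = delta_scale * params.se
    tau1 = liability_scale_coefficient(beta_corrected, params.prevalence)
    tau_standard = tau1 * np.sqrt(2.0 * params.maf * (1.0 - params.maf))
    return tau_standard**2


def _per_snp_vg(panel: ZPanel, delta: np.ndarray) -> np.ndarray:
    if panel.trait_type == "binary":
        params = BinaryConversionParams(prevalence=panel.prevalence,
                                        maf=panel.maf, beta=panel.beta,
                                        se=panel.se)
        return vg_binary(params, delta)
    return vg_continuous(delta, panel.n)


def total_vg(panel: ZPanel, correction: CorrectionResult,
             estimator: str = "unconditional") -> HeritabilityEstimate:
    """Sum per-SNP variance explained into total SNP-based heritability.

    ``unconditional`` (default) converts E[delta|z]; ``conditional``
    converts E[delta|z,H1] and weights each SNP by its probability of
    being non-null, 1 - fdr.  SNPs with fdr = 1 (conditional effect
    undefined) contribute zero and are logged.
    """
    if correction.delta_hat.shape != panel.z.shape:
        raise ValueError("correction is not aligned with the panel")
    if estimator == "unconditional":
        per_snp = _per_snp_vg(panel, correction.delta_hat)
    elif estimator == "conditional":
        undefined = ~np.isfinite(correction.delta_hat_h1)
        if undefined.any():
            logger.info("total_vg: %d SNPs with fdr = 1 contribute 0",
                        int(undefined.sum()))
        h1 = np.where(undefined, 0.0, correction.delta_hat_h1)
        per_snp = _per_snp_vg(panel, h1) * (1.0 - correction.fdr)
        per_snp[undefined] = 0.0
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    total = float(np.sum(per_snp))
    if total > 1.0:
        logger.warning("total Vg %.3f exceeds 1; estimates are not renormalised",
                       total)
    return HeritabilityEstimate(vg_total=total, vg_per_snp=per_snp,
                                estimator=estimator, n_snps=panel.k, n=panel.n)
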