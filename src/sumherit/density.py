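"""Gaussian kernel density estimation with an analytic first derivative.

The empirical-Bayes correction at the core of this package needs both the
marginal density f(z) of the observed z-statistics and its derivative f'(z):
the corrected (posterior-mean) effect is z + f'(z)/f(z).  Neither scipy nor
statsmodels exposes a KDE derivative, so the estimator lives here.

Two evaluation strategies are provided:

``exact``
    Direct summation of the Gaussian kernel (and its analytic derivative)
    over all training points, O(n * n_query).  Used for small samples and
    for queries outside the binned grid.

``binned``
    Linear binning of the sample onto a uniform grid followed by FFT
    convolution with the kernel (and its derivative) sampled on the same
    grid, then linear interpolation at query points.  O(n + G log G) with
    G grid points; this is what makes resampling at GWAS scale (10^5 SNPs,
    hundreds of replicates) tractable.

Bandwidth rules: Silverman's rule of thumb (default), the Botev fixed-point
variant of Sheather-Jones plug-in selection, a normal-reference rule
optimised for *derivative* estimation (h ~ n^(-1/7), noticeably wider than
Silverman's n^(-1/5)), and a user-fixed bandwidth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct
from scipy.optimize import brentq
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: queries are evaluated exactly (not interpolated) when outside the grid
GRID_PAD_BANDWIDTHS = 4.0
#: kernel tails are truncated here when sampled for FFT convolution
_KERNEL_CUTOFF = 8.0


class DegenerateInputError(ValueError):
    """Raised when a data-driven bandwidth rule meets zero-variance input."""


def _robust_scale(z: np.ndarray) -> float:
    sd = float(np.std(z, ddof=1)) if z.size > 1 else 0.0
    q75, q25 = np.percentile(z, [75.0, 25.0])
    iqr = float(q75 - q25)
    if iqr > 0.0 and sd > 0.0:
        return min(sd, iqr / 1.34)
    return max(sd, iqr / 1.34)


def bw_silverman(z: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    s = _robust_scale(z)
    if s <= 0.0:
        raise DegenerateInputError("zero-variance sample: Silverman bandwidth undefined")
    return 0.9 * s * z.size ** (-0.2)


def bw_deriv_reference(z: np.ndarray) -> float:
    """Normal-reference bandwidth optimised for estimating f'.

    Minimising the asymptotic MISE of the Gaussian-kernel estimate of the
    *first derivative* of a normal density gives h = sigma * (0.8/n)^(1/7),
    about twice Silverman's value at n = 1e5.  The wider bandwidth trades
    a little smoothing bias for a large reduction in the variance of
    f'(z)/f(z), which is what the shrinkage correction consumes.
    """
    s = _robust_scale(z)
    if s <= 0.0:
        raise DegenerateInputError("zero-variance sample: bandwidth undefined")
    return s * (0.8 / z.size) ** (1.0 / 7.0)


def bw_sheather_jones(z: np.ndarray, n_grid: int = 2**12) -> float:
    """Sheather-Jones plug-in bandwidth, Botev fixed-point formulation.

    Solves t = xi * gamma^[l](t) for the squared (scaled) bandwidth using
    the DCT of the binned data (Botev, Grotowski & Kroese 2010).  Falls
    back to Silverman's rule when the root bracketing fails (e.g. very
    heavy-tailed or near-degenerate input).
    """
    z = np.asarray(z, dtype=float)
    n = int(np.unique(z).size)
    if n < 2:
        raise DegenerateInputError("need at least 2 distinct points for Sheather-Jones")
    zmin, zmax = float(z.min()), float(z.max())
    span = zmax - zmin
    lo, hi = zmin - span / 10.0, zmax + span / 10.0
    width = hi - lo
    hist, _ = np.histogram(z, bins=n_grid, range=(lo, hi))
    a = dct(hist / z.size, type=2)
    i_sq = np.arange(1, n_grid, dtype=float) ** 2
    a2 = (a[1:] / 2.0) ** 2

    def fixed_point(t: float) -> float:
        ell = 7
        f = 2.0 * np.pi ** (2 * ell) * np.sum(i_sq**ell * a2 * np.exp(-i_sq * np.pi**2 * t))
        if f <= 0.0:
            return np.inf
        for s in range(ell - 1, 1, -1):
            odd_prod = np.prod(np.arange(1, 2 * s, 2, dtype=float))
            k0 = odd_prod / _SQRT2PI
            const = (1.0 + 0.5 ** (s + 0.5)) / 3.0
            t_s = (2.0 * const * k0 / (n * f)) ** (2.0 / (3.0 + 2.0 * s))
            f = 2.0 * np.pi ** (2 * s) * np.sum(i_sq**s * a2 * np.exp(-i_sq * np.pi**2 * t_s))
            if f <= 0.0:
                return np.inf
        return (2.0 * n * np.sqrt(np.pi) * f) ** (-0.4)

    try:
        t_star = brentq(lambda t: t - fixed_point(t), 1e-14, 0.1)
        return float(np.sqrt(t_star) * width)
    except ValueError:
        logger.warning("Sheather-Jones fixed point not bracketed; using Silverman's rule")
        return bw_silverman(z)


_BANDWIDTH_RULES = {
    "silverman": bw_silverman,
    "sheather_jones": bw_sheather_jones,
    "deriv_reference": bw_deriv_reference,
}


def resolve_bandwidth(z: np.ndarray, rule: str, fixed: float | None = None) -> float:
    """Resolve a bandwidth rule name (or ``"fixed"`` + value) to a number."""
    if rule == "fixed":
        if fixed is None or fixed <= 0.0:
            raise ValueError("bandwidth_rule='fixed' requires a positive bandwidth value")
        return float(fixed)
    try:
        fn = _BANDWIDTH_RULES[rule]
    except KeyError:
        raise ValueError(f"unknown bandwidth rule {rule!r}") from None
    if z.size < 10:
        raise ValueError("data-driven bandwidth rules need at least 10 points")
    return float(fn(z))


def _exact_eval(train: np.ndarray, h: float, query: np.ndarray,
                chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """O(n * n_query) Gaussian-kernel sums for f and f' at the query points."""
    n = train.size
    f = np.empty(query.size)
    fp = np.empty(query.size)
    for start in range(0, query.size, chunk):
        q = query[start:start + chunk, None]
        u = (q - train[None, :]) / h
        k = np.exp(-0.5 * u * u)
        f[start:start + chunk] = k.sum(axis=1) / (n * h * _SQRT2PI)
        fp[start:start + chunk] = (-u * k).sum(axis=1) / (n * h * h * _SQRT2PI)
    return f, fp


@dataclass
class DensityModel:
    """Fitted marginal density of z-statistics, with derivative.

    ``support_grid``/``f_grid``/``fprime_grid`` always describe the density
    on a uniform grid spanning the data padded by 4 bandwidths; evaluation
    at arbitrary points goes through :meth:`evaluate`, which interpolates in
    binned mode and falls back to the exact kernel sum outside the grid.
    """

    bandwidth: float
    support_grid: np.ndarray
    f_grid: np.ndarray
    fprime_grid: np.ndarray
    n_points: int
    mode: str
    train_z: np.ndarray = field(repr=False)

    def evaluate(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (f(z), f'(z)) for each query point."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if self.mode == "exact":
            return _exact_eval(self.train_z, self.bandwidth, z)
        f = np.interp(z, self.support_grid, self.f_grid)
        fp = np.interp(z, self.support_grid, self.fprime_grid)
        outside = (z < self.support_grid[0]) | (z > self.support_grid[-1])
        if np.any(outside):
            f_out, fp_out = _exact_eval(self.train_z, self.bandwidth, z[outside])
            f[outside] = f_out
            fp[outside] = fp_out
        return f, fp


def fit_density(z: np.ndarray, bandwidth_rule: str = "silverman",
                mode: str = "auto", grid_size: int = 2**14,
                bandwidth: float | None = None,
                exact_threshold: int = 5000) -> DensityModel:
    """Fit a Gaussian-kernel density (and derivative) to a z vector.

    Parameters
    ----------
    z
        Finite z-statistics.
    bandwidth_rule
        One of ``silverman``, ``sheather_jones``, ``deriv_reference``,
        ``fixed`` (the latter requires ``bandwidth``).
    mode
        ``exact``, ``binned`` or ``auto`` (binned above ``exact_threshold``
        points).  Binned mode agrees with exact summation to ~1e-3 relative
        at the default grid size.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("z must be a non-empty 1-D array")
    if not np.all(np.isfinite(z)):
        raise ValueError("z contains non-finite values")
    h = resolve_bandwidth(z, bandwidth_rule, bandwidth)

    if mode == "auto":
        mode = "binned" if z.size > exact_threshold else "exact"
    if mode not in ("binned", "exact"):
        raise ValueError(f"unknown evaluation mode {mode!r}")

    lo = float(z.min()) - GRID_PAD_BANDWIDTHS * h
    hi = float(z.max()) + GRID_PAD_BANDWIDTHS * h
    grid = np.linspace(lo, hi, grid_size)

    if mode == "exact":
        f_grid, fp_grid = _exact_eval(z, h, grid)
    else:
        dx = grid[1] - grid[0]
        # linear binning: each point splits its mass between flanking nodes
        pos = (z - lo) / dx
        i0 = np.clip(np.floor(pos).astype(np.int64), 0, grid_size - 1)
        w = pos - i0
        counts = (np.bincount(i0, 1.0 - w, minlength=grid_size)
                  + np.bincount(np.minimum(i0 + 1, grid_size - 1), w, minlength=grid_size))
        half = int(np.ceil(_KERNEL_CUTOFF * h / dx))
        u = np.arange(-half, half + 1) * dx
        kern = np.exp(-0.5 * (u / h) ** 2) / (h * _SQRT2PI)
        f_grid = fftconvolve(counts, kern, mode="same") / z.size
        fp_grid = fftconvolve(counts, (-u / h**2) * kern, mode="same") / z.size

    f_grid = np.maximum(f_grid, 1e-12)  # strict positivity on the grid
    return DensityModel(bandwidth=h, support_grid=grid, f_grid=f_grid,
                        fprime_grid=fp_grid, n_points=int(z.size),
                        mode=mode, train_z=z)
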