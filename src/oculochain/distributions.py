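"""Latency-distribution comparisons: fixed-bandwidth KDE, two-sample
Kolmogorov-Smirnov Z tests, and simple regression slope summaries.

Densities are estimated by convolving the latency sample with a Gaussian
kernel of fixed width — the kernel standard deviation, 40 ms by default
(the "width" is read as the SD, not the FWHM; configurable).  The KS Z
statistic is ``D * sqrt(n1 n2 / (n1 + n2))`` with the p-value from the
asymptotic Kolmogorov distribution, matching the classic "KS Z test"
report; an exact small-sample p is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "KernelDensity",
    "GaussianKde",
    "KSResult",
    "SlopeSummary",
    "kernel_density",
    "density_difference",
    "ks_two_sample",
    "ols_slope",
]


@dataclass
class KernelDensity:
    """A latency density on a uniform grid (ms), integrating to 1."""

    grid: np.ndarray
    values: np.ndarray
    bandwidth_ms: float
    n: int

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


class GaussianKde(BaseEstimator):
    """Fixed-bandwidth Gaussian kernel density estimator.

    The fitted density is the mean of Gaussian kernels (SD =
    ``bandwidth_ms``) centered at each latency, evaluated on a uniform grid
    spanning the data plus six bandwidths on either side.

    Attributes (after fit): ``grid_``, ``density_``, ``result_``.
    """

    def __init__(self, bandwidth_ms: float = 40.0, grid_step_ms: float = 1.0):
        self.bandwidth_ms = bandwidth_ms
        self.grid_step_ms = grid_step_ms

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError("empty latency sample")
        if self.bandwidth_ms <= 0:
            raise ValueError("bandwidth must be > 0")
        h = self.bandwidth_ms
        # six bandwidths of margin keep the truncated tail mass below 1e-8,
        # so the trapezoid integral is 1 to tighter than 1e-6
        lo = math.floor(x.min() - 6 * h)
        hi = math.ceil(x.max() + 6 * h)
        grid = np.arange(lo, hi + self.grid_step_ms / 2, self.grid_step_ms)
        norm = 1.0 / (x.size * h * math.sqrt(2 * math.pi))
        dens = np.zeros_like(grid)
        # chunk the sample to bound the (n x grid) broadcast
        for start in range(0, x.size, 512):
            chunk = x[start : start + 512]
            dens += np.exp(-0.5 * ((grid[:, None] - chunk) / h) ** 2).sum(axis=1)
        self.grid_ = grid
        self.density_ = dens * norm
        self.result_ = KernelDensity(grid, self.density_, h, int(x.size))
        return self

    def evaluate(self, points) -> np.ndarray:
        return np.interp(np.asarray(points, dtype=float), self.grid_, self.density_, left=0.0, right=0.0)


def kernel_density(
    latencies: Sequence[float],
    bandwidth_ms: float = 40.0,
    grid_step_ms: float = 1.0,
) -> KernelDensity:
    """Fixed-bandwidth Gaussian KDE; see :class:`GaussianKde`."""
    return GaussianKde(bandwidth_ms=bandwidth_ms, grid_step_ms=grid_step_ms).fit(latencies).result_


def density_difference(a: KernelDensity, b: KernelDensity) -> tuple:
    """Pointwise density difference a - b on the union grid.

    Both densities must share the bandwidth; each is linearly interpolated
    onto the union grid (zero outside its own support, which is negligible
    beyond four bandwidths).  Returns ``(grid, diff)``; the difference
    integrates to ~0 since both densities integrate to 1.
    """
    if a.bandwidth_ms != b.bandwidth_ms:
        raise ValueError("bandwidth mismatch between densities")
    step = min(np.diff(a.grid).min(), np.diff(b.grid).min())
    lo = min(a.grid[0], b.grid[0])
    hi = max(a.grid[-1], b.grid[-1])
    grid = np.arange(lo, hi + step / 2, step)
    da = np.interp(grid, a.grid, a.values, left=0.0, right=0.0)
    db = np.interp(grid, b.grid, b.values, left=0.0, right=0.0)
    return grid, da - db


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison."""

    d_statistic: float
    z_statistic: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(x1: Sequence[float], x2: Sequence[float], exact: bool = False) -> KSResult:
    """Two-sample KS test with the Z parameterization.

    ``D = sup |ECDF1 - ECDF2|``, ``Z = D sqrt(n1 n2/(n1+n2))``, p from the
    asymptotic Kolmogorov distribution (or the exact distribution when
    ``exact``).
    """
    a = np.sort(np.asarray(x1, dtype=float))
    b = np.sort(np.asarray(x2, dtype=float))
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 observations")
    # sup over all jump points of both ECDFs
    pts = np.concatenate([a, b])
    cdf1 = np.searchsorted(a, pts, side="right") / n1
    cdf2 = np.searchsorted(b, pts, side="right") / n2
    d = float(np.abs(cdf1 - cdf2).max())
    z = d * math.sqrt(n1 * n2 / (n1 + n2))
    if exact:
        p = float(stats.ks_2samp(a, b, method="exact").pvalue)
    else:
        p = float(stats.kstwobign.sf(z)) if z > 0 else 1.0
    return KSResult(d, z, min(1.0, p), n1, n2)


@dataclass
class SlopeSummary:
    """OLS slope of latency on duration with standardized effect size."""

    slope: float
    intercept: float
    beta_std: float
    t: float
    F: float
    r2: float
    p_value: float
    n: int


def ols_slope(x: Sequence[float], y: Sequence[float]) -> SlopeSummary:
    """Ordinary least-squares fit of y on x.

    ``beta_std = slope * sd(x)/sd(y)`` (the correlation, for a simple
    regression), with the slope t statistic and its square F = t².
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xa) == 0:
        raise ValueError("x is constant")
    res = stats.linregress(xa, ya)
    sy = ya.std(ddof=1)
    beta = float(res.slope * xa.std(ddof=1) / sy) if sy > 0 else float("nan")
    t = float(res.slope / res.stderr) if res.stderr > 0 else float("inf")
    return SlopeSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        beta_std=beta,
        t=t,
        F=t * t,
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(xa.size),
    )
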