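"""Model-II (errors-in-both-variables) regression: OLS, MA, SMA, RMA.

Ordinary least squares assumes the predictor is noise-free; when both axes
carry measurement error its slope is biased toward zero (regression
dilution).  The model-II family fits a symmetric line: regressing y on x
gives exactly the reciprocal slope of regressing x on y.

* MA  (major axis): first principal axis of the centered data.
* SMA (standardized/scaled major axis): sign(r) * sd(y)/sd(x).
* RMA (ranged major axis): each axis is standardized by its observed
  interval range (max - min), the major axis is fit on the standardized
  data, and the slope is back-transformed by range(y)/range(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SlopeFit", "ols_fit", "ma_slope", "sma_slope", "rma_slope"]


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    method: str
    n: int
    ci_low: float | None = None
    ci_high: float | None = None


def _clean(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    return x, y


def _with_bootstrap(fit_fn, x, y, method, n_boot, seed):
    x, y = _clean(x, y)
    slope, intercept = fit_fn(x, y)
    ci_low = ci_high = None
    if n_boot:
        rng = np.random.default_rng(seed)
        slopes = []
        n = len(x)
        for _ in range(n_boot):
            ix = rng.integers(0, n, n)
            try:
                s, _ = fit_fn(x[ix], y[ix])
            except ValueError:
                continue
            slopes.append(s)
        if slopes:
            ci_low, ci_high = (float(q) for q in np.percentile(slopes, [2.5, 97.5]))
    return SlopeFit(float(slope), float(intercept), method, len(x), ci_low, ci_high)


def _ols(x, y):
    sx2 = np.var(x)
    if sx2 == 0:
        raise ValueError("zero variance in x")
    slope = np.cov(x, y, bias=True)[0, 1] / sx2
    return slope, y.mean() - slope * x.mean()


def _ma(x, y):
    sx2, sy2 = np.var(x), np.var(y)
    sxy = np.cov(x, y, bias=True)[0, 1]
    if sxy == 0:
        raise ValueError("zero covariance: major-axis orientation undefined")
    slope = (sy2 - sx2 + np.sqrt((sy2 - sx2) ** 2 + 4 * sxy**2)) / (2 * sxy)
    return slope, y.mean() - slope * x.mean()


def _sma(x, y):
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on one axis")
    r = np.corrcoef(x, y)[0, 1]
    if r == 0:
        raise ValueError("zero correlation: SMA sign undefined")
    slope = np.sign(r) * sy / sx
    return slope, y.mean() - slope * x.mean()


def _rma(x, y):
    rx = np.ptp(x)
    ry = np.ptp(y)
    if rx == 0 or ry == 0:
        raise ValueError("zero range on one axis")
    slope_std, _ = _ma(x / rx, y / ry)
    slope = slope_std * ry / rx
    return slope, y.mean() - slope * x.mean()


def ols_fit(x, y, n_boot: int = 0, seed: int = 0) -> SlopeFit:
    """Ordinary least-squares slope s_xy / s_x^2 (noise-blind baseline)."""
    return _with_bootstrap(_ols, x, y, "OLS", n_boot, seed)


def ma_slope(x, y, n_boot: int = 0, seed: int = 0) -> SlopeFit:
    """Major-axis slope (first principal axis of the centered data)."""
    return _with_bootstrap(_ma, x, y, "MA", n_boot, seed)


def sma_slope(x, y, n_boot: int = 0, seed: int = 0) -> SlopeFit:
    """Standardized major-axis slope sign(r) * sd(y)/sd(x)."""
    return _with_bootstrap(_sma, x, y, "SMA", n_boot, seed)


def rma_slope(x, y, n_boot: int = 0, seed: int = 0) -> SlopeFit:
    """Ranged major-axis slope (major axis on range-standardized data).

    Confidence intervals, when requested, come from a nonparametric
    bootstrap over genes.
    """
    return _with_bootstrap(_rma, x, y, "RMA", n_boot, seed)
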