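"""Reliability estimation and Spearman-type attenuation corrections.

Measurement noise attenuates observed correlations: if X = phi + e_X and
Y = psi + e_Y with uncorrelated errors, then

    corr(X, Y) = corr(phi, psi) * sqrt(alpha_X * alpha_Y)

where alpha = Var(signal)/Var(total) is the *reliability* of a measurement.
The correlation between two independent replicates estimates the geometric
mean of their reliabilities, so given replicated measurements of both
variables the latent correlation can be disattenuated by dividing the
observed cross-correlation by the geometric mean of the reliability
estimates.  The corrected estimate is not itself a correlation coefficient
and may fall outside (-1, 1) due to sampling error; no p-value is attached.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "ReliabilityEstimate",
    "CorrectedCorrelation",
    "reliability_from_replicates",
    "attenuated_correlation",
    "corrected_correlation_pair4",
    "corrected_correlation_from_components",
    "corrected_correlation_multi",
    "averaging_curve",
]


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Estimated signal-to-total variance ratio of a measurement.

    Sampling error can push the estimate slightly outside [0, 1].
    """

    alpha_hat: float
    n_pairs: int


@dataclass(frozen=True)
class CorrectedCorrelation:
    """Disattenuated correlation estimate plus the correlations it used."""

    r_hat: float
    cross_correlations: tuple[float, ...]
    reliability_x: float
    reliability_y: float


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation on pairwise-complete observations."""
    xx, yy = _pairwise_complete(x, y)
    if len(xx) < 3:
        raise ValueError("need at least 3 shared observed genes")
    return float(np.corrcoef(xx, yy)[0, 1])


def reliability_from_replicates(x1, x2) -> ReliabilityEstimate:
    """Estimate reliability as the Pearson correlation of two replicates.

    The replicate-replicate correlation equals the geometric mean of the two
    replicates' reliabilities; for replicates of comparable quality it is
    reported as the common (symmetric) reliability estimate alpha-hat.
    """
    xx, _ = _pairwise_complete(x1, x2)
    return ReliabilityEstimate(alpha_hat=_corr(x1, x2), n_pairs=len(xx))


def attenuated_correlation(rho_true: float, alpha_x: float, alpha_y: float) -> float:
    """Expected observed correlation given a latent correlation and reliabilities.

    The maximum observable correlation between two noisy measurements is the
    geometric mean of their reliabilities, reached when rho_true = 1.
    """
    if not (0 < alpha_x <= 1 and 0 < alpha_y <= 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    return rho_true * float(np.sqrt(alpha_x * alpha_y))


def _geometric_mean(values: Sequence[float], what: str) -> float:
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"undefined {what} encountered")
    if np.any(arr <= 0):
        raise ValueError(
            f"non-positive {what} {arr[arr <= 0].tolist()}: the geometric mean is "
            "undefined; attenuation corrections require positive correlations "
            "(near-zero or negative correlations carry no recoverable signal)"
        )
    return float(np.exp(np.mean(np.log(arr))))


def corrected_correlation_from_components(
    cross_correlations: Sequence[float], r_xx: float, r_yy: float
) -> CorrectedCorrelation:
    """Disattenuate precomputed correlations.

    ``cross_correlations`` are the observed X-Y correlations (any number);
    ``r_xx`` and ``r_yy`` are the within-set replicate correlations serving
    as reliability estimates.  The estimate is the geometric mean of the
    cross-correlations divided by sqrt(r_xx * r_yy).
    """
    num = _geometric_mean(cross_correlations, "cross-correlation")
    _geometric_mean([r_xx, r_yy], "reliability correlation")  # positivity check
    return CorrectedCorrelation(
        r_hat=num / float(np.sqrt(r_xx * r_yy)),
        cross_correlations=tuple(float(c) for c in cross_correlations),
        reliability_x=float(r_xx),
        reliability_y=float(r_yy),
    )


def corrected_correlation_pair4(x1, x2, y1, y2) -> CorrectedCorrelation:
    """Four-measurement attenuation-corrected correlation estimate.

    r_hat = (r_x1y1 r_x2y2 r_x1y2 r_x2y1)^(1/4) / sqrt(r_x1x2 * r_y1y2).

    Each of the six correlations is computed pairwise-complete, matching use
    on datasets of unequal coverage.  Symmetric under swapping x1<->x2,
    y1<->y2 and exchanging the X and Y roles.
    """
    cross = [_corr(x1, y1), _corr(x2, y2), _corr(x1, y2), _corr(x2, y1)]
    return corrected_correlation_from_components(cross, _corr(x1, x2), _corr(y1, y2))


def corrected_correlation_multi(
    X: Sequence[np.ndarray], Y: Sequence[np.ndarray]
) -> CorrectedCorrelation:
    """N x M generalization of the four-measurement estimator.

    The numerator is the geometric mean of all N*M cross-correlations; the
    denominator is the product of the within-set geometric-mean reliability
    terms, each with exponent 1/(N(N-1)) so that every unordered replicate
    pair effectively contributes twice (once per ordering).  For N = M = 2
    this reduces exactly to :func:`corrected_correlation_pair4`.
    """
    n, m = len(X), len(Y)
    if n < 2 or m < 2:
        raise ValueError("need at least two replicates on each side")
    cross = [_corr(x, y) for x in X for y in Y]
    num = _geometric_mean(cross, "cross-correlation")
    rx = [_corr(X[i], X[j]) for i, j in combinations(range(n), 2)]
    ry = [_corr(Y[i], Y[j]) for i, j in combinations(range(m), 2)]
    for vals in (rx, ry):
        _geometric_mean(vals, "reliability correlation")
    den_x = float(np.prod(rx)) ** (1.0 / (n * (n - 1)))
    den_y = float(np.prod(ry)) ** (1.0 / (m * (m - 1)))
    return CorrectedCorrelation(
        r_hat=num / (den_x * den_y),
        cross_correlations=tuple(cross),
        reliability_x=den_x**2,
        reliability_y=den_y**2,
    )


def averaging_curve(
    X: Sequence[np.ndarray],
    Y: Sequence[np.ndarray],
    k_max: int,
    n_draws: int = 50,
    seed: int | np.random.Generator = 0,
):
    """Observed correlation as a function of how many replicates are averaged.

    For k = 1..k_max, repeatedly samples k replicates per side (without
    replacement), averages the log-scale measurements, and correlates the
    averages; returns per-k mean and SD over ``n_draws`` random subsets.
    Averaging dilutes independent noise, so the curve rises toward the true
    correlation as k grows.
    """
    import pandas as pd

    if k_max > min(len(X), len(Y)):
        raise ValueError("k_max exceeds the number of available replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    rows = []
    for k in range(1, k_max + 1):
        rs = []
        for _ in range(n_draws):
            ix = rng.choice(len(X), size=k, replace=False)
            iy = rng.choice(len(Y), size=k, replace=False)
            rs.append(_corr(Xa[ix].mean(axis=0), Ya[iy].mean(axis=0)))
        rows.append({
            "k": k,
            "mean_correlation": float(np.mean(rs)),
            "sd_correlation": float(np.std(rs, ddof=1)) if n_draws > 1 else 0.0,
        })
    return pd.DataFrame(rows)
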