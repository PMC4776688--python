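"""Sample entropy and multiscale entropy (MSE) shape features.

Sample entropy H_SE(m, r, N) = -ln(A^m(r) / B^m(r)), where B^m counts pairs
of m-length templates within Chebyshev distance r (self-matches excluded)
and A^m the same for (m+1)-length templates; both counts run over the first
N - m template start points, the Richman-Moorman convention.

The multiscale profile coarse-grains the series by non-overlapping window
averages at scales 1..5, holds r fixed at ``r_fraction`` x STD of the
original (scale-1) series, and summarizes the five-point entropy curve by
the coefficients of a least-squares cubic in the scale index.  The fit
coefficients — not the raw entropies — are the features: MSE(1) is the
cubic term and MSE(4) the constant term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import ParameterError


def coarse_grain(values: np.ndarray, scale: int) -> np.ndarray:
    """Average non-overlapping windows of length ``scale``; remainder dropped."""
    v = np.asarray(values, dtype=float)
    if scale < 1 or int(scale) != scale:
        raise ParameterError("scale must be a positive integer")
    if scale > len(v):
        raise ParameterError(f"scale {scale} exceeds series length {len(v)}")
    n = (len(v) // scale) * scale
    return v[:n].reshape(-1, scale).mean(axis=1)


def sample_entropy(values: np.ndarray, m: int = 1, r: float | None = None) -> float:
    """Sample entropy in nats; NaN when no template pairs match.

    ``r`` is the similarity threshold in signal units (two templates match
    when every pointwise difference is <= r, Chebyshev distance).
    """
    v = np.asarray(values, dtype=float)
    N = len(v)
    if m < 1:
        raise ParameterError("template length m must be >= 1")
    if r is None or r <= 0:
        raise ParameterError("similarity threshold r must be positive")
    if N <= m + 1:
        raise ParameterError(f"series length {N} too short for m={m}")

    n_templ = N - m  # template start points for both lengths
    close = np.abs(v[:, None] - v[None, :]) <= r

    def pair_count(length: int) -> int:
        match = close[:n_templ, :n_templ].copy()
        for k in range(1, length):
            match &= close[k : k + n_templ, k : k + n_templ]
        np.fill_diagonal(match, False)
        return int(match.sum()) // 2  # unordered pairs

    B = pair_count(m)
    A = pair_count(m + 1)
    if A == 0 or B == 0:
        return np.nan
    return float(-np.log(A / B))


@dataclass
class EntropyProfile:
    """Entropy values over scales 1..n plus the cubic-fit coefficients.

    ``coeffs`` are in descending degree: ``coeffs[0]`` the cubic term,
    ``coeffs[3]`` the constant term.
    """

    scales: np.ndarray
    h: np.ndarray
    coeffs: np.ndarray
    available: bool = True


def fit_cubic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares third-degree polynomial, coefficients in descending degree."""
    return np.polyfit(np.asarray(x, float), np.asarray(y, float), 3)


def mse_profile(
    values: np.ndarray,
    m: int = 1,
    r_fraction: float = 0.1,
    n_scales: int = 5,
) -> EntropyProfile:
    """Multiscale entropy over the first ``n_scales`` scales plus cubic fit.

    ``r`` is fixed once as ``r_fraction`` x sample STD of the scale-1 series
    and reused at every scale.  If any scale's entropy is undefined (no
    matching templates) the profile is flagged unavailable and the fit is
    skipped.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ParameterError("mse_profile requires a gap-free series")
    r = r_fraction * float(np.std(v, ddof=1))
    scales = np.arange(1, n_scales + 1)
    if r == 0:
        return EntropyProfile(scales, np.full(n_scales, np.nan),
                              np.full(4, np.nan), available=False)
    h = np.array([sample_entropy(coarse_grain(v, int(s)), m=m, r=r) for s in scales])
    if np.isnan(h).any():
        return EntropyProfile(scales, h, np.full(4, np.nan), available=False)
    return EntropyProfile(scales, h, fit_cubic(scales, h))
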