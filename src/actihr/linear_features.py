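"""Summary statistics and non-parametric rest-activity (circadian) metrics.

The rest-activity metrics follow the classical non-parametric actigraphy
convention:

* **L5 / M10** — the aggregate signal level over the least-active 5-hour and
  most-active 10-hour windows of the mean 24-h profile.  Windows are sums of
  native-resolution slots and wrap circularly across midnight.
* **RA** — relative amplitude, ``(M10 - L5) / (M10 + L5)``.
* **IS** — interdaily stability, the variance of the mean 24-h profile over
  the total variance, computed on hourly means with ``p = 24`` hourly bins:
  ``IS = n * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2)``.
* **IV** — intradaily variability, the mean squared successive difference
  over the variance of the hourly means:
  ``IV = n * sum_{i>=2} (x_i - x_{i-1})^2 / ((n - 1) * sum_i (x_i - xbar)^2)``.

Degenerate inputs (constant signal, all-missing) yield NaN rather than an
exception so that a subject's feature vector can carry explicit gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import MINUTES_PER_DAY, ParameterError, RegularSeries


@dataclass
class SummaryStats:
    mean: float
    median: float
    mode: float
    std: float
    iqr: float
    available: bool = True


def summary_stats(values: np.ndarray, mode_resolution: float) -> SummaryStats:
    """Mean, median, mode, sample STD and IQR of the non-missing values.

    The mode is taken after rounding to ``mode_resolution`` (1 bpm for HR,
    0.01 for activity); ties go to the smallest value.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        return SummaryStats(np.nan, np.nan, np.nan, np.nan, np.nan, available=False)
    rounded = np.round(v / mode_resolution) * mode_resolution
    levels, counts = np.unique(rounded, return_counts=True)
    mode = float(levels[np.argmax(counts)])  # np.unique sorts: first max = smallest
    q75, q25 = np.percentile(v, [75, 25])
    return SummaryStats(
        mean=float(np.mean(v)),
        median=float(np.median(v)),
        mode=mode,
        std=float(np.std(v, ddof=1)),
        iqr=float(q75 - q25),
    )


def mean_daily_profile(series: RegularSeries) -> np.ndarray:
    """Per-slot-of-day means over all days; NaN where a slot is never observed."""
    spd = series.slots_per_day
    n = len(series.values)
    if n == 0:
        raise ParameterError("empty series")
    pad = (-n) % spd
    v = np.concatenate([series.values, np.full(pad, np.nan)]) if pad else series.values
    offset = int(round((series.start % MINUTES_PER_DAY) / series.interval))
    days = v.reshape(-1, spd)
    profile = np.full(spd, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slots stay NaN
        means = np.nanmean(days, axis=0)
    profile[(offset + np.arange(spd)) % spd] = means
    return profile


def _interp_circular(profile: np.ndarray) -> np.ndarray:
    """Fill NaN slots by linear interpolation around the circle."""
    p = profile.copy()
    miss = np.isnan(p)
    if not miss.any():
        return p
    if miss.all():
        raise ParameterError("profile has no observed slots")
    n = len(p)
    idx = np.arange(n)
    # unwrap around the circle by tripling, interpolate, take the middle copy
    obs = idx[~miss]
    xs = np.concatenate([obs - n, obs, obs + n])
    ys = np.tile(p[~miss], 3)
    p[miss] = np.interp(idx[miss], xs, ys)
    return p


def l5_m10(profile: np.ndarray, interval: float) -> tuple[float, float, int, int]:
    """L5 and M10 window sums over a mean daily profile.

    Returns ``(L5, M10, l5_start_slot, m10_start_slot)``.  Windows are
    contiguous runs of ``5h/interval`` and ``10h/interval`` slots, searched
    over all circular start positions; window value is the SUM of slot
    values; ties go to the earliest start.
    """
    p = _interp_circular(np.asarray(profile, dtype=float))
    n = len(p)
    w5 = int(round(300.0 / interval))
    w10 = int(round(600.0 / interval))
    if n < w10:
        raise ParameterError("profile shorter than the 10-h window")
    ext = np.concatenate([p, p])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    sums5 = csum[w5 : w5 + n] - csum[:n]
    sums10 = csum[w10 : w10 + n] - csum[:n]
    i5 = int(np.argmin(sums5))   # argmin/argmax return the first (earliest) tie
    i10 = int(np.argmax(sums10))
    return float(sums5[i5]), float(sums10[i10]), i5, i10


def relative_amplitude(l5: float, m10: float) -> float:
    """RA = (M10 - L5) / (M10 + L5); NaN when the denominator is zero."""
    denom = m10 + l5
    if denom == 0 or np.isnan(denom):
        return np.nan
    return (m10 - l5) / denom


def hourly_means(series: RegularSeries) -> tuple[np.ndarray, np.ndarray]:
    """Hourly means of a regular series.

    Returns ``(x, hour_of_day)`` where ``x`` is the time-ordered sequence of
    hourly means (hours with no observation dropped) and ``hour_of_day`` the
    corresponding 0-23 bin of each.  Positions are counted within the series
    (selected days are treated as contiguous).
    """
    per_hour = int(round(60.0 / series.interval))
    n = len(series.values)
    pad = (-n) % per_hour
    v = np.concatenate([series.values, np.full(pad, np.nan)]) if pad else series.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # unobserved hours stay NaN
        x = np.nanmean(v.reshape(-1, per_hour), axis=1)
    start_hour = int(round((series.start % MINUTES_PER_DAY) / 60.0))
    hod = (start_hour + np.arange(len(x))) % 24
    keep = ~np.isnan(x)
    return x[keep], hod[keep]


def interdaily_stability(series: RegularSeries) -> float:
    """IS on hourly means with p = 24 hourly bins; NaN for constant input."""
    x, hod = hourly_means(series)
    n = len(x)
    if n < 25:
        return np.nan
    xbar = x.mean()
    ss_tot = np.sum((x - xbar) ** 2)
    if ss_tot == 0:
        return np.nan
    p = 24
    ss_hour = 0.0
    for h in range(p):
        sel = x[hod == h]
        if len(sel):
            ss_hour += (sel.mean() - xbar) ** 2
    return float(n * ss_hour / (p * ss_tot))


def intradaily_variability(series: RegularSeries) -> float:
    """IV on hourly means; NaN for constant input."""
    x, _ = hourly_means(series)
    n = len(x)
    if n < 2:
        return np.nan
    xbar = x.mean()
    ss_tot = np.sum((x - xbar) ** 2)
    if ss_tot == 0:
        return np.nan
    ss_diff = np.sum(np.diff(x) ** 2)
    return float(n * ss_diff / ((n - 1) * ss_tot))
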