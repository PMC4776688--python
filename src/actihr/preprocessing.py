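"""Preprocessing of irregular wearable-sensor series.

Converts irregularly timestamped heart-rate (HR) and locomotor-activity
samples into synchronized regular grids, applying the quality rules the
analysis assumes:

1. inter-sample spans longer than 1.5x the nominal collection rate
   (15 min for HR, 7.5 min for activity) are flagged as low quality and
   never bridged by interpolation;
2. HR values below 20 bpm are physiologically implausible artifacts and
   are removed (counted toward the subject's artifact fraction);
3. HR is resampled to an exact 10-min grid by zero-order hold;
4. activity is resampled to an exact 5-min grid by zero-order hold;
5. where synchronous series are needed, activity is further down-sampled
   to 10 min as the mean of the two covered 5-min values.

From each record the 10 calendar days with the lowest missing fraction are
retained, and subjects with more than 10% HR artifacts or more than 10%
missing data after day selection are rejected.

All timestamps are float minutes since local midnight of the subject's
first recording day; a day is MINUTES_PER_DAY = 1440 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MINUTES_PER_DAY = 1440.0
HR_INTERVAL = 10.0
ACT_INTERVAL = 5.0
HR_FLOOR_BPM = 20.0
GAP_FACTOR = 1.5
GATE_THRESHOLD = 0.10
N_SELECTED_DAYS = 10


class InputError(ValueError):
    """Malformed input series (unsorted timestamps, wrong signal kind...)."""


class ParameterError(ValueError):
    """Invalid parameter value."""


class RecordRejected(RuntimeError):
    """The record cannot pass preprocessing (e.g. fewer than 10 days)."""


@dataclass
class SampleSeries:
    """Irregularly timestamped samples of one signal.

    Parameters
    ----------
    kind : {"hr", "activity"}
    t : minutes since the subject's reference midnight, strictly increasing.
    v : sample values (bpm for HR, arbitrary units in [0, 1] for activity).
    gap_after : boolean mask of length ``n - 1``; ``gap_after[i]`` marks the
        span ``(t[i], t[i+1]]`` as a low-quality gap. ``None`` until
        :func:`flag_long_gaps` has run.
    n_artifacts : number of samples removed as artifacts so far.
    n_raw : sample count before any filtering (set on construction).
    """

    kind: str
    t: np.ndarray
    v: np.ndarray
    gap_after: np.ndarray | None = None
    n_artifacts: int = 0
    n_raw: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.kind not in ("hr", "activity"):
            raise InputError(f"unknown signal kind {self.kind!r}")
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise InputError("timestamps and values must be 1-D and equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise InputError("timestamps must be strictly increasing")
        if self.kind == "activity" and len(self.v) and (
            np.nanmin(self.v) < 0 or np.nanmax(self.v) > 1
        ):
            raise InputError("activity values must lie in [0, 1]")
        if self.n_raw is None:
            self.n_raw = len(self.t)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def artifact_fraction(self) -> float:
        return self.n_artifacts / self.n_raw if self.n_raw else 0.0


@dataclass
class RegularSeries:
    """Evenly sampled signal with NaN as the explicit missing marker.

    ``start`` is the time of the first slot (minutes); slot ``j`` sits at
    ``start + j * interval``.  After day selection the retained days are
    concatenated and treated as contiguous; ``retained_days`` then lists the
    original calendar-day indices in order.
    """

    kind: str
    start: float
    interval: float
    values: np.ndarray
    retained_days: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) * self.interval

    @property
    def quality_fraction(self) -> float:
        """Fraction of slots missing."""
        if len(self.values) == 0:
            return 1.0
        return float(np.isnan(self.values).mean())

    @property
    def slots_per_day(self) -> int:
        return int(round(MINUTES_PER_DAY / self.interval))


@dataclass
class SubjectRecord:
    """Paired HR/activity series for one subject, before and after processing."""

    subject_id: str
    label: int
    hr_raw: SampleSeries
    act_raw: SampleSeries
    hr: RegularSeries | None = None          # 10-min grid, 10 selected days
    activity: RegularSeries | None = None    # 5-min grid, 10 selected days
    activity_10min: RegularSeries | None = None
    retained_days: list[int] | None = None
    quality: dict = field(default_factory=dict)


def nominal_interval(kind: str) -> float:
    return HR_INTERVAL if kind == "hr" else ACT_INTERVAL


def flag_long_gaps(series: SampleSeries, nominal: float | None = None) -> SampleSeries:
    """Annotate inter-sample spans exceeding 1.5x the nominal collection rate.

    The annotated spans (15 min for HR, 7.5 min for activity) are treated as
    missing by the resampler: no value is held across them.
    """
    if nominal is None:
        nominal = nominal_interval(series.kind)
    if nominal <= 0:
        raise ParameterError("nominal interval must be positive")
    gaps = np.diff(series.t) > GAP_FACTOR * nominal
    return replace(series, gap_after=gaps)


def filter_hr_floor(series: SampleSeries, floor: float = HR_FLOOR_BPM) -> SampleSeries:
    """Remove HR samples strictly below ``floor`` (default 20 bpm).

    The rule is strict: a value of exactly 20 bpm is retained.  Removed
    samples count toward the subject's artifact fraction.
    """
    if series.kind != "hr":
        raise InputError("the HR floor filter applies to HR series only")
    keep = series.v >= floor
    return SampleSeries(
        kind="hr",
        t=series.t[keep],
        v=series.v[keep],
        n_artifacts=series.n_artifacts + int((~keep).sum()),
        n_raw=series.n_raw,
    )


def _grid_start_end(t: np.ndarray, interval: float, align_days: bool) -> tuple[float, float]:
    if align_days:
        start = np.floor(t[0] / MINUTES_PER_DAY) * MINUTES_PER_DAY
        end = (np.floor(t[-1] / MINUTES_PER_DAY) + 1) * MINUTES_PER_DAY - interval
    else:
        start = np.floor(t[0] / interval) * interval
        end = np.ceil(t[-1] / interval) * interval
    return float(start), float(end)


def resample_zoh(
    series: SampleSeries, interval: float, align_days: bool = False
) -> RegularSeries:
    """Resample to an exact grid by zero-order hold (sample-and-hold).

    Each grid slot takes the most recent observed value.  A slot is missing
    when no observation precedes it, when the most recent observation is more
    than 1.5x ``interval`` in the past, or when the slot falls strictly inside
    a flagged low-quality gap (no hold across gaps).

    With ``align_days`` the grid is extended to whole calendar days (slots
    outside the recorded span are missing), so day selection sees complete
    days.
    """
    if len(series) == 0:
        raise InputError("cannot resample an empty series")
    if interval <= 0:
        raise ParameterError("interval must be positive")
    flagged = series if series.gap_after is not None else flag_long_gaps(series, interval)
    start, end = _grid_start_end(series.t, interval, align_days)
    n_slots = int(round((end - start) / interval)) + 1
    slots = start + np.arange(n_slots) * interval

    idx = np.searchsorted(series.t, slots, side="right") - 1
    values = np.full(n_slots, np.nan)
    has_prev = idx >= 0
    prev = idx[has_prev]
    age = slots[has_prev] - series.t[prev]
    ok = age <= GAP_FACTOR * interval
    # strictly inside a flagged gap: prev has a flagged span to the next sample
    inside_gap = np.zeros(len(prev), dtype=bool)
    gapped = prev < len(flagged.gap_after)
    inside_gap[gapped] = flagged.gap_after[prev[gapped]] & (age[gapped] > 0)
    ok &= ~inside_gap
    out = np.where(has_prev)[0][ok]
    values[out] = series.v[prev[ok]]
    return RegularSeries(kind=series.kind, start=start, interval=interval, values=values)


def downsample_linear(series: RegularSeries, target: float = HR_INTERVAL) -> RegularSeries:
    """Down-sample a regular series to a coarser grid by averaging.

    Each target slot is the mean of the source slots it covers (for 5 -> 10
    min, the previous and the next 5-min value); the slot is missing if any
    covered source slot is missing.  A trailing remainder is dropped.
    """
    factor = target / series.interval
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ParameterError(
            f"target interval {target} is not a multiple of {series.interval}"
        )
    factor = int(round(factor))
    n = (len(series.values) // factor) * factor
    blocks = series.values[:n].reshape(-1, factor)
    values = blocks.mean(axis=1)  # NaN propagates: missing in -> missing out
    return RegularSeries(
        kind=series.kind,
        start=series.start,
        interval=target,
        values=values,
        retained_days=series.retained_days,
    )


def per_day_missing(series: RegularSeries) -> dict[int, float]:
    """Missing fraction per calendar day, counting slots outside the grid.

    Every day from the first to the last day touched by the grid contributes
    a full complement of ``slots_per_day`` slots; slots the grid does not
    cover count as missing, so partial edge days rank poorly.
    """
    spd = series.slots_per_day
    days = np.floor(series.times / MINUTES_PER_DAY).astype(int)
    first, last = int(days[0]), int(days[-1])
    observed = ~np.isnan(series.values)
    counts = {d: 0 for d in range(first, last + 1)}
    for d, obs in zip(days, observed):
        if obs:
            counts[int(d)] += 1
    return {d: 1.0 - counts[d] / spd for d in sorted(counts)}


def select_best_days(
    series: RegularSeries,
    n_days: int = N_SELECTED_DAYS,
    day_fractions: dict[int, float] | None = None,
) -> tuple[RegularSeries, dict[int, float]]:
    """Keep the ``n_days`` calendar days with the lowest missing fraction.

    Ties are broken by the earlier calendar day.  The retained days are
    concatenated in calendar order into a day-aligned series (each block a
    complete day).  ``day_fractions`` may supply externally computed per-day
    missing fractions (e.g. combined over both signals) used for the ranking;
    the report returned is always this series' own per-day fractions.

    Raises :class:`RecordRejected` when fewer than ``n_days`` days are spanned.
    """
    report = per_day_missing(series)
    ranking = day_fractions if day_fractions is not None else report
    if len(report) < n_days:
        raise RecordRejected(
            f"record spans {len(report)} days; {n_days} required"
        )
    chosen = sorted(sorted(ranking), key=lambda d: (ranking[d], d))[:n_days]
    chosen = sorted(chosen)

    spd = series.slots_per_day
    blocks = []
    times = series.times
    for d in chosen:
        block = np.full(spd, np.nan)
        in_day = (times >= d * MINUTES_PER_DAY) & (times < (d + 1) * MINUTES_PER_DAY)
        slot_of_day = np.round(
            (times[in_day] - d * MINUTES_PER_DAY) / series.interval
        ).astype(int)
        block[slot_of_day] = series.values[in_day]
        blocks.append(block)
    values = np.concatenate(blocks) if blocks else np.array([])
    out = RegularSeries(
        kind=series.kind,
        start=chosen[0] * MINUTES_PER_DAY,
        interval=series.interval,
        values=values,
        retained_days=list(chosen),
    )
    return out, report


@dataclass
class GateDecision:
    accepted: bool
    reasons: list[str]
    hr_artifact_fraction: float
    hr_missing_fraction: float
    act_missing_fraction: float


def quality_gate(record: SubjectRecord, threshold: float = GATE_THRESHOLD) -> GateDecision:
    """Accept or reject a preprocessed record on the 10% quality rule.

    Rejects when the HR artifact fraction, or the post-selection missing
    fraction of either signal, exceeds ``threshold`` strictly ("more than
    10%"); exactly 10.0% is accepted.
    """
    if record.hr is None or record.activity is None:
        raise InputError("quality_gate requires a preprocessed record")
    art = record.hr_raw.artifact_fraction
    hr_miss = record.hr.quality_fraction
    act_miss = record.activity.quality_fraction
    reasons = []
    if art > threshold:
        reasons.append(f"HR artifact fraction {art:.3f} > {threshold}")
    if hr_miss > threshold:
        reasons.append(f"HR missing fraction {hr_miss:.3f} > {threshold}")
    if act_miss > threshold:
        reasons.append(f"activity missing fraction {act_miss:.3f} > {threshold}")
    return GateDecision(
        accepted=not reasons,
        reasons=reasons,
        hr_artifact_fraction=art,
        hr_missing_fraction=hr_miss,
        act_missing_fraction=act_miss,
    )


def preprocess_subject(
    record: SubjectRecord,
    n_days: int = N_SELECTED_DAYS,
    gate_threshold: float = GATE_THRESHOLD,
) -> tuple[SubjectRecord, GateDecision]:
    """Run the full per-subject preprocessing chain.

    Flags gaps, filters the HR floor, resamples both signals by zero-order
    hold onto day-aligned grids, selects one set of best days per subject
    (ranking days by the mean of the two signals' missing fractions),
    down-samples activity to the synchronous 10-min grid, and applies the
    quality gate.  The record is returned with its regular series attached
    regardless of the gate decision.
    """
    hr = filter_hr_floor(flag_long_gaps(record.hr_raw))
    if len(hr) == 0:
        raise RecordRejected("all HR samples removed as artifacts")
    hr = flag_long_gaps(hr)
    act = flag_long_gaps(record.act_raw)

    hr_grid = resample_zoh(hr, HR_INTERVAL, align_days=True)
    act_grid = resample_zoh(act, ACT_INTERVAL, align_days=True)

    hr_days = per_day_missing(hr_grid)
    act_days = per_day_missing(act_grid)
    common = sorted(set(hr_days) | set(act_days))
    combined = {
        d: (hr_days.get(d, 1.0) + act_days.get(d, 1.0)) / 2.0 for d in common
    }
    hr_sel, _ = select_best_days(hr_grid, n_days, day_fractions=combined)
    act_sel, _ = select_best_days(act_grid, n_days, day_fractions=combined)

    record.hr = hr_sel
    record.activity = act_sel
    record.activity_10min = downsample_linear(act_sel, HR_INTERVAL)
    record.retained_days = hr_sel.retained_days
    record.hr_raw = hr  # carries the artifact count
    decision = quality_gate(record, gate_threshold)
    record.quality = {
        "hr_artifact_fraction": decision.hr_artifact_fraction,
        "hr_missing_fraction": decision.hr_missing_fraction,
        "act_missing_fraction": decision.act_missing_fraction,
        "per_day_missing_hr": {int(k): v for k, v in hr_days.items()},
        "per_day_missing_act": {int(k): v for k, v in act_days.items()},
        "accepted": decision.accepted,
        "reasons": decision.reasons,
    }
    return record, decision
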