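"""Synthetic cohorts of paired heart-rate / locomotor-activity recordings.

The generator stands in for multi-week chest-patch recordings: locomotor
activity sampled roughly every 5 min in arbitrary units on [0, 1], and
ECG-derived heart rate roughly every 10 min in bpm.  Its structure mirrors
what the downstream analysis assumes:

* activity follows a 24-h wake/sleep envelope (rectified sinusoid with
  per-day phase jitter) with lognormal bursts by day and near-zero values
  by night;
* heart rate is baseline + a circadian sinusoid + an instantaneous gain
  times concurrent activity + AR(1) noise whose coefficient
  (``mse_roughness``) controls short-scale irregularity;
* sampling intervals are jittered, and optional contiguous dropouts and
  implausible HR values (< 20 bpm) emulate device artifacts.

Two packaged calibration profiles ("case-like" and "control-like",
``profiles/default.yaml``) are tuned so the cohort reproduces the direction
and rough magnitude of the published group contrasts (elevated mean HR and
reduced activity dispersion in the case group); they are illustrative, not
estimates of any real population's parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml

from .preprocessing import MINUTES_PER_DAY, ParameterError, SampleSeries, SubjectRecord


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one diagnostic group."""

    hr_baseline: float          # bpm
    hr_circadian_amp: float     # bpm
    hr_activity_gain: float     # bpm per activity-unit
    hr_noise_sd: float          # bpm
    act_day_level: float        # activity-units
    act_burst_rate: float       # bursts/hour at full wake envelope
    act_burst_scale: float      # activity-units, lognormal median of a burst
    act_night_level: float      # activity-units
    mse_roughness: float        # AR(1) coefficient of the HR noise, [0, 1)
    sleep_onset_jitter_sd: float  # hours

    def validate(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if f.name == "mse_roughness":
                if not 0 <= val < 1:
                    raise ParameterError("mse_roughness must lie in [0, 1)")
            elif f.name == "hr_baseline":
                if val <= 0:
                    raise ParameterError("hr_baseline must be positive")
            elif val < 0:
                raise ParameterError(f"{f.name} must be nonnegative")
        for name in ("act_day_level", "act_night_level"):
            if getattr(self, name) > 1:
                raise ParameterError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AcquisitionModel:
    """Sampling and corruption characteristics of the recording device."""

    hr_interval_mean: float = 10.0    # minutes
    act_interval_mean: float = 5.0    # minutes
    interval_jitter_sd: float = 0.5   # minutes
    dropout_rate: float = 0.0         # fraction of samples lost in contiguous gaps
    artifact_rate: float = 0.0        # fraction of HR samples made implausible
    record_days: int = 14

    def validate(self) -> None:
        if not (0 <= self.dropout_rate <= 1 and 0 <= self.artifact_rate <= 1):
            raise ParameterError("dropout_rate and artifact_rate must lie in [0, 1]")
        if self.record_days < 1:
            raise ParameterError("record_days must be >= 1")
        if self.hr_interval_mean <= 0 or self.act_interval_mean <= 0:
            raise ParameterError("sampling intervals must be positive")


def load_profiles(path: str | None = None) -> dict:
    """Load the packaged (or a user-supplied) calibration profile file.

    Returns a dict with keys ``case``, ``control`` (GroupProfile) and
    ``acquisition`` (AcquisitionModel).
    """
    if path is None:
        text = resources.files("actihr").joinpath("profiles/default.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {
        "case": GroupProfile(**raw["case"]),
        "control": GroupProfile(**raw["control"]),
    }
    out["acquisition"] = AcquisitionModel(**raw.get("acquisition", {}))
    out["case"].validate()
    out["control"].validate()
    out["acquisition"].validate()
    return out


WAKE_PHASE_H = 8.0   # envelope zero-crossing: activity rises around 08:00
HR_ACROPHASE_H = 15.0  # circadian HR peak mid-afternoon


def _sample_times(rng: np.random.Generator, days: int, mean: float, jitter: float):
    n = int(days * MINUTES_PER_DAY / mean) + 8
    steps = rng.normal(mean, jitter, size=n).clip(mean * 0.2)
    t = np.cumsum(steps) - steps[0]
    return t[t < days * MINUTES_PER_DAY]


def _envelope(t_min: np.ndarray, phase_by_day: np.ndarray) -> np.ndarray:
    """Rectified 24-h sinusoid wake envelope with per-day phase jitter."""
    day = np.floor(t_min / MINUTES_PER_DAY).astype(int)
    phase = phase_by_day[day]
    hours = t_min / 60.0
    raw = np.sin(2 * np.pi * (hours - WAKE_PHASE_H - phase) / 24.0)
    return np.clip(raw, 0.0, None)


def generate_subject(
    profile: GroupProfile,
    acq: AcquisitionModel,
    seed: int,
    subject_id: str = "s000",
    label: int = 0,
) -> SubjectRecord:
    """Generate one subject's paired irregular HR/activity series.

    Reproducible: the same arguments and seed give identical series.
    Corruption (dropouts, implausible HR values) is injected afterwards by
    :func:`inject_artifacts` according to ``acq``.
    """
    profile.validate()
    acq.validate()
    rng = np.random.default_rng(seed)
    days = acq.record_days
    phase_by_day = rng.normal(0.0, profile.sleep_onset_jitter_sd, size=days + 1)

    # --- activity -----------------------------------------------------------
    t_act = _sample_times(rng, days, acq.act_interval_mean, acq.interval_jitter_sd)
    env = _envelope(t_act, phase_by_day)
    act = profile.act_night_level + profile.act_day_level * env
    p_burst = np.clip(profile.act_burst_rate * (acq.act_interval_mean / 60.0) * env, 0, 1)
    burst = rng.random(len(t_act)) < p_burst
    act = act + burst * rng.lognormal(
        np.log(max(profile.act_burst_scale, 1e-9)), 0.7, size=len(t_act)
    )
    act = np.clip(act + rng.normal(0, 0.004, size=len(t_act)), 0.0, 1.0)

    # --- heart rate ---------------------------------------------------------
    t_hr = _sample_times(rng, days, acq.hr_interval_mean, acq.interval_jitter_sd)
    hours = t_hr / 60.0
    day = np.floor(t_hr / MINUTES_PER_DAY).astype(int)
    circ = profile.hr_circadian_amp * np.sin(
        2 * np.pi * (hours - HR_ACROPHASE_H - phase_by_day[day]) / 24.0
    )
    act_at_hr = np.interp(t_hr, t_act, act)
    rho = profile.mse_roughness
    innov = rng.normal(0.0, profile.hr_noise_sd * np.sqrt(1 - rho ** 2), size=len(t_hr))
    noise = np.empty(len(t_hr))
    prev = rng.normal(0.0, profile.hr_noise_sd)
    for i, e in enumerate(innov):
        prev = rho * prev + e
        noise[i] = prev
    hr = profile.hr_baseline + circ + profile.hr_activity_gain * act_at_hr + noise
    hr = np.clip(hr, 25.0, None)  # a clean subject never trips the 20-bpm artifact rule

    record = SubjectRecord(
        subject_id=subject_id,
        label=label,
        hr_raw=SampleSeries("hr", t_hr, hr),
        act_raw=SampleSeries("activity", t_act, act),
    )
    if acq.dropout_rate > 0 or acq.artifact_rate > 0:
        record = inject_artifacts(record, acq, seed=int(rng.integers(2 ** 31)))
    return record


def _drop_contiguous(
    t: np.ndarray, v: np.ndarray, rate: float, rng: np.random.Generator,
    mean_gap_len: int = 6,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    n = len(t)
    target = int(round(rate * n))
    drop = np.zeros(n, dtype=bool)
    gaps: list[tuple[float, float]] = []
    guard = 0
    while drop.sum() < target and guard < 10 * n:
        guard += 1
        length = max(1, int(rng.geometric(1.0 / mean_gap_len)))
        start = int(rng.integers(0, n))
        drop[start : start + length] = True
    if drop.sum() > target:  # trim overshoot from the end of marked samples
        marked = np.where(drop)[0]
        drop[marked[target:]] = False
    # report each contiguous dropped run as (last kept before, first kept after)
    marked = np.where(drop)[0]
    if len(marked):
        run_starts = marked[np.r_[True, np.diff(marked) > 1]]
        run_ends = marked[np.r_[np.diff(marked) > 1, True]]
        for a, b in zip(run_starts, run_ends):
            lo = t[a - 1] if a > 0 else t[a]
            hi = t[b + 1] if b + 1 < n else t[b]
            gaps.append((float(lo), float(hi)))
    return t[~drop], v[~drop], gaps


def inject_artifacts(record: SubjectRecord, acq: AcquisitionModel, seed: int) -> SubjectRecord:
    """Corrupt a record with contiguous dropouts and implausible HR values.

    The injected fractions are recorded in ``record.quality`` under
    ``injected_*`` keys so tests can compare detected against injected
    corruption.
    """
    acq.validate()
    if acq.dropout_rate == 0 and acq.artifact_rate == 0:
        return record
    rng = np.random.default_rng(seed)
    hr_t, hr_v = record.hr_raw.t.copy(), record.hr_raw.v.copy()
    act_t, act_v = record.act_raw.t.copy(), record.act_raw.v.copy()

    n_hr_raw = len(hr_t)
    hr_gaps: list[tuple[float, float]] = []
    act_gaps: list[tuple[float, float]] = []
    if acq.dropout_rate > 0:
        hr_t, hr_v, hr_gaps = _drop_contiguous(hr_t, hr_v, acq.dropout_rate, rng)
        act_t, act_v, act_gaps = _drop_contiguous(act_t, act_v, acq.dropout_rate, rng)

    n_artifacts = 0
    if acq.artifact_rate > 0:
        n_artifacts = int(round(acq.artifact_rate * len(hr_t)))
        idx = rng.choice(len(hr_t), size=n_artifacts, replace=False)
        hr_v[idx] = rng.uniform(5.0, 19.5, size=n_artifacts)

    out = replace(
        record,
        hr_raw=SampleSeries("hr", hr_t, hr_v),
        act_raw=SampleSeries("activity", act_t, act_v),
    )
    out.quality = dict(record.quality)
    out.quality.update({
        "injected_hr_artifact_fraction": n_artifacts / len(hr_t) if len(hr_t) else 0.0,
        "injected_hr_dropout_fraction": 1.0 - len(hr_t) / n_hr_raw if n_hr_raw else 0.0,
        "injected_act_dropout_fraction":
            1.0 - len(act_t) / len(record.act_raw.t) if len(record.act_raw.t) else 0.0,
        "injected_hr_gaps": hr_gaps,
        "injected_act_gaps": act_gaps,
    })
    return out


def generate_cohort(
    n_cases: int,
    n_controls: int,
    case_profile: GroupProfile,
    control_profile: GroupProfile,
    acq: AcquisitionModel,
    seed: int,
) -> list[SubjectRecord]:
    """Generate a labelled cohort; per-subject seeds derive from the master seed."""
    if n_cases < 1 or n_controls < 1:
        raise ParameterError("n_cases and n_controls must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cases + n_controls)
    records = []
    for i in range(n_cases):
        sub_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
        records.append(generate_subject(
            case_profile, acq, sub_seed, subject_id=f"case{i + 1:02d}", label=1
        ))
    for j in range(n_controls):
        sub_seed = int(children[n_cases + j].generate_state(1)[0] % (2 ** 31))
        records.append(generate_subject(
            control_profile, acq, sub_seed, subject_id=f"ctrl{j + 1:02d}", label=0
        ))
    return records
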