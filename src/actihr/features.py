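"""Per-subject assembly of the 36-feature vector.

Eighteen features per signal column: the five summary statistics, the five
rest-activity metrics, the four MSE cubic-fit coefficients, and the four TE
cubic-fit coefficients of one coupling direction.  The HR column carries
TE(HR -> activity) and the activity column TE(activity -> HR).

Residual missing slots that survive preprocessing are linearly interpolated
before entropy and transfer-entropy computation so templates and triples
are contiguous; summary statistics and rest-activity metrics simply skip
missing slots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import complexity, coupling, linear_features as lf
from .preprocessing import InputError, RegularSeries, SubjectRecord

MODE_RESOLUTION = {"hr": 1.0, "activity": 0.01}


def fill_missing(values: np.ndarray) -> np.ndarray:
    """Linear interpolation over slot index; edges filled with nearest value."""
    v = np.asarray(values, dtype=float).copy()
    miss = np.isnan(v)
    if not miss.any():
        return v
    if miss.all():
        raise InputError("series has no observed values")
    idx = np.arange(len(v))
    v[miss] = np.interp(idx[miss], idx[~miss], v[~miss])
    return v


def _signal_linear(series: RegularSeries, prefix: str) -> dict[str, float]:
    stats = lf.summary_stats(series.values, MODE_RESOLUTION[series.kind])
    profile = lf.mean_daily_profile(series)
    l5, m10, _, _ = lf.l5_m10(profile, series.interval)
    return {
        f"{prefix}_mean": stats.mean,
        f"{prefix}_median": stats.median,
        f"{prefix}_mode": stats.mode,
        f"{prefix}_std": stats.std,
        f"{prefix}_iqr": stats.iqr,
        f"{prefix}_l5": l5,
        f"{prefix}_m10": m10,
        f"{prefix}_ra": lf.relative_amplitude(l5, m10),
        f"{prefix}_is": lf.interdaily_stability(series),
        f"{prefix}_iv": lf.intradaily_variability(series),
    }


def extract_features(
    record: SubjectRecord,
    m: int = 1,
    r_fraction: float = 0.1,
    te_alpha: float = 0.05,
    te_min_expected: float = 5.0,
    te_min_triples: int = coupling.MIN_TRIPLES,
) -> dict[str, float]:
    """The 36 named features of one preprocessed subject."""
    if record.hr is None or record.activity is None or record.activity_10min is None:
        raise InputError("extract_features requires a preprocessed record")
    out: dict[str, float] = {}
    out.update(_signal_linear(record.hr, "hr"))
    out.update(_signal_linear(record.activity, "act"))

    hr_filled = fill_missing(record.hr.values)
    act5_filled = fill_missing(record.activity.values)
    act10_filled = fill_missing(record.activity_10min.values)

    for prefix, values in (("hr", hr_filled), ("act", act5_filled)):
        prof = complexity.mse_profile(values, m=m, r_fraction=r_fraction)
        for i in range(4):
            out[f"{prefix}_mse{i + 1}"] = prof.coeffs[i]

    for name, src, dst in (
        ("te_hr_act", hr_filled, act10_filled),
        ("te_act_hr", act10_filled, hr_filled),
    ):
        prof = coupling.te_profile(
            src, dst, direction=name, alpha=te_alpha,
            min_expected=te_min_expected, min_triples=te_min_triples,
        )
        for i in range(4):
            out[f"{name}_{i + 1}"] = prof.coeffs[i]
    return out


def build_feature_matrix(records: list[SubjectRecord], **kwargs) -> pd.DataFrame:
    """Feature rows for a cohort, indexed by subject id, with a ``label`` column."""
    rows = []
    for rec in records:
        row = {"subject_id": rec.subject_id, "label": rec.label}
        row.update(extract_features(rec, **kwargs))
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
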