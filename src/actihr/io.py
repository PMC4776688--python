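"""Long-format CSV exchange for cohorts of paired HR/activity recordings.

Schema (one row per sample)::

    subject_id, group, signal, timestamp, value

``group`` is 0 (control) / 1 (case); ``signal`` is ``hr`` or ``activity``;
``timestamp`` is ISO-8601 UTC.  Internally all times are float minutes since
local midnight of the subject's first recording day, so the reader anchors
each subject at the midnight preceding its earliest sample.
"""

from __future__ import annotations

import pandas as pd

from .preprocessing import SampleSeries, SubjectRecord

EPOCH = pd.Timestamp("2026-01-05 00:00:00", tz="UTC")


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for series in (rec.hr_raw, rec.act_raw):
            ts = EPOCH + pd.to_timedelta(series.t, unit="m")
            rows.append(pd.DataFrame({
                "subject_id": rec.subject_id,
                "group": rec.label,
                "signal": series.kind,
                "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
                "value": series.v,
            }))
    return pd.concat(rows, ignore_index=True)


def write_cohort_csv(records: list[SubjectRecord], path: str) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "group", "signal", "timestamp", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    records = []
    for sid, sub in df.groupby("subject_id", sort=True):
        anchor = sub["timestamp"].min().normalize()
        series = {}
        for kind, chunk in sub.groupby("signal"):
            chunk = chunk.sort_values("timestamp")
            minutes = (chunk["timestamp"] - anchor).dt.total_seconds().to_numpy() / 60.0
            series[kind] = SampleSeries(kind, minutes, chunk["value"].to_numpy())
        if "hr" not in series or "activity" not in series:
            raise ValueError(f"subject {sid} lacks one of the two signals")
        records.append(SubjectRecord(
            subject_id=str(sid),
            label=int(sub["group"].iloc[0]),
            hr_raw=series["hr"],
            act_raw=series["activity"],
        ))
    return records
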