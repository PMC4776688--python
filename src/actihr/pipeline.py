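"""End-to-end orchestration: simulate -> preprocess -> features -> classify.

A run is fully determined by a :class:`RunConfig` (every tunable defaults to
the study protocol: 10-min HR / 5-min activity grids, 10% quality gate,
best 10 days, SampEn m = 1 and r = 0.1 x STD, TE with k = l = t = 1 and
tau = 1..5, RBF-SVM with sigma = 4 and 1000 random-subsampling repeats).
All artifacts are open formats (CSV/JSON) plus a machine-readable manifest
with a config hash, per-stage counts, and every rejected subject with its
reason, so the cohort attrition is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import build_feature_matrix
from .io import read_cohort_csv, write_cohort_csv
from .modeling import (
    ALL_FEATURES,
    ClassifierConfig,
    group_compare,
    mrmr_rank,
    run_feature_set_experiments,
)
from .preprocessing import RecordRejected, preprocess_subject
from .synthetic import AcquisitionModel, generate_cohort, inject_artifacts, load_profiles


@dataclass
class RunConfig:
    seed: int = 0
    n_cases: int = 16
    n_controls: int = 19
    n_corrupted_cases: int = 4
    corrupt_artifact_rate: float = 0.15
    record_days: int = 21
    profile_path: str | None = None
    input_csv: str | None = None     # read a cohort instead of simulating
    gate_threshold: float = 0.10
    n_selected_days: int = 10
    sampen_m: int = 1
    sampen_r_fraction: float = 0.1
    te_alpha: float = 0.05
    te_min_expected: float = 5.0
    te_min_triples: int = 500
    sigma: float = 4.0
    cost: float = 1.0
    n_repeats: int = 1000
    max_k: int = 10
    write_cohort: bool = False

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunResult:
    outdir: Path
    features: pd.DataFrame
    experiments: dict
    comparison: object
    manifest: dict = field(default_factory=dict)


def _build_cohort(config: RunConfig) -> list:
    if config.input_csv is not None:
        return read_cohort_csv(config.input_csv)
    profiles = load_profiles(config.profile_path)
    acq: AcquisitionModel = profiles["acquisition"]
    acq = AcquisitionModel(
        hr_interval_mean=acq.hr_interval_mean,
        act_interval_mean=acq.act_interval_mean,
        interval_jitter_sd=acq.interval_jitter_sd,
        dropout_rate=acq.dropout_rate,
        artifact_rate=acq.artifact_rate,
        record_days=config.record_days,
    )
    cohort = generate_cohort(
        config.n_cases, config.n_controls,
        profiles["case"], profiles["control"], acq, seed=config.seed,
    )
    if config.n_corrupted_cases > 0:
        corrupt_acq = AcquisitionModel(
            hr_interval_mean=acq.hr_interval_mean,
            act_interval_mean=acq.act_interval_mean,
            interval_jitter_sd=acq.interval_jitter_sd,
            dropout_rate=acq.dropout_rate,
            artifact_rate=config.corrupt_artifact_rate,
            record_days=config.record_days,
        )
        ss = np.random.SeedSequence([config.seed, 0xC0]).spawn(config.n_corrupted_cases)
        for i in range(min(config.n_corrupted_cases, config.n_cases)):
            sub_seed = int(ss[i].generate_state(1)[0] % (2 ** 31))
            cohort[i] = inject_artifacts(cohort[i], corrupt_acq, seed=sub_seed)
    return cohort


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute every stage and write all artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _build_cohort(config)
    if config.write_cohort:
        write_cohort_csv(cohort, str(outdir / "cohort.csv"))

    accepted, rejected, reports = [], [], {}
    for rec in cohort:
        try:
            rec, decision = preprocess_subject(
                rec, n_days=config.n_selected_days, gate_threshold=config.gate_threshold
            )
        except RecordRejected as exc:
            rejected.append({"subject_id": rec.subject_id, "reasons": [str(exc)]})
            continue
        reports[rec.subject_id] = rec.quality
        if decision.accepted:
            accepted.append(rec)
        else:
            rejected.append({"subject_id": rec.subject_id, "reasons": decision.reasons})
    (outdir / "preprocessing_report.json").write_text(
        json.dumps({"subjects": reports,
                    "rejected": rejected}, indent=2, default=float)
    )

    features = build_feature_matrix(
        accepted,
        m=config.sampen_m,
        r_fraction=config.sampen_r_fraction,
        te_alpha=config.te_alpha,
        te_min_expected=config.te_min_expected,
        te_min_triples=config.te_min_triples,
    )
    features.to_csv(outdir / "features.csv")
    labels = features["label"].to_numpy()
    X = features.drop(columns=["label"])

    comparison = group_compare(X, labels)
    comparison.table.to_csv(outdir / "group_comparison.csv", index=False)

    from .modeling import impute_missing
    global_ranking = mrmr_rank(impute_missing(X)[ALL_FEATURES], labels)
    global_ranking.to_frame().to_csv(outdir / "ranking_all.csv", index=False)

    clf = ClassifierConfig(sigma=config.sigma, cost=config.cost)
    experiments = run_feature_set_experiments(
        X, labels, clf, n_repeats=config.n_repeats,
        seed=config.seed, max_k=config.max_k,
    )
    metrics = {}
    for name, exp in experiments.items():
        exp.ranking.to_frame().to_csv(outdir / f"ranking_{name}.csv", index=False)
        pd.DataFrame(exp.best.roc_points, columns=["fpr", "tpr"]).to_csv(
            outdir / f"roc_{name}.csv", index=False
        )
        metrics[name] = {
            "accuracy": exp.best.accuracy,
            "sensitivity": exp.best.sensitivity,
            "specificity": exp.best.specificity,
            "auc": exp.best.auc,
            "n_repeats": exp.best.n_repeats,
            "seed": exp.best.seed,
            "selected_features": exp.best.features,
            "accuracy_by_k": exp.accuracy_by_k,
            "note": "feature ranking computed on the full dataset before "
                    "cross-validation; prefix accuracies are optimistically biased",
        }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))

    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "software_version": __version__,
        "n_simulated": len(cohort),
        "n_accepted": len(accepted),
        "n_rejected": len(rejected),
        "rejected": rejected,
        "n_features": X.shape[1],
        "stages": {
            "cohort": len(cohort),
            "preprocessed": len(reports),
            "feature_rows": len(features),
            "experiments": list(experiments),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return RunResult(outdir, features, experiments, comparison, manifest)


def render_report(outdir: str | Path) -> str:
    """Human-readable run summary (feature table + experiment comparison)."""
    outdir = Path(outdir)
    missing = [
        name for name in ("features.csv", "group_comparison.csv",
                          "ranking_all.csv", "metrics.json", "manifest.json")
        if not (outdir / name).exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing artifacts: {missing}")
    features = pd.read_csv(outdir / "features.csv", index_col=0)
    comp = pd.read_csv(outdir / "group_comparison.csv")
    ranking = pd.read_csv(outdir / "ranking_all.csv")
    metrics = json.loads((outdir / "metrics.json").read_text())

    labels = features["label"]
    lines = ["# Run report", "", "## Features (group mean +/- STD)", ""]
    if labels.nunique() < 2:
        lines.append("WARNING: only one group present; group columns collapse.")
    rank_of = dict(zip(ranking["feature"], ranking["rank"]))
    sig_of = dict(zip(comp["feature"], comp["significant"]))
    lines.append("| feature | case | control | mRMR rank | significant |")
    lines.append("|---|---|---|---|---|")
    for col in features.columns.drop("label"):
        case = features.loc[labels == 1, col]
        ctrl = features.loc[labels == 0, col]
        lines.append(
            f"| {col} | {case.mean():.3f} +/- {case.std():.3f} "
            f"| {ctrl.mean():.3f} +/- {ctrl.std():.3f} "
            f"| {rank_of.get(col, '-')} | {'yes' if sig_of.get(col) else 'no'} |"
        )
    lines += ["", "## Classification experiments", "",
              "| feature set | k | accuracy % | sensitivity % | specificity % | AUC |",
              "|---|---|---|---|---|---|"]
    for name, m in metrics.items():
        lines.append(
            f"| {name} | {len(m['selected_features'])} | {m['accuracy']:.1f} "
            f"| {m['sensitivity']:.1f} | {m['specificity']:.1f} | {m['auc']:.3f} |"
        )
    report = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(report)
    return report
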