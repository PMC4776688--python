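"""Feature selection and classification.

Implements the evaluation half of the pipeline: per-feature discretization
into five states at Mean + {-1, -0.5, +0.5, +1} x STD, plug-in discrete
mutual information, incremental mRMR ranking under the Mutual Information
Difference (MID) scheme

    score(x) = I(x; c) - (1/|S|) * sum_{s in S} I(x; s),

RBF-kernel SVM evaluation under repeated random-subsampling two-fold
cross-validation (1000 repeats by default), pooled-score ROC/AUC, and
Wilcoxon rank-sum group screening with Bonferroni correction.

The kernel width follows the sigma convention K(u, v) =
exp(-||u - v||^2 / (2 sigma^2)) with sigma = 4; features are z-scored with
training-half statistics so a shared sigma is meaningful across mixed-unit
features.  Feature selection is performed once on the full dataset before
cross-validation (the dataset-level ranking is itself a reported output);
the optimistic bias this induces is noted in the run report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .preprocessing import ParameterError

N_STATES = 5
DEFAULT_SIGMA = 4.0
DEFAULT_COST = 1.0
DEFAULT_REPEATS = 1000
ALPHA = 0.05


def discretize_feature(values: np.ndarray) -> np.ndarray:
    """Discretize one feature into five ordinal states.

    Bin edges sit at mu - sigma, mu - 0.5 sigma, mu + 0.5 sigma, mu + sigma
    computed over all subjects; a value exactly on an edge goes to the upper
    bin.  A zero-variance feature collapses to the middle state with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2 or len(np.unique(v)) < 2:
        warnings.warn("zero-variance feature discretized to a single state")
        return np.full(len(v), 3, dtype=int)
    mu, sd = v.mean(), v.std(ddof=1)
    edges = mu + sd * np.array([-1.0, -0.5, 0.5, 1.0])
    return np.searchsorted(edges, v, side="right") + 1


def mutual_information_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete label sequences."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ParameterError("label sequences must be equally long")
    n = len(a)
    joint = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy() / n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


@dataclass
class MRMRRanking:
    order: list[str]
    relevance: list[float]
    redundancy: list[float]
    score: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.order,
            "rank": np.arange(1, len(self.order) + 1),
            "relevance": self.relevance,
            "redundancy": self.redundancy,
            "score": self.score,
        })


def mrmr_rank(features: pd.DataFrame, labels: np.ndarray) -> MRMRRanking:
    """Full incremental mRMR (MID) ordering of the feature columns.

    Features are discretized internally; the first pick maximizes relevance
    I(x; c), each subsequent pick maximizes relevance minus mean mutual
    information with the already-selected set.  Ties break lexicographically
    on the feature name.
    """
    if features.shape[1] == 0:
        raise ParameterError("empty feature matrix")
    names = list(features.columns)
    disc = {nm: discretize_feature(features[nm].to_numpy()) for nm in names}
    c = np.asarray(labels)
    relevance = {nm: mutual_information_discrete(disc[nm], c) for nm in names}

    order: list[str] = []
    rel_out: list[float] = []
    red_out: list[float] = []
    score_out: list[float] = []
    remaining = sorted(names)
    mi_cache: dict[tuple[str, str], float] = {}

    def mi(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in mi_cache:
            mi_cache[key] = mutual_information_discrete(disc[a], disc[b])
        return mi_cache[key]

    while remaining:
        best_name, best = None, None
        for nm in remaining:  # lexicographic scan: first strict max wins ties
            red = np.mean([mi(nm, s) for s in order]) if order else 0.0
            sc = relevance[nm] - red
            if best is None or sc > best[0] + 1e-12:
                best, best_name = (sc, red), nm
        order.append(best_name)
        remaining.remove(best_name)
        rel_out.append(relevance[best_name])
        red_out.append(best[1])
        score_out.append(best[0])
    return MRMRRanking(order, rel_out, red_out, score_out)


@dataclass
class ClassifierConfig:
    sigma: float = DEFAULT_SIGMA
    cost: float = DEFAULT_COST
    standardize: bool = True
    test_both_halves: bool = True

    @property
    def gamma(self) -> float:
        """sklearn gamma equivalent of the sigma kernel-width convention."""
        return 1.0 / (2.0 * self.sigma ** 2)


@dataclass
class CVResult:
    accuracy: float      # percent over repeats
    sensitivity: float   # percent, true-positive rate on cases (label 1)
    specificity: float   # percent, true-negative rate on controls
    auc: float
    roc_points: np.ndarray  # (fpr, tpr) rows of the pooled-score ROC
    per_repeat: pd.DataFrame
    n_repeats: int
    seed: int
    features: list[str] = field(default_factory=list)
    n_redraws: int = 0


def _stratified_half(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of a random stratified half (training split)."""
    mask = np.zeros(len(y), dtype=bool)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        mask[idx[: len(idx) // 2 + len(idx) % 2 * rng.integers(0, 2)]] = True
    return mask


def _fold_scores(X_tr, y_tr, X_te, config: ClassifierConfig):
    if config.standardize:
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        X_tr = (X_tr - mu) / sd
        X_te = (X_te - mu) / sd
    clf = SVC(C=config.cost, kernel="rbf", gamma=config.gamma)
    clf.fit(X_tr, y_tr)
    return clf.decision_function(X_te), clf.predict(X_te)


def _confusion_rates(y_true, y_pred):
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return acc, sens, spec


def evaluate_classifier(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_subset: list[str] | None = None,
    config: ClassifierConfig | None = None,
    n_repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> CVResult:
    """Repeated random-subsampling two-fold cross-validation of the RBF-SVM.

    Each repeat draws a stratified 50/50 split; the model is trained on one
    half and tested on the other (and, by default, the roles are swapped so
    both halves are tested per repeat).  Accuracy, sensitivity and
    specificity are averaged over repeats; the ROC is a single curve built
    from the decision scores pooled across all test folds, with AUC by the
    trapezoid rule.  Deterministic for a fixed seed.
    """
    config = config or ClassifierConfig()
    y = np.asarray(labels)
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ParameterError("need at least 2 subjects per class")
    cols = feature_subset if feature_subset is not None else list(features.columns)
    X = features[cols].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    rows = []
    pooled_scores, pooled_truth = [], []
    n_redraws = 0
    for rep in range(n_repeats):
        while True:
            train = _stratified_half(y, rng)
            if len(np.unique(y[train])) == 2 and len(np.unique(y[~train])) == 2:
                break
            n_redraws += 1
        folds = [(train, ~train)]
        if config.test_both_halves:
            folds.append((~train, train))
        accs, senss, specs = [], [], []
        for tr, te in folds:
            scores, pred = _fold_scores(X[tr], y[tr], X[te], config)
            pooled_scores.append(scores)
            pooled_truth.append(y[te])
            a, s, p = _confusion_rates(y[te], pred)
            accs.append(a)
            senss.append(s)
            specs.append(p)
        rows.append((np.mean(accs), np.nanmean(senss), np.nanmean(specs)))

    per_repeat = pd.DataFrame(rows, columns=["accuracy", "sensitivity", "specificity"])
    scores = np.concatenate(pooled_scores)
    truth = np.concatenate(pooled_truth)
    fpr, tpr, _ = roc_curve(truth, scores)
    return CVResult(
        accuracy=100.0 * per_repeat["accuracy"].mean(),
        sensitivity=100.0 * per_repeat["sensitivity"].mean(),
        specificity=100.0 * per_repeat["specificity"].mean(),
        auc=float(trapezoid_auc(fpr, tpr)),
        roc_points=np.column_stack([fpr, tpr]),
        per_repeat=per_repeat,
        n_repeats=n_repeats,
        seed=seed,
        features=list(cols),
        n_redraws=n_redraws,
    )


HR_FEATURES = [
    "hr_mean", "hr_median", "hr_mode", "hr_std", "hr_iqr",
    "hr_l5", "hr_m10", "hr_ra", "hr_is", "hr_iv",
    "hr_mse1", "hr_mse2", "hr_mse3", "hr_mse4",
]
ACT_FEATURES = [
    "act_mean", "act_median", "act_mode", "act_std", "act_iqr",
    "act_l5", "act_m10", "act_ra", "act_is", "act_iv",
    "act_mse1", "act_mse2", "act_mse3", "act_mse4",
]
TE_FEATURES = [
    "te_hr_act_1", "te_hr_act_2", "te_hr_act_3", "te_hr_act_4",
    "te_act_hr_1", "te_act_hr_2", "te_act_hr_3", "te_act_hr_4",
]
ALL_FEATURES = HR_FEATURES + ACT_FEATURES + TE_FEATURES

FEATURE_SETS = {
    "hr": HR_FEATURES,
    "activity": ACT_FEATURES,
    "fused": ALL_FEATURES,
}


@dataclass
class ExperimentResult:
    feature_set: str
    ranking: MRMRRanking
    best_k: int
    best: CVResult
    accuracy_by_k: list[float]


def impute_missing(features: pd.DataFrame) -> pd.DataFrame:
    """Column-median imputation of flagged-unavailable feature values."""
    out = features.copy()
    for col in out.columns:
        med = out[col].median()
        out[col] = out[col].fillna(0.0 if np.isnan(med) else med)
    return out


def run_feature_set_experiments(
    features: pd.DataFrame,
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
    n_repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    max_k: int = 10,
    feature_sets: dict[str, list[str]] | None = None,
) -> dict[str, ExperimentResult]:
    """HR-only, activity-only and fused classification experiments.

    For each feature set the features are re-ranked by mRMR within the set,
    top-k prefixes for k = 1..max_k are evaluated, and the best-accuracy
    prefix is reported (ties to the smaller k).
    """
    config = config or ClassifierConfig()
    feature_sets = feature_sets or FEATURE_SETS
    X = impute_missing(features)
    results = {}
    ss = np.random.SeedSequence(seed)
    for name, cols in feature_sets.items():
        cols = [c for c in cols if c in X.columns]
        ranking = mrmr_rank(X[cols], labels)
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        accs, best = [], None
        for k in range(1, min(max_k, len(cols)) + 1):
            res = evaluate_classifier(
                X, labels, ranking.order[:k], config, n_repeats, seed=sub_seed
            )
            accs.append(res.accuracy)
            if best is None or res.accuracy > best[1].accuracy + 1e-9:
                best = (k, res)
        results[name] = ExperimentResult(name, ranking, best[0], best[1], accs)
    return results


@dataclass
class GroupComparison:
    table: pd.DataFrame  # feature, p_raw, p_adjusted, significant
    alpha: float = ALPHA


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact for small untied samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= 25) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def group_compare(
    features: pd.DataFrame, labels: np.ndarray, alpha: float = ALPHA
) -> GroupComparison:
    """Per-feature Wilcoxon rank-sum screen with Bonferroni correction.

    The Bonferroni factor is the number of features tested; adjusted
    p-values are capped at 1 and flagged significant at ``alpha``.
    """
    y = np.asarray(labels)
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ParameterError("both groups must be nonempty")
    m = features.shape[1]
    rows = []
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        keep = ~np.isnan(v)
        p = rank_sum_p(v[keep & (y == 1)], v[keep & (y == 0)])
        p_adj = min(1.0, p * m)
        rows.append((col, p, p_adj, p_adj < alpha))
    table = pd.DataFrame(rows, columns=["feature", "p_raw", "p_adjusted", "significant"])
    return GroupComparison(table=table, alpha=alpha)
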