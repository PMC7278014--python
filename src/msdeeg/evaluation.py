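"""Classification, cross-validation and the confusion-matrix metric suite.

Two binary tasks are supported:

* ``stress_vs_rest`` — task-state (serial-subtraction arithmetic) trials
  against rest-state trials; the stress state is the positive class.
* ``levels`` — low- against high-stress subjects, classified from their
  task-state trials only; high stress is the positive class.

Five classifiers are wrapped behind one spec: linear discriminant analysis,
linear and cubic (degree-3 polynomial kernel) support-vector machines,
1-nearest-neighbour with Euclidean distance, and a random forest. Validation
is either stratified 5-fold over trials or leave-one-subject-out (all trials
of one subject form the test fold), and every fold is scored with accuracy,
sensitivity, specificity, the Goodness Index sqrt((1-Se)^2 + (1-Sp)^2),
precision, Matthews correlation and the diagnostic odds ratio
DOR = (TP*TN)/(FP*FN).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "TASKS",
    "ClassifierSpec",
    "FoldPlan",
    "ConfusionCounts",
    "MetricReport",
    "make_classifier",
    "task_labels",
    "select_task_trials",
    "make_folds",
    "train_and_predict",
    "compute_metrics",
    "summarize_with_ci",
    "reliability_gate",
    "run_validation",
]

TASKS = ("stress_vs_rest", "levels")
METRICS = ("accuracy", "sensitivity", "specificity", "goodness_index",
           "precision", "mcc", "dor")
CLASSIFIER_KINDS = ("lda", "svm_linear", "svm_cubic", "knn", "random_forest")


@dataclass
class ClassifierSpec:
    """One of the five classification models, with its hyperparameters.

    Defaults: 1-NN uses Euclidean distance with K=1; the cubic SVM a
    degree-3 polynomial kernel; the random forest 100 trees with sqrt(p)
    features per split.
    """

    kind: str = "knn"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator behind a classifier spec."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if spec.kind == "svm_linear":
        hp.setdefault("kernel", "linear")
        hp.setdefault("C", 1.0)
        return SVC(random_state=spec.seed, **hp)
    if spec.kind == "svm_cubic":
        hp.setdefault("kernel", "poly")
        hp.setdefault("degree", 3)
        hp.setdefault("C", 1.0)
        return SVC(random_state=spec.seed, **hp)
    if spec.kind == "knn":
        hp.setdefault("n_neighbors", 1)
        hp.setdefault("metric", "euclidean")
        return KNeighborsClassifier(**hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=spec.seed, **hp)
    raise ValueError(spec.kind)


# ---------------------------------------------------------------------------
# labels and folds


def task_labels(labels: pd.DataFrame, task: str) -> np.ndarray:
    """Binary target vector (1 = positive class) for a task."""
    if task == "stress_vs_rest":
        return (labels["state"].to_numpy() == "task").astype(int)
    if task == "levels":
        return (labels["group"].to_numpy() == "high_stress").astype(int)
    raise ValueError(f"task must be one of {TASKS}")


def select_task_trials(fm: FeatureMatrix, task: str,
                       levels_task_state_only: bool = True) -> FeatureMatrix:
    """Restrict a feature matrix to the trials relevant for a task.

    For the stress-level task only task-state trials are kept by default
    (rest-state activity does not separate the two groups); the detection
    task uses all trials.
    """
    if task == "levels" and levels_task_state_only:
        mask = (fm.labels["state"] == "task").to_numpy()
        return fm.subset_rows(mask)
    return fm


@dataclass
class FoldPlan:
    """Assignment of every trial to exactly one test fold."""

    scheme: str  # "kfold5" | "leave_subject_out"
    assignments: np.ndarray
    seed: int
    fold_names: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return int(self.assignments.max()) + 1


def make_folds(fm: FeatureMatrix, scheme: str = "kfold5", seed: int = 0,
               task: str = "stress_vs_rest") -> FoldPlan:
    """Build a fold plan over the trials of a feature matrix.

    ``kfold5`` stratifies by the task's class labels; ``leave_subject_out``
    makes one fold per subject so test subjects never contribute training
    trials.
    """
    labels = fm.labels
    n = len(labels)
    if scheme == "kfold5":
        y = task_labels(labels, task)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        assignments = np.full(n, -1, dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), y)):
            assignments[test_idx] = f
        return FoldPlan(scheme=scheme, assignments=assignments, seed=seed,
                        fold_names=[f"fold{f + 1}" for f in range(5)])
    if scheme == "leave_subject_out":
        subjects = sorted(labels["subject_id"].unique())
        if len(subjects) < 2:
            raise ValueError("leave-subject-out needs at least 2 subjects")
        index = {s: i for i, s in enumerate(subjects)}
        assignments = labels["subject_id"].map(index).to_numpy()
        return FoldPlan(scheme=scheme, assignments=assignments, seed=seed,
                        fold_names=list(subjects))
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# confusion counts and metrics


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return ConfusionCounts(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def compute_metrics(counts: ConfusionCounts) -> dict:
    """The seven confusion-matrix metrics of one fold.

    Rates are returned as fractions in [0, 1]. The diagnostic odds ratio is
    flagged infinite when there are no errors at all (FP = FN = 0); with any
    other zero cell a 0.5 continuity correction is applied to every cell and
    flagged.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion table")

    def _ratio(a: float, b: float) -> float:
        return a / b if b > 0 else float("nan")

    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    acc = (tp + tn) / counts.total
    prec = _ratio(tp, tp + fp)
    g = math.sqrt((1 - se) ** 2 + (1 - sp) ** 2) if not (math.isnan(se) or math.isnan(sp)) else float("nan")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / mcc_den) if mcc_den > 0 else 0.0

    dor_infinite = fp == 0 and fn == 0 and tp > 0 and tn > 0
    dor_corrected = False
    if dor_infinite:
        dor = float("inf")
    elif min(tp, tn, fp, fn) == 0:
        dor_corrected = True
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    else:
        dor = (tp * tn) / (fp * fn)

    return {
        "accuracy": acc,
        "sensitivity": se,
        "specificity": sp,
        "goodness_index": g,
        "precision": prec,
        "mcc": mcc,
        "dor": dor,
        "dor_infinite": dor_infinite,
        "dor_corrected": dor_corrected,
    }


@dataclass
class MetricReport:
    """Per-fold metrics with fold-mean point values and 95% CIs."""

    point: dict  # metric -> (mean, ci_low, ci_high)
    per_fold: list
    pooled: dict
    counts: list
    scheme: str = ""
    ci_method: str = "t"

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, float) and math.isinf(v):
                return "inf"
            return v

        return {
            "scheme": self.scheme,
            "ci_method": self.ci_method,
            "point": {m: [_clean(x) for x in v] for m, v in self.point.items()},
            "pooled": {m: _clean(v) for m, v in self.pooled.items()},
            "per_fold": [{m: _clean(v) for m, v in f.items()} for f in self.per_fold],
            "counts": [vars(c) for c in self.counts],
        }


def _t_interval(values: np.ndarray, level: float = 0.95):
    n = values.size
    mean = float(values.mean())
    if n < 2 or np.allclose(values, values[0]):
        return mean, mean, mean
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * values.std(ddof=1) / math.sqrt(n)
    return mean, mean - half, mean + half


def _bootstrap_interval(values: np.ndarray, seed: int, n_boot: int = 1000,
                        level: float = 0.95):
    rng = np.random.default_rng(seed)
    n = values.size
    means = rng.choice(values, size=(n_boot, n), replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 0.5 + level / 2])
    return float(values.mean()), float(lo), float(hi)


def summarize_with_ci(per_fold_counts: list[ConfusionCounts],
                      ci_method: str = "t", seed: int = 0,
                      scheme: str = "") -> MetricReport:
    """Aggregate per-fold confusion counts into a metric report.

    Point values are means over folds with 95% confidence intervals
    (Student-t by default, percentile bootstrap optionally). Metrics of the
    pooled (summed) confusion table are reported alongside. Infinite
    fold-level odds ratios are excluded from the mean/CI and surface as an
    infinite pooled value when the pooled table is error-free.
    """
    if len(per_fold_counts) < 2:
        raise ValueError("need at least two folds to summarize")
    per_fold = [compute_metrics(c) for c in per_fold_counts]
    point: dict = {}
    for m in METRICS:
        vals = np.array([f[m] for f in per_fold], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            point[m] = (float("inf"), float("inf"), float("inf"))
            continue
        if ci_method == "t":
            point[m] = _t_interval(vals)
        elif ci_method == "bootstrap":
            point[m] = _bootstrap_interval(vals, seed=seed)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    pooled_counts = sum(per_fold_counts, ConfusionCounts())
    pooled = compute_metrics(pooled_counts)
    return MetricReport(point=point, per_fold=per_fold, pooled=pooled,
                        counts=list(per_fold_counts), scheme=scheme,
                        ci_method=ci_method)


def reliability_gate(report: MetricReport) -> dict:
    """Check the reliability thresholds for a diagnostic system.

    Requires sensitivity >= 80%, specificity >= 95%, precision >= 95% and a
    diagnostic odds ratio >= 100, evaluated on the pooled confusion table.
    An infinite odds ratio passes its criterion.
    """
    p = report.pooled
    checks = {
        "sensitivity": p["sensitivity"] >= 0.80,
        "specificity": p["specificity"] >= 0.95,
        "precision": p["precision"] >= 0.95,
        "dor": math.isinf(p["dor"]) or p["dor"] >= 100.0,
    }
    checks["overall"] = all(checks.values())
    return checks


# ---------------------------------------------------------------------------
# training


def _build_pipeline(clf_spec: ClassifierSpec, standardize: bool,
                    n_components: int | None) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    if n_components is not None:
        steps.append(("pca", PCA(n_components=n_components)))
    steps.append(("clf", make_classifier(clf_spec)))
    return Pipeline(steps)


def train_and_predict(fm: FeatureMatrix, plan: FoldPlan,
                      clf_spec: ClassifierSpec, task: str = "stress_vs_rest",
                      standardize: bool = True,
                      n_components: int | None = None) -> list[ConfusionCounts]:
    """Fit and score the classifier fold by fold.

    Standardization (and PCA, when requested) is fitted on the training rows
    of each fold only, so no test information leaks into the model. Folds
    whose training rows contain a single class are skipped with a warning.
    """
    y = task_labels(fm.labels, task)
    X = fm.values
    out: list[ConfusionCounts] = []
    for f in range(plan.n_folds):
        test = plan.assignments == f
        train = ~test
        if test.sum() == 0:
            continue
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {f}: single-class training set, skipped")
            continue
        pipe = _build_pipeline(clf_spec, standardize, n_components)
        pipe.fit(X[train], y[train])
        pred = pipe.predict(X[test])
        out.append(ConfusionCounts.from_predictions(y[test], pred))
    return out


def run_validation(fm: FeatureMatrix, clf_spec: ClassifierSpec,
                   task: str = "stress_vs_rest", scheme: str = "kfold5",
                   seed: int = 0, standardize: bool = True,
                   n_components: int | None = None,
                   ci_method: str = "t") -> MetricReport:
    """Convenience wrapper: select trials, plan folds, train, summarize."""
    fm = select_task_trials(fm, task)
    plan = make_folds(fm, scheme=scheme, seed=seed, task=task)
    counts = train_and_predict(fm, plan, clf_spec, task=task,
                               standardize=standardize,
                               n_components=n_components)
    return summarize_with_ci(counts, ci_method=ci_method, seed=seed,
                             scheme=scheme)
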