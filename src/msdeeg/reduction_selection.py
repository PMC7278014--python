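"""Dimensionality reduction and electrode selection.

Two complementary reductions are implemented:

* Principal-component analysis of the feature matrix, with the number of
  retained components chosen by a sequential forward scan: classifier
  accuracy under 5-fold cross-validation is evaluated for k = 1, 2, ...
  leading (eigenvalue-ordered) components and the smallest k attaining the
  maximum is kept. PCA and standardization are refit inside each training
  fold so the scan is leakage-free; a ``pca_scope="global"`` option
  reproduces the simpler whole-data fit for comparison.

* Electrode ablation: features are rebuilt from channel subsets (the five
  scalp sites, single frontal electrodes, or small frontal fusions such as
  Fp1+Fp2) and each subset is scored with the full metric suite. Because
  every feature is computed from one channel alone, restricting the feature
  matrix to a channel's columns is identical to re-extracting features from
  the channel-restricted trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .evaluation import (ClassifierSpec, MetricReport, make_classifier,
                         make_folds, run_validation, select_task_trials,
                         task_labels)
from .features import FeatureMatrix, build_feature_matrix
from .segmentation import SegmentSet
from .signal_io import Montage, default_montage, normalize_label

__all__ = [
    "PCModel",
    "SearchTrace",
    "fit_pca",
    "project",
    "sequential_forward_pc_search",
    "SequentialPCSearch",
    "channel_subset_evaluation",
    "site_subsets",
    "frontal_single_subsets",
    "fusion_subsets",
]


@dataclass
class PCModel:
    """Fitted principal-component map of a feature matrix.

    ``loadings`` rows are orthonormal eigenvectors of the feature covariance
    matrix, ordered by nonincreasing eigenvalue.
    """

    means: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(fm: FeatureMatrix | np.ndarray) -> PCModel:
    """Eigendecompose the covariance of a feature matrix."""
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    pca = PCA(svd_solver="full")
    pca.fit(X)
    return PCModel(means=pca.mean_, loadings=pca.components_,
                   eigenvalues=pca.explained_variance_)


def project(fm: FeatureMatrix, model: PCModel,
            n_components: int | None = None) -> FeatureMatrix:
    """Project centered features onto the first ``n_components`` loadings."""
    k = model.n_components if n_components is None else int(n_components)
    if not 1 <= k <= model.n_components:
        raise ValueError(
            f"n_components must be in 1..{model.n_components}, got {k}"
        )
    scores = (fm.values - model.means) @ model.loadings[:k].T
    data = pd.DataFrame(scores, columns=[f"pc{i + 1}" for i in range(k)])
    return FeatureMatrix(data=data, labels=fm.labels.reset_index(drop=True),
                         feature_set=fm.feature_set)


@dataclass
class SearchTrace:
    """Accuracy-vs-component-count curve from the sequential forward scan."""

    ks: list[int]
    scores: list[float]

    @property
    def best_k(self) -> int:
        best = int(np.argmax(self.scores))  # argmax takes the first maximum
        return self.ks[best]

    @property
    def best_score(self) -> float:
        return float(max(self.scores))

    def to_dict(self) -> dict:
        return {"ks": self.ks, "scores": self.scores, "best_k": self.best_k,
                "best_score": self.best_score}


def sequential_forward_pc_search(fm: FeatureMatrix, clf_spec: ClassifierSpec,
                                 max_k: int | None = None,
                                 task: str = "stress_vs_rest", seed: int = 0,
                                 standardize: bool = True,
                                 pca_scope: str = "fold") -> SearchTrace:
    """Scan cross-validated accuracy over the number of leading components.

    For every k up to ``max_k`` the classifier is scored with 5-fold
    cross-validation on the first k principal components. With the default
    ``pca_scope="fold"`` the scaler and PCA are fitted on each training fold
    only (one fit per fold, shared by all k, since the leading k components
    of a fitted model do not depend on k); ``"global"`` fits them once on
    all rows before splitting.
    """
    fm = select_task_trials(fm, task)
    X = fm.values
    y = task_labels(fm.labels, task)
    p = X.shape[1]
    max_k = p if max_k is None else int(max_k)
    if not 1 <= max_k <= p:
        raise ValueError(f"max_k must be in 1..{p}, got {max_k}")
    if pca_scope not in ("fold", "global"):
        raise ValueError("pca_scope must be 'fold' or 'global'")

    plan = make_folds(fm, scheme="kfold5", seed=seed, task=task)

    if pca_scope == "global":
        Z_all = _scores(X, X, max_k, standardize)
        fold_scores = [(Z_all[plan.assignments != f], y[plan.assignments != f],
                        Z_all[plan.assignments == f], y[plan.assignments == f])
                       for f in range(plan.n_folds)]
    else:
        fold_scores = []
        for f in range(plan.n_folds):
            test = plan.assignments == f
            train = ~test
            Z_train = _scores(X[train], X[train], max_k, standardize)
            Z_test = _scores(X[train], X[test], max_k, standardize)
            fold_scores.append((Z_train, y[train], Z_test, y[test]))

    ks = list(range(1, max_k + 1))
    scores: list[float] = []
    for k in ks:
        correct = 0
        total = 0
        for Z_train, y_train, Z_test, y_test in fold_scores:
            clf = make_classifier(clf_spec)
            clf.fit(Z_train[:, :k], y_train)
            correct += int((clf.predict(Z_test[:, :k]) == y_test).sum())
            total += y_test.size
        scores.append(correct / total)
    return SearchTrace(ks=ks, scores=scores)


def _scores(X_fit: np.ndarray, X_apply: np.ndarray, k: int,
            standardize: bool) -> np.ndarray:
    if standardize:
        scaler = StandardScaler().fit(X_fit)
        X_fit = scaler.transform(X_fit)
        X_apply = scaler.transform(X_apply)
    k = min(k, min(X_fit.shape))
    pca = PCA(n_components=k, svd_solver="full").fit(X_fit)
    return pca.transform(X_apply)


class SequentialPCSearch:
    """scikit-learn-style estimator wrapping the component-count scan.

    ``fit(X, y)`` runs the scan and refits scaler + PCA + classifier with the
    selected count on all rows; fitted attributes carry the trailing
    underscore convention (``trace_``, ``best_k_``).
    """

    def __init__(self, clf_spec: ClassifierSpec | None = None,
                 max_k: int | None = None, seed: int = 0,
                 standardize: bool = True, pca_scope: str = "fold"):
        self.clf_spec = clf_spec
        self.max_k = max_k
        self.seed = seed
        self.standardize = standardize
        self.pca_scope = pca_scope

    def fit(self, X: np.ndarray, y: np.ndarray):
        spec = self.clf_spec or ClassifierSpec(kind="knn", seed=self.seed)
        labels = pd.DataFrame({
            "subject_id": ["?"] * len(y),
            "state": np.where(np.asarray(y) == 1, "task", "rest"),
            "group": ["unknown"] * len(y),
        })
        fm = FeatureMatrix(
            data=pd.DataFrame(np.asarray(X, float),
                              columns=[f"x{i}" for i in range(np.shape(X)[1])]),
            labels=labels, feature_set="set3")
        self.trace_ = sequential_forward_pc_search(
            fm, spec, max_k=self.max_k, seed=self.seed,
            standardize=self.standardize, pca_scope=self.pca_scope)
        self.best_k_ = self.trace_.best_k
        self._scaler = StandardScaler().fit(X) if self.standardize else None
        Xs = self._scaler.transform(X) if self._scaler is not None else X
        self._pca = PCA(n_components=self.best_k_, svd_solver="full").fit(Xs)
        self._clf = make_classifier(spec).fit(self._pca.transform(Xs), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self._scaler.transform(X) if self._scaler is not None else X
        return self._clf.predict(self._pca.transform(Xs))

    def get_params(self, deep: bool = True) -> dict:
        return {"clf_spec": self.clf_spec, "max_k": self.max_k,
                "seed": self.seed, "standardize": self.standardize,
                "pca_scope": self.pca_scope}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


# ---------------------------------------------------------------------------
# electrode subsets


def site_subsets(montage: Montage | None = None) -> dict[str, list[str]]:
    """The five scalp sites of the montage as named channel subsets."""
    montage = montage or default_montage()
    return {site: list(labels) for site, labels in montage.site_map.items()}


def frontal_single_subsets(montage: Montage | None = None) -> dict[str, list[str]]:
    """Each of the seven frontal electrodes as a one-channel subset."""
    montage = montage or default_montage()
    return {ch: [ch] for ch in montage.site("frontal")}


def fusion_subsets() -> dict[str, list[str]]:
    """The small frontal fusions examined for a minimal-electrode system."""
    return {
        "Fp1+Fp2": ["Fp1", "Fp2"],
        "Fp1+F8": ["Fp1", "F8"],
        "Fp1+F7+F8": ["Fp1", "F7", "F8"],
    }


def _dedupe(subsets: dict[str, list[str]] | list[list[str]]) -> dict[str, list[str]]:
    if isinstance(subsets, dict):
        items = list(subsets.items())
    else:
        items = [("+".join(s), list(s)) for s in subsets]
    out: dict[str, list[str]] = {}
    seen: set[tuple[str, ...]] = set()
    for name, labels in items:
        labels = [normalize_label(l) for l in labels]
        if not labels:
            raise ValueError(f"empty channel subset {name!r}")
        key = tuple(labels)
        if key in seen:
            warnings.warn(f"duplicate channel subset {name!r} dropped")
            continue
        seen.add(key)
        out[name] = labels
    return out


def channel_subset_evaluation(
    segs_or_fm: SegmentSet | FeatureMatrix,
    subsets: dict[str, list[str]] | list[list[str]],
    clf_specs: list[ClassifierSpec],
    task: str = "stress_vs_rest",
    scheme: str = "kfold5",
    seed: int = 0,
    feature_set: str = "set3",
    standardize: bool = True,
    ci_method: str = "t",
) -> dict[tuple[str, str], MetricReport]:
    """Score every channel subset with every classifier.

    Accepts either a segment set (features are extracted once on the full
    montage, then restricted per subset — features being per-channel, this
    equals rebuilding them from the restricted trials) or an already built
    feature matrix. Returns reports keyed by (subset name, classifier kind).
    Folds are planned identically (same seed) for every subset, so the
    all-channels subset reproduces the full-montage result exactly.
    """
    subsets = _dedupe(subsets)
    if isinstance(segs_or_fm, SegmentSet):
        fm_full = build_feature_matrix(segs_or_fm, set_tag=feature_set)
    else:
        fm_full = segs_or_fm
    reports: dict[tuple[str, str], MetricReport] = {}
    for name, labels in subsets.items():
        fm = fm_full.select_channels(labels)
        for spec in clf_specs:
            reports[(name, spec.kind)] = run_validation(
                fm, spec, task=task, scheme=scheme, seed=seed,
                standardize=standardize, ci_method=ci_method)
    return reports


def reports_to_table(reports: dict[tuple[str, str], MetricReport]) -> pd.DataFrame:
    """Flatten subset/classifier reports into a tidy percentage table."""
    rows = []
    for (subset, clf), rep in reports.items():
        row = {"subset": subset, "classifier": clf}
        for m, (mean, lo, hi) in rep.point.items():
            scale = 100.0 if m not in ("goodness_index", "dor") else 1.0
            row[m] = mean * scale
            row[f"{m}_ci_low"] = lo * scale
            row[f"{m}_ci_high"] = hi * scale
        rows.append(row)
    return pd.DataFrame(rows)
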