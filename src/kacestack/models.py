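"""Baseline classifiers: construction, grid search and cross-validation.

Five tree-ensemble families (RF, ERT, GB, AB, XGB) serve as baseline
models; SVM (RBF) joins them as a candidate meta-classifier only.  All
cross-validation is stratified k-fold (default 5) with shuffling driven
by an explicit seed, and model selection maximizes the cross-validated
MCC computed from pooled out-of-fold predictions.  Grid search is
exhaustive over the Cartesian product of the candidate lists, in grid
order; ties keep the earlier candidate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .evaluation import EvalReport, evaluate

# we deliberately keep SVC's native probability outputs (Platt scaling)
warnings.filterwarnings(
    "ignore", message=".*`probability` parameter.*", category=FutureWarning
)

FAMILIES = ("RF", "ERT", "GB", "AB", "XGB", "SVM")
TREE_FAMILIES = ("RF", "ERT", "GB", "AB", "XGB")

DECISION_THRESHOLD = 0.5


class ModelError(RuntimeError):
    pass


def default_grid(family: str) -> dict[str, list]:
    """Default hyperparameter grids (configurable; replace at will)."""
    if family in ("RF", "ERT"):
        return {"n_estimators": [100, 300, 500], "max_depth": [4, 8, None]}
    if family == "GB":
        return {"n_estimators": [100, 300], "learning_rate": [0.01, 0.1, 0.3],
                "max_depth": [4, 8]}
    if family == "AB":
        return {"n_estimators": [100, 300, 500],
                "learning_rate": [0.01, 0.1, 0.3]}
    if family == "XGB":
        return {"n_estimators": [100, 300], "learning_rate": [0.01, 0.1, 0.3],
                "max_depth": [4, 8]}
    if family == "SVM":
        return {"C": [2.0 ** e for e in range(-5, 6)],
                "gamma": [2.0 ** e for e in range(-7, 2)]}
    raise ModelError(f"unknown classifier family {family!r}")


def small_grid(family: str) -> dict[str, list]:
    """Singleton grids with modest tree counts, for quick benchmark runs."""
    if family in ("RF", "ERT"):
        return {"n_estimators": [60], "max_depth": [None]}
    if family == "GB":
        return {"n_estimators": [60], "learning_rate": [0.1], "max_depth": [3]}
    if family == "AB":
        return {"n_estimators": [60], "learning_rate": [0.5]}
    if family == "XGB":
        return {"n_estimators": [60], "learning_rate": [0.3], "max_depth": [3]}
    if family == "SVM":
        return {"C": [1.0], "gamma": ["scale"]}
    raise ModelError(f"unknown classifier family {family!r}")


def build_estimator(family: str, params: dict | None = None, seed: int = 0):
    """Instantiate a scikit-learn / XGBoost classifier for ``family``."""
    params = dict(params or {})
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "ERT":
        return ExtraTreesClassifier(random_state=seed, **params)
    if family == "GB":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "AB":
        return AdaBoostClassifier(random_state=seed, **params)
    if family == "XGB":
        params.setdefault("tree_method", "hist")
        params.setdefault("eval_metric", "logloss")
        params.setdefault("n_jobs", 1)
        return XGBClassifier(random_state=seed, **params)
    if family == "SVM":
        params.setdefault("kernel", "rbf")
        return SVC(probability=True, random_state=seed, **params)
    raise ModelError(f"unknown classifier family {family!r}")


@dataclass
class ClassifierSpec:
    """One classifier family with its candidate grid and base seed."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown classifier family {self.family!r}")
        if not self.grid:
            self.grid = default_grid(self.family)

    def candidates(self) -> Iterator[dict]:
        keys = list(self.grid)
        for combo in itertools.product(*(self.grid[k] for k in keys)):
            yield {**self.fixed_params, **dict(zip(keys, combo))}


@dataclass
class CVProtocol:
    """Stratified k-fold settings; repeats are seeded seed, seed+1, ..."""

    n_folds: int = 5
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ModelError("need at least 2 folds")

    def splitter(self, repeat: int = 0) -> StratifiedKFold:
        return StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed + repeat
        )

    def repeat_seeds(self) -> list[int]:
        return [self.seed + r for r in range(self.n_repeats)]


def out_of_fold_predict(
    spec: ClassifierSpec,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVProtocol,
    repeat: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (probability, label) from models that never saw the sample."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    prob = np.full(len(y), np.nan)
    for train_idx, test_idx in cv.splitter(repeat).split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            raise ModelError("degenerate fold: single-class training split")
        est = build_estimator(spec.family, {**spec.fixed_params, **params}, spec.seed)
        est.fit(X[train_idx], y[train_idx])
        prob[test_idx] = est.predict_proba(X[test_idx])[:, 1]
    assert not np.isnan(prob).any()
    labels = (prob >= DECISION_THRESHOLD).astype(int)
    return prob, labels


def cross_validate(
    spec: ClassifierSpec,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVProtocol,
    repeat: int = 0,
) -> EvalReport:
    """Evaluation report from pooled out-of-fold predictions."""
    prob, _ = out_of_fold_predict(spec, params, X, y, cv, repeat)
    return evaluate(y, prob, DECISION_THRESHOLD)


@dataclass
class GridSearchResult:
    best_params: dict
    best_report: EvalReport
    trace: list[tuple[dict, EvalReport]]


def grid_search_cv(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVProtocol,
    repeat: int = 0,
) -> GridSearchResult:
    """Exhaustive grid search maximizing CV MCC; ties keep grid order."""
    if len(np.unique(np.asarray(y))) < 2:
        raise ModelError("grid search requires both classes")
    best: tuple[dict, EvalReport] | None = None
    trace = []
    failures = []
    for params in spec.candidates():
        try:
            report = cross_validate(spec, params, X, y, cv, repeat)
        except Exception as e:  # noqa: BLE001 - aggregate candidate failures
            failures.append((params, repr(e)))
            continue
        trace.append((params, report))
        if best is None or report.mcc > best[1].mcc:
            best = (params, report)
    if best is None:
        raise ModelError(f"all grid candidates failed: {failures}")
    return GridSearchResult(best[0], best[1], trace)


@dataclass
class BaselineModel:
    """A fitted classifier bound to its selected feature subset."""

    spec: ClassifierSpec
    method: str                 # scoring-method provenance: Fscore | RFIS | XFIS
    feature_subset: np.ndarray  # column indices into the hybrid matrix
    params: dict
    estimator: object
    cv_report: EvalReport

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        prob = self.estimator.predict_proba(
            np.asarray(X, dtype=float)[:, self.feature_subset]
        )[:, 1]
        return prob, (prob >= DECISION_THRESHOLD).astype(int)


def train_baseline(
    spec: ClassifierSpec,
    sfs_result,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVProtocol,
) -> BaselineModel:
    """Grid-search hyperparameters on the SFS-optimal subset and refit."""
    subset = np.asarray(sfs_result.optimal_subset, dtype=int)
    if subset.size == 0:
        raise ModelError("empty feature subset")
    Xs = np.asarray(X, dtype=float)[:, subset]
    gs = grid_search_cv(spec, Xs, y, cv)
    est = build_estimator(spec.family, {**spec.fixed_params, **gs.best_params},
                          spec.seed)
    est.fit(Xs, np.asarray(y, dtype=int))
    return BaselineModel(spec, sfs_result.method, subset, gs.best_params, est,
                         gs.best_report)
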