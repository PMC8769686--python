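"""Two-step feature selection: score-based ranking, then sequential
forward search.

Step one ranks all hybrid features with one of three scoring functions:

* ``Fscore`` — the two-class Fisher score
  F(i) = [(x+ - x)^2 + (x- - x)^2] / [var+(i) + var-(i)]
  with sample (ddof=1) within-class variances; a zero denominator with
  separated means ranks first (treated as +inf);
* ``RFIS`` — mean-impurity-decrease importances from a seeded random
  forest (non-negative, sum to 1);
* ``XFIS`` — gain importances from a seeded gradient-boosted-tree fit;
  features never used by any split score exactly 0.

F-score and RFIS lists are truncated to the top 2000 features; the XFIS
list keeps only strictly positive scores.  Step two walks the ranked
list in blocks of ``step`` features (5 for Fscore/RFIS, 2 for XFIS),
evaluating each prefix by stratified 5-fold CV and keeping the prefix
with the highest MCC (ties favor the smaller subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .evaluation import EvalReport
from .models import ClassifierSpec, CVProtocol, cross_validate

METHODS = ("Fscore", "RFIS", "XFIS")
TRUNCATION = 2000
DEFAULT_STEPS = {"Fscore": 5, "RFIS": 5, "XFIS": 2}


class SelectionError(ValueError):
    pass


def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise SelectionError("scoring requires both classes present")
    return y


def score_fscore(X, y) -> np.ndarray:
    """Two-class Fisher score per feature (vectorized)."""
    X = np.asarray(X, dtype=float)
    y = _check_two_class(y)
    if len(y) < 4:
        raise SelectionError("need n >= 4 for within-class variances")
    pos, neg = X[y == 1], X[y == 0]
    mean, mp, mn = X.mean(0), pos.mean(0), neg.mean(0)
    num = (mp - mean) ** 2 + (mn - mean) ** 2
    den = pos.var(0, ddof=1) + neg.var(0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = num / den
    s[(den == 0) & (num == 0)] = 0.0
    s[(den == 0) & (num > 0)] = np.inf
    return s


def score_rfis(X, y, seed: int = 0, n_estimators: int = 100) -> np.ndarray:
    """Random-forest impurity-decrease importances (sum to 1)."""
    y = _check_two_class(y)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(np.asarray(X, dtype=float), y)
    return rf.feature_importances_


def score_xfis(X, y, seed: int = 0, n_estimators: int = 100) -> np.ndarray:
    """Gradient-boosted-tree gain importances; unused features score 0."""
    y = _check_two_class(y)
    xgb = XGBClassifier(
        n_estimators=n_estimators, random_state=seed, tree_method="hist",
        eval_metric="logloss", n_jobs=1,
    )
    xgb.fit(np.asarray(X, dtype=float), y)
    return xgb.feature_importances_.astype(float)


_SCORERS = {"Fscore": score_fscore, "RFIS": score_rfis, "XFIS": score_xfis}


def score_features(method: str, X, y, seed: int = 0) -> np.ndarray:
    if method not in METHODS:
        raise SelectionError(f"unknown scoring method {method!r}")
    if method == "Fscore":
        return score_fscore(X, y)
    return _SCORERS[method](X, y, seed=seed)


@dataclass
class RankedFeatureList:
    """Feature indices in descending score order, after truncation."""

    method: str
    indices: np.ndarray
    scores: np.ndarray
    truncation: int | str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.indices) != len(self.scores):
            raise SelectionError("indices/scores length mismatch")
        if len(np.unique(self.indices)) != len(self.indices):
            raise SelectionError("duplicate feature indices in ranking")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size > 1 and (np.diff(finite) > 1e-12).any():
            raise SelectionError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.indices)


def rank_and_truncate(
    scores, method: str, truncation: int = TRUNCATION
) -> RankedFeatureList:
    """Sort descending (ties: lower original index first) and truncate.

    Fscore/RFIS keep the top ``min(truncation, d)`` features; XFIS keeps
    every strictly positive score.
    """
    if method not in METHODS:
        raise SelectionError(f"unknown scoring method {method!r}")
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise SelectionError("NaN feature score")
    order = np.lexsort((np.arange(len(scores)), -scores))
    if method == "XFIS":
        order = order[scores[order] > 0]
        trunc: int | str = "nonzero"
    else:
        order = order[:min(truncation, len(order))]
        trunc = min(truncation, len(scores))
    return RankedFeatureList(method, order, scores[order], trunc)


@dataclass
class SFSResult:
    classifier: str
    method: str
    trace: list[tuple[int, EvalReport]]
    optimal_subset: np.ndarray
    optimal_mcc: float

    @property
    def optimal_size(self) -> int:
        return len(self.optimal_subset)


def sequential_forward_search(
    ranked: RankedFeatureList,
    classifier_spec: ClassifierSpec,
    X,
    y,
    step: int | None = None,
    cv_protocol: CVProtocol | None = None,
    search_params: dict | None = None,
) -> SFSResult:
    """Evaluate growing prefixes of the ranked list; keep the MCC-best one.

    The trace has ceil(len(ranked)/step) entries (the last prefix is the
    whole list).  The search classifier uses ``search_params`` (default:
    the spec's fixed params only); hyperparameter tuning of the winning
    subset is the caller's job (``models.train_baseline``).
    """
    if len(ranked) == 0:
        raise SelectionError("empty ranked feature list")
    step = step if step is not None else DEFAULT_STEPS[ranked.method]
    if step < 1:
        raise SelectionError("step must be >= 1")
    cv = cv_protocol or CVProtocol()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    params = search_params or {}
    trace: list[tuple[int, EvalReport]] = []
    best_size, best_report = None, None
    sizes = list(range(step, len(ranked), step)) + [len(ranked)]
    for size in sizes:
        subset = ranked.indices[:size]
        report = cross_validate(classifier_spec, params, X[:, subset], y, cv)
        trace.append((size, report))
        if best_report is None or report.mcc > best_report.mcc:
            best_size, best_report = size, report
    return SFSResult(
        classifier=classifier_spec.family,
        method=ranked.method,
        trace=trace,
        optimal_subset=ranked.indices[:best_size].copy(),
        optimal_mcc=best_report.mcc,
    )


def write_sfs_trace_tsv(result: SFSResult, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("subset_size\tSn\tSp\tACC\tBACC\tMCC\tAUC\n")
        for size, r in result.trace:
            auc = "" if r.auc is None else f"{r.auc:.6g}"
            fh.write(
                f"{size}\t{r.sn:.6g}\t{r.sp:.6g}\t{r.acc:.6g}\t"
                f"{r.bacc:.6g}\t{r.mcc:.6g}\t{auc}\n"
            )
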