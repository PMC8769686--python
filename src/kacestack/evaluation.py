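"""Binary-classification metrics and the KNN-encoding leakage audit.

Metrics follow the usual confusion-matrix definitions: sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy, balanced
accuracy BACC = (Sn+Sp)/2, and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)),

with the convention MCC = 0 when the denominator vanishes.  AUC is the
rank-based (midrank tie handling) area under the ROC curve.  A score
exactly at the threshold counts as a positive prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


class ConfusionCounts(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvalReport:
    sn: float
    sp: float
    acc: float
    bacc: float
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None
    threshold: float = 0.5

    def as_dict(self) -> dict:
        d = {
            "Sn": self.sn, "Sp": self.sp, "ACC": self.acc,
            "BACC": self.bacc, "MCC": self.mcc, "AUC": self.auc,
            "threshold": self.threshold,
        }
        if self.counts is not None:
            d["counts"] = {"TP": self.counts.tp, "TN": self.counts.tn,
                           "FP": self.counts.fp, "FN": self.counts.fn}
        return d


def confusion_counts(y_true, y_prob, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; prob >= threshold predicts positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} truth vs {y_prob.shape} scores"
        )
    pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    return ConfusionCounts(tp, tn, fp, fn)


def compute_metrics(counts: ConfusionCounts, threshold: float = 0.5) -> EvalReport:
    """Threshold metrics from confusion counts (AUC left unset)."""
    tp, tn, fp, fn = counts
    if counts.n == 0:
        raise ValueError("empty evaluation")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.n
    bacc = 0.5 * sn + 0.5 * sp
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return EvalReport(sn, sp, acc, bacc, mcc, counts=counts, threshold=threshold)


def roc_auc(y_true, y_prob) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties half."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("roc_auc requires both classes in y_true")
    return float(roc_auc_score(y_true, np.asarray(y_prob, dtype=float)))


def evaluate(y_true, y_prob, threshold: float = 0.5) -> EvalReport:
    """Full report: threshold metrics plus AUC."""
    report = compute_metrics(confusion_counts(y_true, y_prob, threshold), threshold)
    y_true = np.asarray(y_true, dtype=int)
    report.auc = roc_auc(y_true, y_prob) if len(np.unique(y_true)) == 2 else None
    return report


def write_roc_tsv(y_true, y_prob, path: str | Path) -> None:
    """Write the empirical ROC curve as TSV (FPR, TPR, threshold)."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true, int), np.asarray(y_prob, float))
    with open(path, "w", newline="\n") as fh:
        fh.write("FPR\tTPR\tthreshold\n")
        for f, t, h in zip(fpr, tpr, thr):
            fh.write(f"{f:.6g}\t{t:.6g}\t{h:.6g}\n")


# ---------------------------------------------------------------------------
# KNN leakage audit


@dataclass
class LeakageAuditResult:
    training_cv: EvalReport
    independent: EvalReport
    auc_gap: float
    mode: str = "naive"


def knn_leakage_audit(
    dataset,
    held_out,
    classifier_spec=None,
    cv_protocol=None,
    encoder_mode: str = "naive",
    neighbor_counts: tuple[int, ...] | None = None,
    config=None,
) -> LeakageAuditResult:
    """Quantify label leakage of the KNN encoding.

    Trains a classifier on KNN features only and compares stratified-CV
    performance on ``dataset`` against performance on the disjoint
    ``held_out`` set.  In ``naive`` mode each training fragment's
    features are computed against the full labeled pool *including
    itself*, so its own label leaks into its features and the CV AUC is
    inflated; ``leave_one_out`` mode removes the query from its own
    neighbor set and closes the gap.  Returns both reports and their AUC
    difference (training CV minus independent).
    """
    from .encoders import (DEFAULT_NEIGHBOR_COUNTS, EncodingConfig,
                           KNNReference, encode_knn)
    from .models import ClassifierSpec, CVProtocol, build_estimator, out_of_fold_predict

    if encoder_mode not in ("naive", "leave_one_out"):
        raise ValueError(f"unknown encoder mode {encoder_mode!r}")
    train_seqs = set(dataset.sequences)
    overlap = train_seqs & set(held_out.sequences)
    if overlap:
        raise ValueError(
            f"held-out set overlaps the training set ({len(overlap)} fragments)"
        )
    config = config or EncodingConfig()
    counts = neighbor_counts or tuple(
        x for x in DEFAULT_NEIGHBOR_COUNTS if x <= len(dataset) - 1
    )
    reference = KNNReference(dataset, counts)
    loo = encoder_mode == "leave_one_out"
    X_train = encode_knn(dataset, reference, config, leave_one_out=loo).matrix
    X_test = encode_knn(held_out, reference, config).matrix

    spec = classifier_spec or ClassifierSpec("RF", {}, seed=0)
    cv = cv_protocol or CVProtocol(seed=spec.seed)
    prob_cv, _ = out_of_fold_predict(spec, {}, X_train, dataset.labels, cv)
    training_cv = evaluate(dataset.labels, prob_cv)

    est = build_estimator(spec.family, spec.fixed_params, spec.seed)
    est.fit(X_train, dataset.labels)
    prob_ind = est.predict_proba(X_test)[:, 1]
    independent = evaluate(held_out.labels, prob_ind)
    gap = float(training_cv.auc - independent.auc)
    return LeakageAuditResult(training_cv, independent, gap, mode=encoder_mode)
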