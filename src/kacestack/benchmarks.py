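"""Reference benchmark protocols on synthetic data.

These are the package's standing desk-scale experiments: each function
generates its own motif-planted (or signal-free) data, runs one stage
of the pipeline and returns the measured quantities.  The problem sizes
(400 samples, a 300-column reduced encoder set, SFS step 10, reduced
tree counts) are fixed here so that the test suite and the
reproducibility script exercise identical conditions; they are small by
design and are documented in docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .encoders import KNNReference, encode_hybrid, encode_knn
from .evaluation import knn_leakage_audit
from .models import ClassifierSpec, CVProtocol, cross_validate
from .selection import (METHODS, rank_and_truncate, score_features,
                        sequential_forward_search)
from .simulate import MotifSpec, SyntheticDatasetSpec, generate_dataset
from .stacking import StackingConfig, fit_stacked

#: Reduced encoder set used by the stacking benchmark: 150+105+25+20 = 300
#: columns, spanning group-pair, positional-physicochemical and rank blocks.
REDUCED_TAGS: tuple[str, ...] = ("CKSAAGP", "Zscale", "GDPC", "NRF")

#: Light hyperparameters for benchmark runs (singleton grids).
FAST_PARAMS: dict[str, dict] = {
    "RF": {"n_estimators": 30, "max_depth": None},
    "ERT": {"n_estimators": 30, "max_depth": None},
    "GB": {"n_estimators": 25, "max_depth": 2, "learning_rate": 0.3},
    "AB": {"n_estimators": 25, "learning_rate": 1.0},
    "XGB": {"n_estimators": 30, "max_depth": 3, "learning_rate": 0.3},
    "SVM": {"C": 1.0, "gamma": "scale"},
}


def fast_grids() -> dict[str, dict]:
    return {f: {k: [v] for k, v in p.items()} for f, p in FAST_PARAMS.items()}


def dimension_report() -> dict[str, int]:
    """Recompute every encoder's output width on a tiny fragment set."""
    ds = generate_dataset(SyntheticDatasetSpec(70, 70, seed=0))
    hybrid = encode_hybrid(ds)
    dims = {tag: sl.stop - sl.start for tag, sl in hybrid.block_slices.items()}
    dims["HYBRID"] = hybrid.n_features
    ref = KNNReference(ds)  # default X = 2..128 fits in a 140-fragment pool
    dims["KNN"] = encode_knn(ds, ref).n_features
    return dims


def selection_recovery(seed: int = 0, n: int = 400,
                       n_noise: int = 200) -> dict:
    """Plant one label-copy feature among noise; measure ranker + SFS recovery.

    Returns the planted feature's rank position under each scoring
    function, and the SFS result (subset membership + CV MCC) on the
    F-score list with a random-forest search classifier.
    """
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n // 2, int), np.zeros(n - n // 2, int)])
    rng.shuffle(y)
    X = rng.normal(size=(n, n_noise + 1))
    planted = n_noise // 2
    X[:, planted] = y + 0.01 * rng.normal(size=n)
    out: dict = {"planted_index": planted, "rank_position": {}}
    ranked_lists = {}
    for method in METHODS:
        scores = score_features(method, X, y, seed=seed)
        ranked = rank_and_truncate(scores, method)
        ranked_lists[method] = ranked
        pos = np.flatnonzero(ranked.indices == planted)
        out["rank_position"][method] = int(pos[0]) if pos.size else -1
    spec = ClassifierSpec("RF", fast_grids()["RF"], seed=seed)
    sfs = sequential_forward_search(
        ranked_lists["Fscore"], spec, X, y, step=5,
        cv_protocol=CVProtocol(seed=seed), search_params=FAST_PARAMS["RF"],
    )
    out["sfs_mcc"] = float(sfs.optimal_mcc)
    out["sfs_contains_planted"] = bool(planted in sfs.optimal_subset)
    out["sfs_subset_size"] = int(sfs.optimal_size)
    return out


def stacking_benchmark(seed: int = 0, n_per_class: int = 200,
                       p_signal: float = 0.7) -> dict:
    """One seed of the stacked-vs-single-block comparison.

    400 fragments, the 300-column reduced encoder set, F-score ranking
    with SFS step 10, five baseline families with the light
    hyperparameters, ten-repeat meta selection over all six candidates
    reduced to three repeats for tractability.  Single-block reference
    models are RF and XGB fits per encoder block; the comparison value
    is the best block/family CV MCC.
    """
    ds = generate_dataset(SyntheticDatasetSpec(
        n_per_class, n_per_class, MotifSpec(p_signal=p_signal), seed=seed))
    grids = fast_grids()
    config = StackingConfig(
        encoder_tags=REDUCED_TAGS,
        ranking_methods=("Fscore",),
        grids=grids, meta_grids=grids,
        search_params={f: FAST_PARAMS[f] for f in ("RF", "ERT", "GB", "AB", "XGB")},
        sfs_steps={"Fscore": 10},
        cv=CVProtocol(seed=seed),
        meta_repeats=3,
        seed=seed,
    )
    model = fit_stacked(ds, config=config)
    hybrid = encode_hybrid(ds, config.encoding, REDUCED_TAGS)
    block_mcc: dict[str, float] = {}
    for tag, sl in hybrid.block_slices.items():
        for family in ("RF", "XGB"):
            spec = ClassifierSpec(family, grids[family], seed=seed)
            report = cross_validate(spec, FAST_PARAMS[family],
                                    hybrid.matrix[:, sl], ds.labels,
                                    CVProtocol(seed=seed))
            block_mcc[f"{tag}:{family}"] = float(report.mcc)
    return {
        "stacked_mcc": float(model.cv_report.mcc),
        "best_block_mcc": max(block_mcc.values()),
        "block_mcc": block_mcc,
        "meta_family": model.meta_family,
    }


def knn_leakage_benchmark(seed: int = 0, n_train_per_class: int = 200,
                          n_test_per_class: int = 100) -> dict:
    """Naive vs leave-one-out KNN-encoding AUC gap on signal-free data."""
    null = MotifSpec(p_signal=0.0, padding_rate=0.0)
    train = generate_dataset(SyntheticDatasetSpec(
        n_train_per_class, n_train_per_class, null, seed=seed))
    test = generate_dataset(SyntheticDatasetSpec(
        n_test_per_class, n_test_per_class, null, seed=seed + 100_000))
    spec = ClassifierSpec("RF", fast_grids()["RF"], seed=seed,
                          fixed_params=FAST_PARAMS["RF"])
    out = {}
    for mode in ("naive", "leave_one_out"):
        res = knn_leakage_audit(train, test, spec, CVProtocol(seed=seed),
                                encoder_mode=mode)
        out[mode] = {
            "training_cv_auc": float(res.training_cv.auc),
            "independent_auc": float(res.independent.auc),
            "auc_gap": float(res.auc_gap),
        }
    return out
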