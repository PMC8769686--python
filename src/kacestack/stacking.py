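"""Stacked ensemble assembly.

The stacked predictor is built in three stages:

1. *Feature representation* — the hybrid encoding of the training
   fragments (2616 columns at defaults).
2. *Per-classifier feature selection* — each ranking method (Fscore,
   RFIS, XFIS) is combined with each tree-ensemble family through a
   sequential forward search, giving up to |methods| x |families|
   candidate models; for each family the MCC-best ranking wins and is
   tuned by grid search on its optimal subset, yielding one baseline
   model per family.
3. *Stacking* — each baseline contributes its predicted probability and
   0.5-thresholded label, in the fixed order RF, ERT, GB, AB, XGB, to a
   10-D meta-feature vector.  Six candidate meta-classifiers (the five
   families plus SVM) are compared over ten differently-seeded 5-fold
   CVs; the winner is refit with per-parameter median hyperparameters
   (lower median for even counts, mode for categorical values).

Meta-features are generated out-of-fold by default, so a sample's own
label never reaches its own meta-features; ``resubstitution`` mode
(the naive variant) is retained for comparison.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np

from .encoders import EncodingConfig, HYBRID_ORDER, encode_hybrid
from .evaluation import EvalReport, evaluate
from .fragments import FragmentDataset
from .models import (BaselineModel, ClassifierSpec, CVProtocol,
                     DECISION_THRESHOLD, FAMILIES, TREE_FAMILIES, ModelError,
                     build_estimator, default_grid, grid_search_cv,
                     out_of_fold_predict, train_baseline)
from .selection import (DEFAULT_STEPS, METHODS, TRUNCATION, rank_and_truncate,
                        score_features, sequential_forward_search)

BASELINE_ORDER: tuple[str, ...] = TREE_FAMILIES  # RF, ERT, GB, AB, XGB
META_CANDIDATE_ORDER: tuple[str, ...] = FAMILIES


class StackingError(RuntimeError):
    pass


@dataclass
class StackingConfig:
    """Everything ``fit_stacked`` needs, with reproducible seeds."""

    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    encoder_tags: tuple[str, ...] = HYBRID_ORDER
    ranking_methods: tuple[str, ...] = METHODS
    families: tuple[str, ...] = BASELINE_ORDER
    grids: dict[str, dict] = field(default_factory=dict)
    search_params: dict[str, dict] = field(default_factory=dict)
    sfs_steps: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_STEPS))
    truncation: int = TRUNCATION
    cv: CVProtocol = field(default_factory=CVProtocol)
    meta_candidates: tuple[str, ...] = META_CANDIDATE_ORDER
    meta_grids: dict[str, dict] = field(default_factory=dict)
    meta_repeats: int = 10
    meta_mode: str = "out_of_fold"
    seed: int = 0
    species: str = ""

    def __post_init__(self) -> None:
        bad = set(self.families) - set(BASELINE_ORDER)
        if bad:
            raise StackingError(f"unknown baseline families: {sorted(bad)}")
        self.families = tuple(f for f in BASELINE_ORDER if f in self.families)
        bad = set(self.ranking_methods) - set(METHODS)
        if bad:
            raise StackingError(f"unknown ranking methods: {sorted(bad)}")
        if self.meta_mode not in ("out_of_fold", "resubstitution"):
            raise StackingError(f"unknown meta mode {self.meta_mode!r}")

    def grid_for(self, family: str) -> dict:
        return self.grids.get(family) or default_grid(family)

    def meta_grid_for(self, family: str) -> dict:
        return self.meta_grids.get(family) or self.grids.get(family) \
            or default_grid(family)

    def manifest(self) -> dict:
        """A JSON-serializable summary sufficient to reproduce a fit."""
        m = {
            "seed": self.seed,
            "species": self.species,
            "encoder_tags": list(self.encoder_tags),
            "ranking_methods": list(self.ranking_methods),
            "families": list(self.families),
            "grids": {f: self.grid_for(f) for f in self.families},
            "meta_grids": {f: self.meta_grid_for(f) for f in self.meta_candidates},
            "search_params": self.search_params,
            "sfs_steps": self.sfs_steps,
            "truncation": self.truncation,
            "cv": {"n_folds": self.cv.n_folds, "seed": self.cv.seed},
            "meta_candidates": list(self.meta_candidates),
            "meta_repeats": self.meta_repeats,
            "meta_mode": self.meta_mode,
            "window": self.encoding.window,
        }
        m["config_hash"] = hashlib.sha256(
            json.dumps(m, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return m


def build_meta_features(
    baselines: Sequence[BaselineModel],
    X: np.ndarray,
    y: np.ndarray | None,
    cv_protocol: CVProtocol | None = None,
    mode: str = "out_of_fold",
) -> tuple[np.ndarray, list[str]]:
    """The n x 10 meta matrix: (probability, label) per baseline, fixed order."""
    fams = [b.spec.family for b in baselines]
    if len(set(fams)) != len(fams):
        raise StackingError(f"duplicate baseline families: {fams}")
    ordered = sorted(baselines, key=lambda b: BASELINE_ORDER.index(b.spec.family))
    cols, names = [], []
    for b in ordered:
        if mode == "out_of_fold":
            if y is None or cv_protocol is None:
                raise StackingError("out_of_fold mode needs labels and a protocol")
            prob, lab = out_of_fold_predict(
                b.spec, b.params, np.asarray(X, float)[:, b.feature_subset],
                y, cv_protocol,
            )
        elif mode == "resubstitution":
            prob, lab = b.predict(X)
        else:
            raise StackingError(f"unknown meta-feature mode {mode!r}")
        cols.extend([prob, lab.astype(float)])
        names.extend([f"{b.spec.family}:prob", f"{b.spec.family}:label"])
    return np.column_stack(cols), names


def _median_params(winners: list[dict]) -> dict:
    """Per-parameter median (lower median for even counts; mode otherwise)."""
    out = {}
    for key in winners[0]:
        vals = [w[key] for w in winners]
        if all(isinstance(v, (int, float)) and not isinstance(v, bool)
               for v in vals):
            ordered = sorted(vals)
            out[key] = ordered[(len(ordered) - 1) // 2]
        else:
            seen: list = []
            for v in vals:
                if v not in seen:
                    seen.append(v)
            out[key] = max(seen, key=lambda v: (vals.count(v), -seen.index(v)))
    return out


@dataclass
class MetaSelection:
    family: str
    params: dict
    mean_mcc: dict[str, float]
    repeat_reports: dict[str, list[EvalReport]]


def select_meta_classifier(
    meta_X: np.ndarray,
    y: np.ndarray,
    candidates: Sequence[ClassifierSpec],
    cv_protocol: CVProtocol,
) -> MetaSelection:
    """Ten randomized 5-fold CVs per candidate; best mean MCC wins.

    Each repeat runs its own grid search; the winner's final
    hyperparameters are the per-parameter medians over its ten
    repeat-level optima.
    """
    if cv_protocol.n_repeats < 1:
        raise StackingError("need at least one CV repeat")
    per_family: dict[str, tuple[list[dict], list[EvalReport]]] = {}
    for spec in candidates:
        winners, reports = [], []
        for r in range(cv_protocol.n_repeats):
            gs = grid_search_cv(spec, meta_X, y, cv_protocol, repeat=r)
            winners.append(gs.best_params)
            reports.append(gs.best_report)
        per_family[spec.family] = (winners, reports)
    mean_mcc = {
        f: float(np.mean([rep.mcc for rep in reps]))
        for f, (_, reps) in per_family.items()
    }
    order = [s.family for s in candidates]
    best = max(order, key=lambda f: (mean_mcc[f], -order.index(f)))
    params = _median_params(per_family[best][0])
    return MetaSelection(
        best, params, mean_mcc,
        {f: reps for f, (_, reps) in per_family.items()},
    )


@dataclass
class StackedModel:
    baselines: list[BaselineModel]           # RF, ERT, GB, AB, XGB order
    meta_family: str
    meta_params: dict
    meta_estimator: object
    config: StackingConfig
    meta_selection: MetaSelection
    sfs_results: dict                        # (family, method) -> SFSResult
    cv_report: EvalReport                    # stacked out-of-fold report
    manifest: dict

    def predict(self, fragments) -> tuple[np.ndarray, np.ndarray]:
        """Per-fragment (probability, label) through the full stack."""
        hybrid = encode_hybrid(fragments, self.config.encoding,
                               self.config.encoder_tags)
        meta_X, _ = build_meta_features(self.baselines, hybrid.matrix, None,
                                        mode="resubstitution")
        prob = self.meta_estimator.predict_proba(meta_X)[:, 1]
        return prob, (prob >= DECISION_THRESHOLD).astype(int)


def fit_stacked(
    fragments: FragmentDataset | Sequence,
    labels=None,
    config: StackingConfig | None = None,
) -> StackedModel:
    """Run the full three-stage pipeline on a labeled fragment dataset."""
    config = config or StackingConfig()
    if isinstance(fragments, FragmentDataset):
        dataset = fragments
        y = dataset.labels if labels is None else np.asarray(labels, int)
    else:
        dataset = FragmentDataset(list(fragments), np.asarray(labels, int))
        y = dataset.labels
    if len(np.unique(y)) < 2:
        raise StackingError("training data must contain both classes")

    stage = "feature representation"
    try:
        hybrid = encode_hybrid(dataset, config.encoding, config.encoder_tags)
        X = hybrid.matrix

        stage = "feature ranking"
        rankings = {}
        for method in config.ranking_methods:
            scores = score_features(method, X, y, seed=config.seed)
            rankings[method] = rank_and_truncate(scores, method, config.truncation)

        stage = "sequential forward search"
        sfs_results = {}
        for family in config.families:
            spec = ClassifierSpec(family, config.grid_for(family),
                                  seed=config.seed)
            for method, ranked in rankings.items():
                if len(ranked) == 0:
                    continue
                sfs_results[(family, method)] = sequential_forward_search(
                    ranked, spec, X, y,
                    step=config.sfs_steps.get(method, DEFAULT_STEPS[method]),
                    cv_protocol=config.cv,
                    search_params=config.search_params.get(family, {}),
                )

        stage = "baseline training"
        baselines = []
        for family in config.families:
            fam_results = [r for (f, _), r in sfs_results.items() if f == family]
            if not fam_results:
                raise StackingError(f"no SFS result for family {family}")
            best = max(fam_results,
                       key=lambda r: (r.optimal_mcc, -r.optimal_size))
            spec = ClassifierSpec(family, config.grid_for(family),
                                  seed=config.seed)
            baselines.append(train_baseline(spec, best, X, y, config.cv))

        stage = "meta-feature construction"
        meta_X, _ = build_meta_features(baselines, X, y, config.cv,
                                        mode=config.meta_mode)

        stage = "meta-classifier selection"
        meta_cv = CVProtocol(n_folds=config.cv.n_folds,
                             n_repeats=config.meta_repeats,
                             seed=config.seed + 1000)
        candidates = [
            ClassifierSpec(f, config.meta_grid_for(f), seed=config.seed)
            for f in config.meta_candidates
        ]
        selection = select_meta_classifier(meta_X, y, candidates, meta_cv)

        stage = "final fit"
        meta_spec = ClassifierSpec(selection.family,
                                   config.meta_grid_for(selection.family),
                                   seed=config.seed)
        meta_est = build_estimator(selection.family, selection.params,
                                   config.seed)
        meta_est.fit(meta_X, y)
        prob_oof, _ = out_of_fold_predict(meta_spec, selection.params,
                                          meta_X, y, config.cv)
        cv_report = evaluate(y, prob_oof)
    except (StackingError, ModelError):
        raise
    except Exception as e:
        raise StackingError(f"stage {stage!r} failed: {e}") from e

    manifest = config.manifest()
    manifest["meta_family"] = selection.family
    manifest["meta_params"] = {k: repr(v) for k, v in selection.params.items()}
    manifest["n_train"] = int(len(y))
    return StackedModel(baselines, selection.family, selection.params,
                        meta_est, config, selection, sfs_results, cv_report,
                        manifest)


def predict_stacked(model: StackedModel, fragments) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(fragments)


def save_stacked(model: StackedModel, path) -> None:
    """Serialize the stacked model (joblib archive + JSON manifest sidecar)."""
    joblib.dump(model, path)
    with open(f"{path}.manifest.json", "w", newline="\n") as fh:
        json.dump(model.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_stacked(path) -> StackedModel:
    return joblib.load(path)
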