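"""Meta-feature construction, median-hyperparameter rule, stacked fits."""

import numpy as np
import pytest

from kacestack.benchmarks import FAST_PARAMS, fast_grids
from kacestack.models import ClassifierSpec, CVProtocol, train_baseline
from kacestack.selection import SFSResult
from kacestack.simulate import MotifSpec, SyntheticDatasetSpec, generate_dataset
from kacestack.stacking import (StackingConfig, StackingError,
                                _median_params, build_meta_features,
                                fit_stacked, load_stacked, save_stacked,
                                select_meta_classifier)


@pytest.fixture(scope="module")
def tiny_fit():
    """A complete stacked fit on 100 strongly-signalled fragments."""
    ds = generate_dataset(
        SyntheticDatasetSpec(50, 50, MotifSpec(p_signal=0.95), seed=21)
    )
    grids = fast_grids()
    config = StackingConfig(
        encoder_tags=("Zscale", "GDPC", "NRF"),
        ranking_methods=("Fscore", "XFIS"),
        grids=grids, meta_grids=grids,
        search_params={f: FAST_PARAMS[f]
                       for f in ("RF", "ERT", "GB", "AB", "XGB")},
        sfs_steps={"Fscore": 30, "XFIS": 10},
        cv=CVProtocol(seed=0), meta_repeats=2, seed=0,
    )
    return ds, config, fit_stacked(ds, config=config)


def make_baselines(X, y, families=("RF", "ERT", "GB", "AB", "XGB")):
    cv = CVProtocol(seed=0)
    subset = np.arange(X.shape[1])
    out = []
    for f in families:
        spec = ClassifierSpec(f, fast_grids()[f], seed=0)
        out.append(train_baseline(
            spec, SFSResult(f, "Fscore", [], subset, 0.0), X, y, cv))
    return out


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(3)
    y = np.array([0, 1] * 40)
    X = rng.normal(size=(80, 6))
    X[:, 0] = y + 0.1 * rng.normal(size=80)
    return X, y, make_baselines(X, y)


class TestMetaFeatures:
    def test_ten_columns_in_fixed_order(self, fitted):
        X, y, baselines = fitted
        meta, names = build_meta_features(baselines, X, y, CVProtocol(seed=0))
        assert meta.shape == (80, 10)
        assert names == [
            "RF:prob", "RF:label", "ERT:prob", "ERT:label", "GB:prob",
            "GB:label", "AB:prob", "AB:label", "XGB:prob", "XGB:label",
        ]
        assert meta.min() >= 0 and meta.max() <= 1

    def test_label_columns_threshold_their_probability(self, fitted):
        X, y, baselines = fitted
        meta, _ = build_meta_features(baselines, X, y, CVProtocol(seed=0))
        for j in range(0, 10, 2):
            assert np.array_equal(meta[:, j + 1], (meta[:, j] >= 0.5))

    def test_duplicate_families_rejected(self, fitted):
        X, y, baselines = fitted
        with pytest.raises(StackingError, match="duplicate"):
            build_meta_features([baselines[0], baselines[0]], X, y,
                                CVProtocol(seed=0))

    def test_out_of_fold_rows_come_from_models_that_never_saw_them(self, fitted):
        """Recompute each fold's model by hand and compare its predictions."""
        from kacestack.models import build_estimator, out_of_fold_predict

        X, y, baselines = fitted
        b = baselines[0]
        cv = CVProtocol(seed=9)
        prob, _ = out_of_fold_predict(b.spec, b.params, X, y, cv)
        for train_idx, test_idx in cv.splitter().split(X, y):
            est = build_estimator(b.spec.family,
                                  {**b.spec.fixed_params, **b.params},
                                  b.spec.seed)
            est.fit(X[train_idx], y[train_idx])
            assert prob[test_idx] == pytest.approx(
                est.predict_proba(X[test_idx])[:, 1])


class TestMedianRule:
    def test_even_count_takes_lower_median(self):
        winners = [{"C": c} for c in (1, 1, 2, 2, 4, 4, 4, 8, 8, 16)]
        assert _median_params(winners) == {"C": 4}

    def test_categorical_takes_mode(self):
        winners = [{"gamma": g} for g in ("scale", "auto", "scale")]
        assert _median_params(winners) == {"gamma": "scale"}

    def test_mixed_params(self):
        winners = [{"n": n, "depth": d}
                   for n, d in [(10, None), (20, None), (30, 4)]]
        assert _median_params(winners) == {"n": 20, "depth": None}


class TestMetaSelection:
    def test_dominating_candidate_chosen_with_median_params(self, rng):
        y = np.array([0, 1] * 50)
        meta = np.column_stack([
            y + 0.05 * rng.normal(size=100),
            rng.random(100),
        ]).clip(0, 1)
        candidates = [
            ClassifierSpec("RF", {"n_estimators": [10, 20]}, seed=0),
            ClassifierSpec("SVM", {"C": [1.0], "gamma": ["scale"]}, seed=0),
        ]
        cv = CVProtocol(n_folds=5, n_repeats=3, seed=0)
        sel = select_meta_classifier(meta, y, candidates, cv)
        assert sel.family in ("RF", "SVM")
        assert sel.mean_mcc[sel.family] == max(sel.mean_mcc.values())
        assert len(sel.repeat_reports["RF"]) == 3

    def test_identical_seeds_identical_choice(self, rng):
        y = np.array([0, 1] * 30)
        meta = rng.random((60, 4))
        candidates = [ClassifierSpec("RF", {"n_estimators": [10]}, seed=0)]
        cv = CVProtocol(n_repeats=2, seed=1)
        a = select_meta_classifier(meta, y, candidates, cv)
        b = select_meta_classifier(meta, y, candidates, cv)
        assert a.params == b.params
        assert a.mean_mcc == b.mean_mcc


class TestFitStacked:
    def test_candidate_models_per_ranking_and_family(self, tiny_fit):
        ds, config, model = tiny_fit
        assert len(model.sfs_results) == \
            len(config.ranking_methods) * len(config.families)
        assert len(model.baselines) == 5
        assert [b.spec.family for b in model.baselines] == \
            ["RF", "ERT", "GB", "AB", "XGB"]

    def test_learns_planted_motif(self, tiny_fit):
        ds, _, model = tiny_fit
        assert model.cv_report.mcc > 0.5

    def test_prediction_contract(self, tiny_fit):
        ds, _, model = tiny_fit
        prob, label = model.predict(ds)
        assert prob.shape == (len(ds),)
        assert (0 <= prob).all() and (prob <= 1).all()
        assert np.array_equal(label, (prob >= 0.5).astype(int))

    def test_batch_equals_record_by_record(self, tiny_fit):
        ds, _, model = tiny_fit
        batch, _ = model.predict(ds.subset(range(5)))
        singles = np.concatenate(
            [model.predict(ds.subset([i]))[0] for i in range(5)]
        )
        assert batch == pytest.approx(singles)

    def test_rerun_is_deterministic(self, tiny_fit):
        ds, config, model = tiny_fit
        again = fit_stacked(ds, config=config)
        assert again.meta_family == model.meta_family
        assert again.manifest["config_hash"] == model.manifest["config_hash"]
        assert np.array_equal(again.predict(ds)[0], model.predict(ds)[0])

    def test_save_load_round_trip(self, tiny_fit, tmp_path):
        ds, _, model = tiny_fit
        path = tmp_path / "model.joblib"
        save_stacked(model, path)
        loaded = load_stacked(path)
        assert np.array_equal(loaded.predict(ds)[0], model.predict(ds)[0])
        assert (tmp_path / "model.joblib.manifest.json").exists()

    def test_single_class_rejected(self):
        ds = generate_dataset(SyntheticDatasetSpec(10, 0, seed=0))
        with pytest.raises(StackingError, match="both classes"):
            fit_stacked(ds, config=StackingConfig())
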