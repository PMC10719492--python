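"""Predictors: determinism, dispatch contract, recovery, cross-validation."""

import numpy as np
import pytest

from abypap.dataset import split
from abypap.evaluation import classification_metrics, regression_metrics
from abypap.features import featurize
from abypap.models import (
    GBRConfig,
    GatedPackingAngleRegressor,
    ModelBundle,
    PackingAngleGBR,
    PackingAngleMLP,
    classify_angle,
    classify_angles,
    cross_validate,
    predict,
    records_to_xy,
    train_gated,
    train_gbr,
    train_mlp,
)
from abypap.synthetic import PlantedDatasetSpec, make_planted_dataset

FAST = dict(n_estimators=200, min_samples_leaf=2)


@pytest.fixture(scope="module")
def planted():
    records, info = make_planted_dataset(PlantedDatasetSpec(n=800, noise_sd=1.0, seed=3))
    part = split(records, 0.1, seed=100)
    Xtr, ytr = records_to_xy(part.train, "gbr1")
    Xte, yte = records_to_xy(part.test, "gbr1")
    return Xtr, ytr, Xte, yte


@pytest.fixture(scope="module")
def three_class():
    records, _ = make_planted_dataset(
        PlantedDatasetSpec(n=900, class_mix=(0.12, 0.76, 0.12), seed=9)
    )
    part = split(records, 0.15, seed=100)
    Xtr, ytr = records_to_xy(part.train, "gbr1")
    Xte, yte = records_to_xy(part.test, "gbr1")
    return Xtr, ytr, Xte, yte


class TestClassifyAngle:
    @pytest.mark.parametrize(
        "angle,label",
        [
            (-45.0, "normal"),
            (-40.0, "normal"),
            (-50.0, "normal"),  # band inclusive on both ends
            (-39.9, "max_outlier"),
            (-50.1, "min_outlier"),
        ],
    )
    def test_band_membership(self, angle, label):
        assert classify_angle(angle) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_angle(float("nan"))


class TestPlainGBR:
    def test_planted_signal_recovered(self, planted):
        Xtr, ytr, Xte, yte = planted
        model = PackingAngleGBR(schema="gbr1", **FAST).fit(Xtr, ytr)
        report = regression_metrics(yte, model.predict(Xte))
        assert report.pearson_r >= 0.95

    def test_constant_target(self, planted):
        Xtr, *_ = planted
        model = PackingAngleGBR(schema="gbr1", **FAST).fit(Xtr, np.full(len(Xtr), -46.0))
        np.testing.assert_allclose(model.predict(Xtr[:5]), -46.0, atol=1e-9)

    def test_training_deterministic(self, planted):
        Xtr, ytr, Xte, _ = planted
        a = PackingAngleGBR(schema="gbr1", **FAST).fit(Xtr, ytr).predict(Xte)
        b = PackingAngleGBR(schema="gbr1", **FAST).fit(Xtr, ytr).predict(Xte)
        np.testing.assert_array_equal(a, b)

    def test_predictions_within_training_range(self, planted):
        # additive trees with small learning rate cannot extrapolate far
        Xtr, ytr, Xte, _ = planted
        model = PackingAngleGBR(schema="gbr1", **FAST).fit(Xtr, ytr)
        pred = model.predict(Xte)
        assert pred.min() >= ytr.min() - 1.0 and pred.max() <= ytr.max() + 1.0

    def test_schema_width_enforced(self, planted):
        Xtr, ytr, *_ = planted
        with pytest.raises(ValueError, match="features"):
            PackingAngleGBR(schema="gbr4", **FAST).fit(Xtr, ytr)

    def test_table_defaults(self):
        params = PackingAngleGBR().get_params()
        assert params["alpha"] == 0.01
        assert params["learning_rate"] == 0.1
        assert params["max_depth"] == 2
        assert params["min_samples_leaf"] == 10
        assert params["n_estimators"] == 50_000
        assert params["random_state"] == 100


class TestGated:
    def test_gatekeeper_recovers_separable_classes(self, three_class):
        Xtr, ytr, Xte, yte = three_class
        model = GatedPackingAngleRegressor(schema="gbr1", **FAST).fit(Xtr, ytr)
        report = classification_metrics(classify_angles(yte), model.predict_class(Xte))
        assert report.accuracy >= 0.95
        assert report.mcc >= 0.9

    def test_dispatch_routes_each_query_once(self, three_class):
        Xtr, ytr, Xte, _ = three_class
        model = GatedPackingAngleRegressor(schema="gbr1", **FAST).fit(Xtr, ytr)
        pred = model.predict(Xte)
        assert np.all(np.isfinite(pred))
        assert sum(model.last_dispatch_counts_.values()) == len(Xte)
        labels = model.predict_class(Xte)
        for cls, count in model.last_dispatch_counts_.items():
            assert count == int(np.sum(labels == cls))

    def test_normal_queries_use_normal_regressor(self, three_class):
        Xtr, ytr, Xte, _ = three_class
        model = GatedPackingAngleRegressor(schema="gbr1", **FAST).fit(Xtr, ytr)
        labels = model.predict_class(Xte)
        normal = Xte[labels == "normal"]
        expected = model.regressors_["normal"].predict(normal)
        np.testing.assert_array_equal(model.predict(normal), expected)

    def test_empty_class_raises(self, planted):
        Xtr, ytr, *_ = planted  # all angles well inside the normal band? no:
        ytr_normal = np.clip(ytr, -49.0, -41.0)
        with pytest.raises(ValueError, match="widen"):
            GatedPackingAngleRegressor(schema="gbr1", **FAST).fit(Xtr, ytr_normal)

    def test_perfectly_separable_mcc_is_one(self, three_class):
        Xtr, ytr, Xte, yte = three_class
        model = GatedPackingAngleRegressor(schema="gbr1", **FAST).fit(Xtr, ytr)
        report = classification_metrics(classify_angles(yte), model.predict_class(Xte))
        assert report.mcc == pytest.approx(1.0, abs=0.1)


class TestMLP:
    def test_planted_linear_signal_learned(self):
        records, _ = make_planted_dataset(
            PlantedDatasetSpec(n=2000, schema="gbr4", noise_sd=0.5, seed=21)
        )
        part = split(records, 0.1, seed=100)
        Xtr, ytr = records_to_xy(part.train, "gbr4")
        Xte, yte = records_to_xy(part.test, "gbr4")
        model = PackingAngleMLP(schema="gbr4", random_state=1).fit(Xtr, ytr)
        report = regression_metrics(yte, model.predict(Xte))
        assert report.pearson_r >= 0.9

    def test_different_seeds_differ_but_finite(self, planted):
        Xtr, ytr, Xte, _ = planted
        a = PackingAngleMLP(schema="gbr1", random_state=1, max_iter=80).fit(Xtr, ytr)
        b = PackingAngleMLP(schema="gbr1", random_state=2, max_iter=80).fit(Xtr, ytr)
        pa, pb = a.predict(Xte), b.predict(Xte)
        assert np.all(np.isfinite(pa)) and np.all(np.isfinite(pb))
        assert not np.allclose(pa, pb)

    def test_wrong_width_rejected(self, planted):
        Xtr, ytr, Xte, _ = planted
        model = PackingAngleMLP(schema="gbr1", random_state=0, max_iter=50).fit(Xtr, ytr)
        with pytest.raises(ValueError, match="features"):
            model.predict(Xte[:, :20])


class TestBundles:
    def test_train_predict_round_trip(self, tmp_path):
        records, _ = make_planted_dataset(PlantedDatasetSpec(n=300, seed=5))
        bundle = train_gbr(records, schema="gbr1",
                           config=GBRConfig(n_estimators=100, min_samples_leaf=2))
        path = tmp_path / "m.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        X, _ = records_to_xy(records[:1], "gbr1")
        assert loaded.predict_vector(X[0]) == pytest.approx(bundle.predict_vector(X[0]))

    def test_load_refuses_schema_mismatch(self, tmp_path):
        records, _ = make_planted_dataset(PlantedDatasetSpec(n=300, seed=5))
        bundle = train_gbr(records, schema="gbr1",
                           config=GBRConfig(n_estimators=50, min_samples_leaf=2))
        path = tmp_path / "m.joblib"
        bundle.save(path)
        with pytest.raises(ValueError, match="schema"):
            ModelBundle.load(path, expect_schema="gbr4")

    def test_predict_from_structure(self, fv_minus46):
        records, _ = make_planted_dataset(PlantedDatasetSpec(n=300, schema="gbr4", seed=6))
        bundle = train_gbr(records, schema="gbr4",
                           config=GBRConfig(n_estimators=50, min_samples_leaf=2))
        angle = predict(bundle, fv_minus46)
        assert np.isfinite(angle)
        vec = featurize(fv_minus46, "gbr4")
        assert angle == pytest.approx(bundle.predict_vector(vec))

    def test_gated_and_mlp_bundles(self):
        records, _ = make_planted_dataset(
            PlantedDatasetSpec(n=600, class_mix=(0.15, 0.7, 0.15), seed=8)
        )
        gated = train_gated(records, schema="gbr1",
                            gbr=GBRConfig(n_estimators=60, min_samples_leaf=2))
        assert gated.kind == "gated"
        mlp = train_mlp(records, schema="gbr1", max_iter=60, seed=0)
        assert mlp.kind == "mlp"
        X, _ = records_to_xy(records[:3], "gbr1")
        for bundle in (gated, mlp):
            assert np.isfinite(bundle.predict_vector(X[0]))


class TestCrossValidate:
    def test_leave_one_out_covers_every_record(self):
        records, _ = make_planted_dataset(PlantedDatasetSpec(n=20, seed=2))
        est = PackingAngleGBR(schema="gbr1", n_estimators=30, min_samples_leaf=2)
        pooled, folds, oof = cross_validate(records, "gbr1", est, folds=20, seed=4)
        assert oof.shape == (1, 20)
        assert np.all(np.isfinite(oof))
        assert pooled.n == 20

    def test_fold_assignment_reproducible(self):
        records, _ = make_planted_dataset(PlantedDatasetSpec(n=60, seed=2))
        est = PackingAngleGBR(schema="gbr1", n_estimators=20, min_samples_leaf=2)
        _, _, a = cross_validate(records, "gbr1", est, folds=5, seed=11)
        _, _, b = cross_validate(records, "gbr1", est, folds=5, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_repeats_predict_each_record_per_repeat(self):
        records, _ = make_planted_dataset(PlantedDatasetSpec(n=40, seed=2))
        est = PackingAngleGBR(schema="gbr1", n_estimators=20, min_samples_leaf=2)
        _, _, oof = cross_validate(records, "gbr1", est, folds=4, repeats=2, seed=1)
        assert oof.shape == (2, 40)
        assert np.all(np.isfinite(oof))

    def test_too_many_folds(self):
        records, _ = make_planted_dataset(PlantedDatasetSpec(n=5, seed=2))
        with pytest.raises(ValueError):
            cross_validate(records, "gbr1", folds=10)
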