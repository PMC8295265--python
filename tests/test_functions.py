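"""Function forests: IDR-restricted training sets, masking, recovery."""

import numpy as np
import pytest

import disofun as d
from disofun.functions import annotation_track
from disofun.pipeline import _encoder


def random_profile(rng, pid="p1", L=10):
    schema = d.default_schema()
    return d.Profile(pid, rng.random((L, schema.n_channels)), schema.channels)


def tiny_forest(rng, function="linker", n=80):
    """A forest trained on random function-task features (for masking tests)."""
    enc = _encoder(d.FUNCTION_ENCODING, None)
    X = rng.random((n, enc.n_features_))
    y = (rng.random(n) < 0.5).astype(int)
    return d.FunctionForest(
        function=function, n_estimators_grid=(10,), max_depth_grid=(3,), seed=1
    ).fit(X, y)


class TestBuildTrainingSet:
    def test_idr_annotation_intersection(self, rng):
        profile = random_profile(rng, L=10)
        predicted = {"p1": np.ones(10, dtype=int)}
        regions = [d.RegionAnnotation("p1", 1, 5, "protein_binding")]
        X, y = d.build_function_training_set([profile], predicted, regions, "protein_binding")
        assert X.shape[0] == 10
        np.testing.assert_array_equal(y, [1] * 5 + [0] * 5)

    def test_structured_protein_contributes_no_rows(self, rng):
        informative = random_profile(rng, "p1", 8)
        structured = random_profile(rng, "p2", 8)
        predicted = {"p1": np.ones(8, dtype=int), "p2": np.zeros(8, dtype=int)}
        X, _ = d.build_function_training_set(
            [informative, structured], predicted, [], "linker"
        )
        assert X.shape[0] == 8

    def test_annotation_outside_predicted_idr_all_negative(self, rng):
        profile = random_profile(rng, L=10)
        predicted = {"p1": np.array([1] * 3 + [0] * 7)}
        regions = [d.RegionAnnotation("p1", 6, 9, "dna_binding")]
        _, y = d.build_function_training_set([profile], predicted, regions, "dna_binding")
        assert y.sum() == 0 and len(y) == 3

    def test_no_disordered_residues_anywhere_rejected(self, rng):
        profile = random_profile(rng, L=6)
        with pytest.raises(ValueError, match="no predicted-disordered"):
            d.build_function_training_set(
                [profile], {"p1": np.zeros(6, dtype=int)}, [], "linker"
            )

    def test_functions_labelled_independently(self, rng):
        profile = random_profile(rng, L=10)
        predicted = {"p1": np.ones(10, dtype=int)}
        regions = [
            d.RegionAnnotation("p1", 1, 4, "protein_binding"),
            d.RegionAnnotation("p1", 5, 8, "linker"),
        ]
        _, y_with = d.build_function_training_set([profile], predicted, regions, "linker")
        no_pb = [r for r in regions if r.label != "protein_binding"]
        _, y_without = d.build_function_training_set([profile], predicted, no_pb, "linker")
        np.testing.assert_array_equal(y_with, y_without)


class TestFunctionForest:
    def test_grid_of_one_point_selected(self, rng):
        forest = tiny_forest(rng)
        assert forest.best_params_ == {"n_estimators": 10, "max_depth": 3}

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            d.FunctionForest(n_estimators_grid=(10,), max_depth_grid=(3,)).fit(
                rng.random((30, 5)), np.zeros(30)
            )

    def test_shuffled_labels_cv_auc_near_chance(self, rng):
        X = rng.random((400, 20))
        y = np.r_[np.zeros(200), np.ones(200)]
        rng.shuffle(y)
        forest = d.FunctionForest(
            n_estimators_grid=(50,), max_depth_grid=(5,), seed=1
        ).fit(X, y)
        assert 0.4 <= forest.cv_auc_ <= 0.6

    def test_planted_channel_signal_recovered(self, rng):
        X = rng.random((500, 10))
        y = (X[:, 3] + rng.normal(0, 0.1, 500) > 0.5).astype(int)
        forest = d.FunctionForest(
            n_estimators_grid=(100,), max_depth_grid=(None,), seed=1
        ).fit(X, y)
        from sklearn.metrics import roc_auc_score

        Xh = rng.random((300, 10))
        yh = (Xh[:, 3] + rng.normal(0, 0.1, 300) > 0.5).astype(int)
        assert roc_auc_score(yh, forest.propensity(Xh)) >= 0.9
        assert np.argmax(forest.feature_importances_) == 3

    def test_save_load(self, tmp_path, rng):
        forest = tiny_forest(rng)
        X = rng.random((10, forest.n_features_in_))
        forest.save(tmp_path / "rf")
        loaded = d.FunctionForest.load(tmp_path / "rf")
        np.testing.assert_allclose(loaded.propensity(X), forest.propensity(X))


class TestPredictFunctions:
    def _models(self, rng):
        return {f: tiny_forest(rng, f) for f in d.FUNCTION_LABELS}

    def test_fully_structured_prediction_all_zero(self, rng):
        models = self._models(rng)
        profile = random_profile(rng, L=5)
        prop, binary = d.predict_functions(models, profile, np.zeros(5, dtype=int))
        for f in d.FUNCTION_LABELS:
            assert prop[f].sum() == 0 and binary[f].sum() == 0

    def test_masking_limits_calls_to_idr(self, rng):
        models = self._models(rng)
        profile = random_profile(rng, L=5)
        disorder = np.array([1, 1, 1, 0, 0])
        prop, binary = d.predict_functions(models, profile, disorder)
        for f in d.FUNCTION_LABELS:
            assert (prop[f][3:] == 0).all() and (binary[f][3:] == 0).all()
            # function-positive implies disorder-positive
            assert set(np.flatnonzero(binary[f])) <= set(np.flatnonzero(disorder))

    def test_missing_model_rejected(self, rng):
        models = self._models(rng)
        del models["linker"]
        with pytest.raises(ValueError, match="linker"):
            d.predict_functions(models, random_profile(rng, L=5), np.ones(5, dtype=int))


def test_annotation_track_overlap_union():
    regions = [
        d.RegionAnnotation("p1", 1, 3, "linker"),
        d.RegionAnnotation("p1", 2, 4, "linker"),
        d.RegionAnnotation("p1", 2, 3, "dna_binding"),  # other labels ignored
    ]
    np.testing.assert_array_equal(annotation_track(regions, "p1", 5, "linker"), [1, 1, 1, 1, 0])


class TestTrainedFunctionModels:
    def test_each_model_ranks_its_planted_channel_highest(self, function_pipeline, suite):
        planted = {
            "protein_binding": "disordpbind_protein",
            "dna_binding": "disordpbind_dna",
            "rna_binding": "disordpbind_rna",
            "linker": "dflpred",
        }
        names = function_pipeline.function_encoder_.get_feature_names_out()
        for f, channel in planted.items():
            model = function_pipeline.function_models_[f]
            top = names[np.argmax(model.feature_importances_)]
            assert channel in top, (f, top)
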