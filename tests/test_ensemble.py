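"""Boosting: weight bookkeeping, the classifier-weight formula, vote
aggregation, the multi-class one-vs-rest bank, and JSON persistence."""

import numpy as np
import pytest
from sklearn.base import clone

from mirloop.ensemble import (
    BoostedHairpinClassifier,
    SpeciesBoostedClassifier,
    load_model,
    save_model,
    train_weak,
)
from mirloop.network import NetworkConfig

# 0.5 * ln((1 - eps) / eps), computed by hand
ALPHA_BY_EPS = {
    0.1: 1.0986122886681098,
    0.25: 0.5493061443340549,
    0.49: 0.020002667306849603,
}


def _gaussian_blobs(rng, n_per=40, centers=((-2, -2), (2, 2)), spread=0.6):
    X = np.vstack(
        [rng.normal(c, spread, size=(n_per, 2)) for c in centers]
    )
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


class TestAdaBoostFit:
    def test_weights_stay_on_simplex_every_round(self, rng):
        X, y = _gaussian_blobs(rng)
        clf = BoostedHairpinClassifier(
            n_rounds=5, n_hidden=3, random_state=0
        ).fit(X, y)
        assert len(clf.weight_history_) == len(clf.learners_)
        for w in clf.weight_history_:
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_alpha_formula_matches_hand_computation(self):
        for eps, expected in ALPHA_BY_EPS.items():
            eps_c = min(max(eps, 1e-10), 1 - 1e-10)
            assert 0.5 * np.log((1 - eps_c) / eps_c) == pytest.approx(expected)

    def test_perfect_learner_alpha_is_clamped_finite(self, rng):
        X, y = _gaussian_blobs(rng, centers=((-5, -5), (5, 5)), spread=0.2)
        clf = BoostedHairpinClassifier(
            n_rounds=3, n_hidden=3, random_state=0
        ).fit(X, y)
        assert np.all(np.isfinite(clf.alphas_))
        assert np.all(clf.alphas_ > 0)
        assert np.array_equal(clf.predict(X), y)

    def test_ensemble_training_error_le_first_learner(self, small_Xy):
        X, y = small_Xy
        clf = BoostedHairpinClassifier(n_rounds=5, random_state=3).fit(X, y)
        Xs = clf.scaler_.transform(X)
        y_signed = np.where(y == clf.classes_[1], 1.0, -1.0)
        first = np.where(clf.learners_[0].forward(Xs) >= 0, 1.0, -1.0)
        first_err = np.mean(first != y_signed)
        ens_err = np.mean(clf.predict(X) != y)
        assert ens_err <= first_err

    def test_rejects_single_class(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            BoostedHairpinClassifier(n_hidden=2).fit(X, np.zeros(10))


class TestAdaBoostPredict:
    def test_single_learner_equals_weak_learner(self, rng):
        X, y = _gaussian_blobs(rng)
        clf = BoostedHairpinClassifier(
            n_rounds=1, n_hidden=3, random_state=0
        ).fit(X, y)
        Xs = clf.scaler_.transform(X)
        weak = np.where(clf.learners_[0].forward(Xs) >= 0, 1, 0)
        np.testing.assert_array_equal(clf.predict(X), weak)

    def test_tie_score_falls_to_negative_class(self, rng):
        X, y = _gaussian_blobs(rng)
        clf = BoostedHairpinClassifier(
            n_rounds=2, n_hidden=3, random_state=0
        ).fit(X, y)
        # force two equal-weight learners voting oppositely
        clf.learners_ = clf.learners_[:1] * 2
        clf.alphas_ = np.array([1.0, 1.0])
        orig = clf.learners_[0]
        flipped = type(orig).from_dict(orig.to_dict())
        flipped.W2 = -flipped.W2
        flipped.b2 = -flipped.b2
        clf.learners_ = [orig, flipped]
        scores = clf.decision_function(X)
        np.testing.assert_allclose(scores, 0.0)
        assert np.all(clf.predict(X) == clf.classes_[0])

    def test_score_equals_brute_force_weighted_vote(self, small_Xy):
        X, y = small_Xy
        clf = BoostedHairpinClassifier(n_rounds=4, random_state=1).fit(X, y)
        Xs = clf.scaler_.transform(X[:10])
        expected = np.zeros(10)
        for net, alpha in zip(clf.learners_, clf.alphas_):
            expected += alpha * np.where(net.forward(Xs) >= 0, 1.0, -1.0)
        np.testing.assert_allclose(clf.decision_function(X[:10]), expected)

    def test_unfitted_predict_rejected(self, rng):
        with pytest.raises(Exception):
            BoostedHairpinClassifier().predict(rng.normal(size=(3, 2)))


class TestTrainWeak:
    def test_requires_simplex_weights(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.where(rng.random(10) > 0.5, 1.0, -1.0)
        config = NetworkConfig(n_inputs=2, n_hidden=2)
        with pytest.raises(ValueError):
            train_weak(X, y, np.ones(10), config, seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.where(X.sum(axis=1) > 0, 1.0, -1.0)
        w = np.full(20, 0.05)
        config = NetworkConfig(n_inputs=2, n_hidden=3)
        a = train_weak(X, y, w, config, seed=4)
        b = train_weak(X, y, w, config, seed=4)
        np.testing.assert_array_equal(a.W1, b.W1)


class TestMulticlass:
    def test_two_class_consistent_with_binary_path(self, rng):
        X, y = _gaussian_blobs(rng)
        multi = SpeciesBoostedClassifier(
            n_rounds=2, n_hidden=3, random_state=0
        ).fit(X, y)
        acc = np.mean(multi.predict(X) == y)
        assert acc > 0.9

    def test_three_well_separated_gaussians_beat_chance(self, rng):
        X, y = _gaussian_blobs(
            rng, centers=((-4, 0), (0, 4), (4, 0)), spread=0.5
        )
        clf = SpeciesBoostedClassifier(
            n_rounds=3, n_hidden=3, random_state=2
        ).fit(X, y)
        pred = clf.predict(X)
        for cls in np.unique(y):
            assert np.mean(pred[y == cls] == cls) > 1 / 3

    def test_argmax_matches_stored_scores(self, rng):
        X, y = _gaussian_blobs(rng, centers=((-3, 0), (0, 3), (3, 0)))
        clf = SpeciesBoostedClassifier(
            n_rounds=2, n_hidden=3, random_state=1
        ).fit(X, y)
        scores = clf.decision_function(X)
        np.testing.assert_array_equal(
            clf.predict(X), clf.classes_[np.argmax(scores, axis=1)]
        )


class TestPersistence:
    def test_binary_json_roundtrip_preserves_predictions(self, small_Xy, tmp_path):
        X, y = small_Xy
        clf = BoostedHairpinClassifier(n_rounds=3, random_state=5).fit(X, y)
        path = tmp_path / "model.json"
        save_model(clf, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict(X), clf.predict(X))
        np.testing.assert_allclose(
            loaded.decision_function(X), clf.decision_function(X)
        )

    def test_multiclass_json_roundtrip(self, rng, tmp_path):
        X, y = _gaussian_blobs(rng, centers=((-3, 0), (3, 0)))
        labels = np.where(y == 0, "sp_a", "sp_b")
        clf = SpeciesBoostedClassifier(
            n_rounds=2, n_hidden=3, random_state=0
        ).fit(X, labels)
        path = tmp_path / "model.json"
        save_model(clf, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict(X), clf.predict(X))


def test_sklearn_estimator_contract(small_Xy):
    X, y = small_Xy
    est = BoostedHairpinClassifier(n_rounds=2, random_state=0)
    params = est.get_params()
    assert params["n_rounds"] == 2
    cloned = clone(est)
    assert cloned.get_params() == params
    cloned.set_params(n_rounds=3)
    assert cloned.n_rounds == 3
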