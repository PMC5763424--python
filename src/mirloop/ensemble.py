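"""AdaBoost over back-propagation network weak learners.

:class:`BoostedHairpinClassifier` is the binary real-vs-pseudo classifier:
discrete AdaBoost (the classical AdaBoost.M1 weighting) whose round-``t``
weak learner is a small feedforward net trained on a weighted bootstrap of
the data.  :class:`SpeciesBoostedClassifier` extends it one-vs-rest for
species assignment.  Both follow the scikit-learn estimator contract
(``fit`` / ``predict`` / ``decision_function``, ``get_params``, fitted
attributes with trailing underscores) and therefore compose with sklearn
pipelines and model selection.

Per boosting round: sample weights (initialized uniform, kept on the
probability simplex) drive a bootstrap resample; the trained learner's
weighted 0/1 error eps_t on the full set gives the classifier weight
alpha_t = 0.5 * ln((1 - eps_t) / eps_t) with eps clamped away from {0, 1};
weights of misclassified samples are raised and of correct ones lowered via
w_i <- w_i * exp(-alpha_t * y_i * h_t(x_i)) and renormalized.  A round with
eps_t >= 0.5 is retrained once from a fresh seed and, failing that, stops
the boosting early.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .network import BPNetwork, NetworkConfig

__all__ = [
    "BoostedHairpinClassifier",
    "SpeciesBoostedClassifier",
    "train_weak",
    "adaboost_fit",
    "multiclass_fit",
    "save_model",
    "load_model",
]

MODEL_SCHEMA_VERSION = "mirloop-model-1"
_EPS_CLAMP = 1e-10


def train_weak(
    X: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray,
    config: NetworkConfig,
    seed: int,
) -> BPNetwork:
    """Train one weak learner on a weighted bootstrap of (X, y).

    ``y`` holds +/-1 targets and ``sample_weights`` a probability vector
    over the rows; the net itself has no native sample-weight support, so
    the weighting is realized by resampling ``n`` rows with replacement
    proportionally to the weights before an ordinary MSE fit.
    """
    sample_weights = np.asarray(sample_weights, dtype=float)
    if not np.isclose(sample_weights.sum(), 1.0, atol=1e-9):
        raise ValueError("sample_weights must sum to 1")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    idx = rng.choice(n, size=n, replace=True, p=sample_weights)
    net = BPNetwork(config, rng)
    net.fit(X[idx], y[idx])
    return net


def _hypothesis(net: BPNetwork, X: np.ndarray) -> np.ndarray:
    """Discrete +/-1 hypothesis: threshold the network score at 0."""
    return np.where(net.forward(X) >= 0.0, 1.0, -1.0)


class BoostedHairpinClassifier(ClassifierMixin, BaseEstimator):
    """Binary AdaBoost ensemble of small back-propagation networks.

    Parameters
    ----------
    n_rounds : int, default 10
        Boosting rounds (weak learners) to train.
    n_hidden : int or None
        Hidden-layer size; ``None`` derives it from the empirical formula
        ``round(sqrt(n_features + 1) + a_offset)`` (12 for 98 features).
    a_offset : int, default 2
        Offset of the node-count formula, in [1, 10].
    epochs, learning_rate, error_bound, trainer
        Weak-learner training controls; see :class:`NetworkConfig`.
    threshold : float, default 0.0
        Decision threshold on the aggregated score; ties fall to the
        negative class.
    random_state : int or None
        Seed for weight initialization and bootstrap resampling.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; the first maps to -1, the second to +1.
    learners_ : list of BPNetwork
    alphas_ : ndarray
        Classifier weights, one per kept learner, all positive.
    weight_history_ : list of ndarray
        Sample-weight vector after each round's update (each sums to 1).
    scaler_ : StandardScaler
        Per-column standardization fitted on the training data; mixed
        feature scales (frequencies vs kcal/mol) otherwise swamp the
        tansig units.
    """

    def __init__(
        self,
        n_rounds: int = 10,
        n_hidden: int | None = None,
        a_offset: int = 2,
        epochs: int = 50,
        learning_rate: float = 0.1,
        error_bound: float = 0.01,
        trainer: str = "levenberg_marquardt",
        threshold: float = 0.0,
        random_state: int | None = None,
    ):
        self.n_rounds = n_rounds
        self.n_hidden = n_hidden
        self.a_offset = a_offset
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.error_bound = error_bound
        self.trainer = trainer
        self.threshold = threshold
        self.random_state = random_state

    def _network_config(self, n_features: int) -> NetworkConfig:
        return NetworkConfig(
            n_inputs=n_features,
            n_hidden=self.n_hidden,
            n_outputs=1,
            a_offset=self.a_offset,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            error_bound=self.error_bound,
            trainer=self.trainer,
        )

    def fit(self, X, y) -> "BoostedHairpinClassifier":
        X, y = check_X_y(X, y)
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly 2 classes, got {len(self.classes_)}"
            )
        y_signed = np.where(y == self.classes_[1], 1.0, -1.0)
        self.n_features_in_ = X.shape[1]
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)

        config = self._network_config(self.n_features_in_)
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.learners_: list[BPNetwork] = []
        self.alphas_list_: list[float] = []
        self.weight_history_: list[np.ndarray] = []
        for _ in range(self.n_rounds):
            net = train_weak(Xs, y_signed, w, config, int(rng.integers(2**31)))
            h = _hypothesis(net, Xs)
            eps = float(w[h != y_signed].sum())
            if eps >= 0.5:
                # one retry from a fresh seed, then stop boosting early
                net = train_weak(Xs, y_signed, w, config, int(rng.integers(2**31)))
                h = _hypothesis(net, Xs)
                eps = float(w[h != y_signed].sum())
                if eps >= 0.5:
                    break
            eps_c = min(max(eps, _EPS_CLAMP), 1.0 - _EPS_CLAMP)
            alpha = 0.5 * np.log((1.0 - eps_c) / eps_c)
            w = w * np.exp(-alpha * y_signed * h)
            w = w / w.sum()
            self.learners_.append(net)
            self.alphas_list_.append(float(alpha))
            self.weight_history_.append(w.copy())
        if not self.learners_:
            raise RuntimeError(
                "boosting failed: no weak learner beat chance (round 1)"
            )
        self.alphas_ = np.asarray(self.alphas_list_)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Aggregated vote score sum_t alpha_t * h_t(x) (h_t in {-1, +1})."""
        check_is_fitted(self, "learners_")
        X = check_array(X)
        Xs = self.scaler_.transform(X)
        score = np.zeros(X.shape[0])
        for net, alpha in zip(self.learners_, self.alphas_):
            score += alpha * _hypothesis(net, Xs)
        return score

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return self.classes_[(score > self.threshold).astype(int)]

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "learners_")
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "binary",
            "params": self.get_params(),
            "classes": self.classes_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "alphas": self.alphas_.tolist(),
            "learners": [net.to_dict() for net in self.learners_],
            "n_features_in": self.n_features_in_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BoostedHairpinClassifier":
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema {payload.get('schema_version')!r}"
            )
        model = cls(**payload["params"])
        model.classes_ = np.asarray(payload["classes"])
        model.n_features_in_ = payload["n_features_in"]
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(payload["scaler_mean"], dtype=float)
        scaler.scale_ = np.asarray(payload["scaler_scale"], dtype=float)
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = model.n_features_in_
        scaler.n_samples_seen_ = 1
        scaler.with_mean = scaler.with_std = True
        model.scaler_ = scaler
        model.learners_ = [BPNetwork.from_dict(p) for p in payload["learners"]]
        model.alphas_ = np.asarray(payload["alphas"], dtype=float)
        model.alphas_list_ = model.alphas_.tolist()
        model.weight_history_ = []
        return model


class SpeciesBoostedClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-rest bank of boosted ensembles for multi-class species calls.

    One binary :class:`BoostedHairpinClassifier` is trained per species
    (that species vs the rest); prediction takes the argmax of per-class
    scores normalized by the total vote mass, with ties resolved to the
    lowest class index in the sorted label order.  Takes the same
    hyperparameters as the binary classifier.
    """

    def __init__(
        self,
        n_rounds: int = 10,
        n_hidden: int | None = None,
        a_offset: int = 2,
        epochs: int = 50,
        learning_rate: float = 0.1,
        error_bound: float = 0.01,
        trainer: str = "levenberg_marquardt",
        random_state: int | None = None,
    ):
        self.n_rounds = n_rounds
        self.n_hidden = n_hidden
        self.a_offset = a_offset
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.error_bound = error_bound
        self.trainer = trainer
        self.random_state = random_state

    def fit(self, X, y) -> "SpeciesBoostedClassifier":
        X, y = check_X_y(X, y, dtype=None)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for cls in self.classes_:
            binary = BoostedHairpinClassifier(
                n_rounds=self.n_rounds,
                n_hidden=self.n_hidden,
                a_offset=self.a_offset,
                epochs=self.epochs,
                learning_rate=self.learning_rate,
                error_bound=self.error_bound,
                trainer=self.trainer,
                random_state=int(rng.integers(2**31)),
            )
            binary.fit(X, (y == cls).astype(int))
            self.estimators_.append(binary)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class normalized vote margins, shape (n_samples, n_classes)."""
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        scores = np.column_stack(
            [
                est.decision_function(X) / est.alphas_.sum()
                for est in self.estimators_
            ]
        )
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def to_dict(self) -> dict:
        check_is_fitted(self, "estimators_")
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "multiclass",
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "estimators": [est.to_dict() for est in self.estimators_],
            "n_features_in": self.n_features_in_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SpeciesBoostedClassifier":
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema {payload.get('schema_version')!r}"
            )
        model = cls(**payload["params"])
        model.classes_ = np.asarray(payload["classes"])
        model.n_features_in_ = payload["n_features_in"]
        model.estimators_ = [
            BoostedHairpinClassifier.from_dict(p) for p in payload["estimators"]
        ]
        return model


# -- thin functional wrappers -----------------------------------------------

def adaboost_fit(X, y, rounds: int = 10, seed: int | None = None, **kwargs):
    """Fit a binary boosted ensemble; wrapper over the estimator class."""
    return BoostedHairpinClassifier(
        n_rounds=rounds, random_state=seed, **kwargs
    ).fit(X, y)


def multiclass_fit(X, species_labels, rounds: int = 10, seed: int | None = None, **kwargs):
    """Fit a one-vs-rest species classifier; wrapper over the estimator."""
    return SpeciesBoostedClassifier(
        n_rounds=rounds, random_state=seed, **kwargs
    ).fit(X, species_labels)


def save_model(model, path) -> None:
    """Serialize a fitted (binary or multi-class) model to JSON."""
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path):
    """Load a model saved by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") == "multiclass":
        return SpeciesBoostedClassifier.from_dict(payload)
    return BoostedHairpinClassifier.from_dict(payload)
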