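"""The back-propagation weak learner: a single-hidden-layer feedforward net.

Architecture is input -> tansig hidden layer -> purelin (linear) scalar
output; with the 98-feature vector and the empirical node-count formula the
instantiated shape is 98-12-1.  Training minimizes the mean squared error
against +/-1 targets, either by Levenberg-Marquardt (the default; fast on a
net this small) or by plain batch gradient descent, stopping at the epoch
cap or as soon as the MSE drops below the error bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkConfig", "BPNetwork", "hidden_nodes", "tansig", "purelin"]

TRAINERS = ("levenberg_marquardt", "gradient_descent")


def hidden_nodes(n_inputs: int, n_outputs: int, a_offset: int) -> int:
    """Empirical hidden-layer size: round(sqrt(N + L) + a).

    ``N`` inputs, ``L`` outputs, integer offset ``a`` in [1, 10].  With the
    98-feature vector, one output and a = 2 this gives 12 hidden nodes.
    Rounding is half-up for determinism.
    """
    if n_inputs < 1 or n_outputs < 1:
        raise ValueError("n_inputs and n_outputs must be >= 1")
    if not (1 <= a_offset <= 10):
        raise ValueError(f"a_offset must be in [1, 10], got {a_offset}")
    return int(math.floor(math.sqrt(n_inputs + n_outputs) + a_offset + 0.5))


def tansig(x):
    """Hyperbolic-tangent sigmoid transfer function."""
    return np.tanh(x)


def purelin(x):
    """Identity (linear) transfer function."""
    return x


@dataclass
class NetworkConfig:
    """Hyperparameters of the weak learner.

    ``n_hidden=None`` derives the hidden-layer size from the node-count
    formula with ``a_offset``.  ``error_bound`` is the MSE at which training
    stops early; ``learning_rate`` only applies to the gradient-descent
    trainer (Levenberg-Marquardt adapts its own damping).
    """

    n_inputs: int = 98
    n_hidden: int | None = None
    n_outputs: int = 1
    a_offset: int = 2
    epochs: int = 50
    learning_rate: float = 0.1
    error_bound: float = 0.01
    trainer: str = "levenberg_marquardt"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.error_bound <= 0:
            raise ValueError("error_bound must be > 0")
        if self.trainer not in TRAINERS:
            raise ValueError(f"trainer must be one of {TRAINERS}")
        if self.n_hidden is None:
            self.n_hidden = hidden_nodes(self.n_inputs, self.n_outputs, self.a_offset)


class BPNetwork:
    """One trained feedforward network (the boosting weak learner).

    Weights are initialized uniformly in [-0.5, 0.5] from a seeded
    generator; the forward pass is a pure function of the stored weights.
    Diagnostics after :meth:`fit`: ``final_mse_``, ``epochs_run_``,
    ``warning_``.
    """

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        h, d = config.n_hidden, config.n_inputs
        self.W1 = rng.uniform(-0.5, 0.5, size=(h, d))
        self.b1 = rng.uniform(-0.5, 0.5, size=h)
        self.W2 = rng.uniform(-0.5, 0.5, size=h)
        self.b2 = rng.uniform(-0.5, 0.5)
        self.final_mse_: float | None = None
        self.epochs_run_: int = 0
        self.warning_: str | None = None

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output purelin(W2 . tansig(W1 x + b1) + b2) per row."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X2 = X[None, :] if single else X
        if X2.shape[1] != self.config.n_inputs:
            raise ValueError(
                f"expected {self.config.n_inputs} inputs, got {X2.shape[1]}"
            )
        hidden = tansig(X2 @ self.W1.T + self.b1)
        out = purelin(hidden @ self.W2 + self.b2)
        return out[0] if single else out

    # -- parameter flattening (for Levenberg-Marquardt) --------------------
    def _get_params(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2, [self.b2]]
        )

    def _set_params(self, theta: np.ndarray) -> None:
        h, d = self.config.n_hidden, self.config.n_inputs
        self.W1 = theta[: h * d].reshape(h, d)
        self.b1 = theta[h * d : h * d + h]
        self.W2 = theta[h * d + h : h * d + 2 * h]
        self.b2 = float(theta[-1])

    def _jacobian(self, X: np.ndarray):
        """Jacobian of the outputs w.r.t. the flattened parameters."""
        hidden_pre = X @ self.W1.T + self.b1
        a1 = np.tanh(hidden_pre)
        out = a1 @ self.W2 + self.b2
        gate = (1.0 - a1**2) * self.W2  # d out / d hidden_pre, (n, h)
        n = X.shape[0]
        J_W1 = (gate[:, :, None] * X[:, None, :]).reshape(n, -1)
        J = np.concatenate(
            [J_W1, gate, a1, np.ones((n, 1))], axis=1
        )
        return out, J

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "BPNetwork":
        """Train on (X, y) to minimize MSE; y should be +/-1 targets."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if len(np.unique(y)) < 2:
            self.warning_ = "single-class targets; trained a constant model"
        if self.config.trainer == "levenberg_marquardt":
            self._fit_lm(X, y)
        else:
            self._fit_gd(X, y)
        return self

    def _fit_lm(self, X: np.ndarray, y: np.ndarray) -> None:
        cfg = self.config
        theta = self._get_params()
        mu = 1e-2
        n, p = X.shape[0], theta.size
        mse = float(np.mean((y - self.forward(X)) ** 2))
        for epoch in range(cfg.epochs):
            self.epochs_run_ = epoch + 1
            if mse <= cfg.error_bound:
                self.epochs_run_ = epoch
                break
            out, J = self._jacobian(X)
            r = y - out
            improved = False
            for _ in range(12):
                # (J'J + mu I)^-1 J'r, via the dual when parameters
                # outnumber samples.
                try:
                    if p <= n:
                        A = J.T @ J
                        A[np.diag_indices_from(A)] += mu
                        delta = np.linalg.solve(A, J.T @ r)
                    else:
                        A = J @ J.T
                        A[np.diag_indices_from(A)] += mu
                        delta = J.T @ np.linalg.solve(A, r)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                candidate = theta + delta
                self._set_params(candidate)
                new_mse = float(np.mean((y - self.forward(X)) ** 2))
                if new_mse < mse:
                    theta, mse = candidate, new_mse
                    mu = max(mu / 10.0, 1e-12)
                    improved = True
                    break
                mu *= 10.0
            if not improved:
                self._set_params(theta)
                break
        self._set_params(theta)
        self.final_mse_ = mse

    def _fit_gd(self, X: np.ndarray, y: np.ndarray) -> None:
        cfg = self.config
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            self.epochs_run_ = epoch + 1
            hidden_pre = X @ self.W1.T + self.b1
            a1 = np.tanh(hidden_pre)
            out = a1 @ self.W2 + self.b2
            r = out - y
            mse = float(np.mean(r**2))
            if mse <= cfg.error_bound:
                self.epochs_run_ = epoch
                break
            # batch gradients of the mean squared error
            g_out = 2.0 * r / n
            gW2 = g_out @ a1
            gb2 = g_out.sum()
            g_hidden = (g_out[:, None] * self.W2) * (1.0 - a1**2)
            gW1 = g_hidden.T @ X
            gb1 = g_hidden.sum(axis=0)
            lr = cfg.learning_rate
            self.W1 -= lr * gW1
            self.b1 -= lr * gb1
            self.W2 -= lr * gW2
            self.b2 -= lr * gb2
        self.final_mse_ = float(np.mean((y - self.forward(X)) ** 2))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_inputs": self.config.n_inputs,
            "n_hidden": self.config.n_hidden,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2,
            "final_mse": self.final_mse_,
            "epochs_run": self.epochs_run_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BPNetwork":
        config = NetworkConfig(
            n_inputs=payload["n_inputs"], n_hidden=payload["n_hidden"]
        )
        net = cls.__new__(cls)
        net.config = config
        net.W1 = np.asarray(payload["W1"], dtype=float)
        net.b1 = np.asarray(payload["b1"], dtype=float)
        net.W2 = np.asarray(payload["W2"], dtype=float)
        net.b2 = float(payload["b2"])
        net.final_mse_ = payload.get("final_mse")
        net.epochs_run_ = payload.get("epochs_run", 0)
        net.warning_ = None
        return net
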