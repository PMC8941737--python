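"""Extreme learning machine: random hidden layer, least-squares output.

A single-hidden-layer feedforward network whose input weights ``P`` and
biases ``t`` are drawn once from a seeded uniform[-1, 1] and never
adjusted; the hidden activations ``H(j, i) = f(p_i . x_j + t_i)`` then
make training a linear least-squares problem, solved in closed form by the
Moore-Penrose pseudoinverse: ``q = pinv(H) @ l``.  Continuous outputs
``O_j = H q`` are used directly for ranking/ROC; hard labels threshold
them at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class ELMModel:
    input_weights: np.ndarray  # (n_hidden, n_features)
    biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden, n_outputs)
    activation: str
    seed: int

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.input_weights.shape[1]


def _hidden(X: np.ndarray, P: np.ndarray, t: np.ndarray, activation: str) -> np.ndarray:
    f = _ACTIVATIONS[activation]
    return f(X @ P.T + t)


def _draw_hidden_layer(n_hidden: int, n_features: int, seed: int):
    # one (p_i, t_i) row per hidden unit, so hidden layers drawn with the
    # same seed nest: the first k units are identical for any n_hidden >= k
    rng = np.random.default_rng(seed)
    block = rng.uniform(-1.0, 1.0, size=(n_hidden, n_features + 1))
    return block[:, :n_features], block[:, n_features]


def elm_fit(
    X: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 500,
    activation: str = "sigmoid",
    seed: int = 0,
    one_hot: bool = False,
    l2: float = 0.0,
) -> ELMModel:
    """Fit output weights by least squares on a random hidden layer.

    ``labels`` are binary {0,1}; they form a single output column unless
    ``one_hot`` requests a two-column indicator target for multi-class
    reuse.  ``l2`` adds an optional ridge term for ill-conditioned hidden
    matrices (off by default).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 samples")
    if X.shape[1] < 1:
        raise ValueError("feature matrix has zero features")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation: {activation!r}")
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all() or classes.size < 2:
        raise ValueError("labels must contain both classes 0 and 1")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")

    P, t = _draw_hidden_layer(n_hidden, X.shape[1], seed)
    H = _hidden(X, P, t, activation)
    if one_hot:
        L = np.stack([(labels == 0).astype(float), (labels == 1).astype(float)], axis=1)
    else:
        L = labels.astype(float)[:, None]
    if l2 > 0.0:
        q = linalg.solve(
            H.T @ H + l2 * np.eye(n_hidden), H.T @ L, assume_a="pos"
        )
    else:
        q = linalg.lstsq(H, L, lapack_driver="gelsd")[0]
    return ELMModel(P, t, q, activation, seed)


def elm_score(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Continuous network outputs O_j; ranking/ROC uses these directly."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    out = _hidden(X, model.input_weights, model.biases, model.activation) \
        @ model.output_weights
    return out.ravel() if out.shape[1] == 1 else out


def elm_predict(model: ELMModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff score >= threshold (argmax for one-hot models)."""
    scores = elm_score(model, X)
    if scores.ndim == 2:
        return scores.argmax(axis=1).astype(np.int8)
    return (scores >= threshold).astype(np.int8)
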