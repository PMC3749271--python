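"""Five-layer autoencoder extracting nonlinear principal components.

Architecture (unit counts): input N -> h (sigmoid) -> m (linear bottleneck)
-> h (sigmoid) -> output N (linear). Trained by full-batch back-propagation
on the mean squared reconstruction error with momentum 0.8 and an adaptive
learning rate (grow 5% after an accepted step, halve and retry after a
rejected one). The bottleneck activations are the nonlinear principal
components of the input; with identity activations the network reduces to
a linear autoencoder whose optimal reconstruction error equals the m-rank
PCA error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from anpca.data import ConfigurationError, DimensionError

__all__ = ["MnnModel", "build_mnn", "train_mnn", "extract_nonlinear_pcs", "reconstruct"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass
class MnnModel:
    """Weights of the five-layer bottleneck network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    nonlinear: bool = True          # False = identity activations (linear limit)
    learning_rate: float = 0.3
    momentum: float = 0.8
    velocity_w: list[np.ndarray] = field(default_factory=list)
    velocity_b: list[np.ndarray] = field(default_factory=list)

    @property
    def n_in(self) -> int:
        return self.weights[0].shape[1]

    @property
    def bottleneck(self) -> int:
        return self.weights[1].shape[0]

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_in,) + tuple(w.shape[0] for w in self.weights)


def build_mnn(
    n_in: int,
    m_bottleneck: int,
    h: int | None = None,
    seed: int = 0,
    nonlinear: bool = True,
    learning_rate: float = 0.3,
    momentum: float = 0.8,
) -> MnnModel:
    """Build a seeded network with layer sizes (N, h, m, h, N).

    The hidden width defaults to ``2 * n_in`` so the sigmoid approximation
    layers are wider than the bottleneck.
    """
    if not (1 <= m_bottleneck < n_in):
        raise ConfigurationError(
            f"bottleneck must satisfy 1 <= m < n_in, got m={m_bottleneck}, n_in={n_in}"
        )
    h = h or 2 * n_in
    if h < 1:
        raise ConfigurationError("hidden width must be >= 1")
    sizes = (n_in, h, m_bottleneck, h, n_in)
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-scale, scale, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    model = MnnModel(
        weights=weights, biases=biases, nonlinear=nonlinear,
        learning_rate=learning_rate, momentum=momentum,
    )
    model.velocity_w = [np.zeros_like(w) for w in weights]
    model.velocity_b = [np.zeros_like(b) for b in biases]
    return model


def _forward(model: MnnModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer for data ``samples x n_in``; returns [a0..a4]."""
    act = _sigmoid if model.nonlinear else (lambda z: z)
    a = [X]
    # layers 1 and 3 are nonlinear, layers 2 and 4 linear
    z1 = a[0] @ model.weights[0].T + model.biases[0]
    a.append(act(z1))
    a.append(a[1] @ model.weights[1].T + model.biases[1])
    z3 = a[2] @ model.weights[2].T + model.biases[2]
    a.append(act(z3))
    a.append(a[3] @ model.weights[3].T + model.biases[3])
    return a


def reconstruct(model: MnnModel, data: np.ndarray) -> np.ndarray:
    """Autoencoder output for ``samples x n_in`` data."""
    X = _check_data(model, data)
    return _forward(model, X)[-1]


def _check_data(model: MnnModel, data: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(data, float))
    if X.shape[1] != model.n_in:
        raise DimensionError(
            f"data has {X.shape[1]} columns, network expects {model.n_in}"
        )
    return X


def _gradients(model: MnnModel, X: np.ndarray):
    """Back-propagated MSE gradients; returns (loss, dW list, db list)."""
    a = _forward(model, X)
    n = X.shape[0]
    err = a[4] - X
    loss = 0.5 * float(np.mean(np.sum(err**2, axis=1)))

    deltas = [None] * 4
    deltas[3] = err / n                                   # linear output layer
    d = deltas[3] @ model.weights[3]
    if model.nonlinear:
        d = d * a[3] * (1 - a[3])                         # sigmoid derivative
    deltas[2] = d
    deltas[1] = deltas[2] @ model.weights[2]              # linear bottleneck
    d = deltas[1] @ model.weights[1]
    if model.nonlinear:
        d = d * a[1] * (1 - a[1])
    deltas[0] = d

    dW = [deltas[i].T @ a[i] for i in range(4)]
    db = [deltas[i].sum(axis=0) for i in range(4)]
    return loss, dW, db


def train_mnn(
    model: MnnModel, data: np.ndarray, epochs: int
) -> tuple[MnnModel, np.ndarray]:
    """Train by full-batch gradient descent with momentum.

    A step that increases the loss is undone and the learning rate halved;
    an accepted step grows the rate by 5%. The returned loss trace holds
    the accepted loss per epoch and is therefore non-increasing.
    """
    X = _check_data(model, data)
    trace = []
    loss, dW, db = _gradients(model, X)
    for _ in range(epochs):
        saved = (
            [w.copy() for w in model.weights],
            [b.copy() for b in model.biases],
            [v.copy() for v in model.velocity_w],
            [v.copy() for v in model.velocity_b],
        )
        for i in range(4):
            model.velocity_w[i] = model.momentum * model.velocity_w[i] - model.learning_rate * dW[i]
            model.velocity_b[i] = model.momentum * model.velocity_b[i] - model.learning_rate * db[i]
            model.weights[i] = model.weights[i] + model.velocity_w[i]
            model.biases[i] = model.biases[i] + model.velocity_b[i]
        new_loss, new_dW, new_db = _gradients(model, X)
        if not np.isfinite(new_loss):
            raise RuntimeError("training produced a non-finite loss; reduce the learning rate")
        if new_loss > loss:
            model.weights, model.biases, _, _ = saved
            # a rejected step means the momentum direction is bad: replaying
            # it would be rejected forever, so the velocity is reset
            model.velocity_w = [np.zeros_like(w) for w in model.weights]
            model.velocity_b = [np.zeros_like(b) for b in model.biases]
            model.learning_rate *= 0.5
        else:
            loss, dW, db = new_loss, new_dW, new_db
            model.learning_rate *= 1.05
        trace.append(loss)
    return model, np.asarray(trace)


def extract_nonlinear_pcs(model: MnnModel, data: np.ndarray) -> np.ndarray:
    """Bottleneck (layer-2) activations: ``samples x m`` component matrix."""
    X = _check_data(model, data)
    return _forward(model, X)[2]
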