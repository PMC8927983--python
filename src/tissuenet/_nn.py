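"""Minimal dense neural-network machinery (numpy only).

Provides exactly what the autoencoder stages need: fully connected layers
with ReLU / linear / softplus activations, an Adam optimizer, mean-squared
reconstruction loss, softmax cross-entropy for the adversary head, and a
seeded training loop with validation-based early stopping.  All randomness
flows through :class:`numpy.random.Generator` streams spawned from a single
seed, so identical seeds give bit-identical training trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Dense",
    "MLP",
    "Adam",
    "Autoencoder",
    "fit_autoencoder",
    "softmax",
    "cross_entropy",
]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _drelu(pre: np.ndarray) -> np.ndarray:
    return (pre > 0).astype(pre.dtype)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _dsoftplus(pre: np.ndarray) -> np.ndarray:
    # derivative of softplus is the logistic sigmoid
    return 1.0 / (1.0 + np.exp(-pre))


def _identity(x: np.ndarray) -> np.ndarray:
    return x


def _done(pre: np.ndarray) -> np.ndarray:
    return np.ones_like(pre)


_ACTIVATIONS = {
    "relu": (_relu, _drelu),
    "linear": (_identity, _done),
    "softplus": (_softplus, _dsoftplus),
}


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Mean categorical cross-entropy over a batch."""
    eps = 1e-12
    return float(-(onehot * np.log(probs + eps)).sum(axis=1).mean())


class Dense:
    """One fully connected layer with a named activation.

    Weights use a seeded uniform-He initialization: U(-l, l) with
    l = sqrt(6 / fan_in); biases start at zero.
    """

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        limit = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._act, self._dact = _ACTIVATIONS[activation]
        self._X: np.ndarray | None = None
        self._pre: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, X: np.ndarray, cache: bool = True) -> np.ndarray:
        pre = X @ self.W + self.b
        if cache:
            self._X, self._pre = X, pre
        return self._act(pre)

    def backward(self, dA: np.ndarray, accumulate: bool = True) -> np.ndarray:
        """Backprop dLoss/d(activation output); returns dLoss/d(input)."""
        dpre = dA * self._dact(self._pre)
        if accumulate:
            self.dW = self._X.T @ dpre
            self.db = dpre.sum(axis=0)
        return dpre @ self.W.T


class MLP:
    """A stack of Dense layers sharing a forward/backward interface."""

    def __init__(self, dims: Sequence[int], activations: Sequence[str], rng: np.random.Generator):
        if len(activations) != len(dims) - 1:
            raise ValueError("need one activation per layer")
        self.layers = [
            Dense(dims[i], dims[i + 1], activations[i], rng) for i in range(len(dims) - 1)
        ]

    def forward(self, X: np.ndarray, cache: bool = True) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out, cache=cache)
        return out

    def backward(self, dOut: np.ndarray, accumulate: bool = True) -> np.ndarray:
        grad = dOut
        for layer in reversed(self.layers):
            grad = layer.backward(grad, accumulate=accumulate)
        return grad

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend([layer.W, layer.b])
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend([layer.dW, layer.db])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class Autoencoder:
    """Trained encoder/decoder pair plus the input scaler used for training.

    ``mean`` / ``scale`` are per-feature statistics applied before encoding
    and inverted after decoding (all-ones/zeros when standardization was
    disabled).
    """

    encoder: MLP
    decoder: MLP
    mean: np.ndarray
    scale: np.ndarray
    history: dict = field(default_factory=dict)

    def encode(self, X: np.ndarray) -> np.ndarray:
        return self.encoder.forward((X - self.mean) / self.scale, cache=False)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        Z = self.encode(X)
        return self.decoder.forward(Z, cache=False) * self.scale + self.mean


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def fit_autoencoder(
    X: np.ndarray,
    *,
    embedding_dim: int,
    hidden_dim: int | None = None,
    embedding_activation: str = "relu",
    learning_rate: float = 1e-3,
    minibatch_size: int = 128,
    max_epochs: int = 200,
    patience: int = 10,
    val_fraction: float = 0.2,
    standardize: bool = True,
    seed: int = 0,
    restarts: int = 1,
) -> Autoencoder:
    """Train a one-hidden-layer autoencoder on rows of ``X``.

    Architecture: input -> hidden (ReLU) -> embedding (``embedding_activation``)
    -> hidden (ReLU) -> output (linear), hidden defaulting to half the input
    dimension.  Optimized by Adam on mean squared error with an 80/20
    train/validation split; the returned weights are the ones minimizing
    validation loss, and training stops once validation loss has not improved
    for ``patience`` epochs.

    ``restarts > 1`` trains that many models from derived seeds and keeps the
    one with the lowest validation loss — narrow rectified bottlenecks
    occasionally die at initialization, and a restart is the reliable cure.
    """
    if restarts > 1:
        fits = [
            fit_autoencoder(
                X, embedding_dim=embedding_dim, hidden_dim=hidden_dim,
                embedding_activation=embedding_activation, learning_rate=learning_rate,
                minibatch_size=minibatch_size, max_epochs=max_epochs, patience=patience,
                val_fraction=val_fraction, standardize=standardize,
                seed=int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2 ** 31)),
                restarts=1,
            )
            for r in range(restarts)
        ]
        return min(fits, key=lambda ae: ae.history["best_val_mse"])
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    n, m = X.shape
    if embedding_dim >= m:
        raise ValueError(f"embedding_dim {embedding_dim} must be < input dim {m}")
    if hidden_dim is None:
        hidden_dim = max(int(np.ceil(m / 2)), embedding_dim)

    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(m)
        scale = np.ones(m)
    Xs = (X - mean) / scale

    ss = np.random.SeedSequence(seed)
    rng_split, rng_enc, rng_dec, rng_shuffle = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    encoder = MLP([m, hidden_dim, embedding_dim], ["relu", embedding_activation], rng_enc)
    decoder = MLP([embedding_dim, hidden_dim, m], ["relu", "linear"], rng_dec)

    n_val = int(round(n * val_fraction))
    order = rng_split.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xtr, Xval = Xs[train_idx], Xs[val_idx]

    opt = Adam(encoder.params + decoder.params, lr=learning_rate)
    history: dict[str, list[float]] = {"train_mse": [], "val_mse": []}
    best_val = np.inf
    best_state: tuple[list[np.ndarray], list[np.ndarray]] | None = None
    stale = 0

    for _epoch in range(max_epochs):
        for idx in _minibatches(len(Xtr), minibatch_size, rng_shuffle):
            xb = Xtr[idx]
            Z = encoder.forward(xb)
            Xh = decoder.forward(Z)
            dXh = 2.0 * (Xh - xb) / xb.size
            dZ = decoder.backward(dXh)
            encoder.backward(dZ)
            opt.step(encoder.grads + decoder.grads)

        train_mse = float(np.mean((decoder.forward(encoder.forward(Xtr, cache=False), cache=False) - Xtr) ** 2))
        monitor = Xval if len(Xval) else Xtr
        val_mse = float(np.mean((decoder.forward(encoder.forward(monitor, cache=False), cache=False) - monitor) ** 2))
        history["train_mse"].append(train_mse)
        history["val_mse"].append(val_mse)

        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_state = (encoder.get_state(), decoder.get_state())
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    if best_state is not None:
        encoder.set_state(best_state[0])
        decoder.set_state(best_state[1])
    history["best_val_mse"] = best_val
    return Autoencoder(encoder=encoder, decoder=decoder, mean=mean, scale=scale, history=history)
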