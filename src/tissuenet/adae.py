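"""Adversarial deconfounding autoencoder.

A plain autoencoder maps each sample's gene vector to a low-dimensional
embedding and back (mean squared reconstruction error, Adam, ReLU hidden
layers, linear output).  The adversarial variant alternates two phases per
round: (a) with the adversary frozen, the autoencoder takes one pass over
shuffled minibatches minimizing

    ||x - g(f(x))||^2  -  lambda * CE(h(f(x)), confounder)

and (b) with the autoencoder frozen, the adversary trains one full epoch of
categorical cross-entropy to predict the confounder class from the
embedding.  At convergence the adversary sits near chance while
reconstruction stays good, i.e. the embedding carries little confounder
information.

Inputs are standardized per gene before training and the standardization is
inverted on reconstruction.  With ``lambda_adv = 0`` the adversarial
objective reduces exactly to the plain reconstruction objective, so
``train_adae`` delegates to ``train_autoencoder`` in that case.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from ._nn import MLP, Adam, cross_entropy, softmax
from .preprocess import ExpressionBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdaeSpec:
    """Architecture and training hyperparameters.

    ``hidden_dim`` defaults to half the gene number; the adversary is a
    two-hidden-layer (100, 100) ReLU network with a softmax head over the
    confounder classes.
    """

    embedding_dim: int = 100
    hidden_dim: int | None = None
    adversary_hidden: tuple[int, int] = (100, 100)
    lambda_adv: float = 1.0
    embedding_activation: str = "relu"
    learning_rate: float = 1e-4
    minibatch_size: int = 128
    max_epochs: int = 200
    patience: int = 10
    warmup_rounds: int = 5
    restarts: int = 1
    seed: int = 0

    def validate(self, n_genes: int) -> None:
        if self.embedding_dim >= n_genes:
            raise ValueError(
                f"embedding_dim {self.embedding_dim} must be < gene number {n_genes}")
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be >= 0")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")

    def resolved_hidden(self, n_genes: int) -> int:
        return self.hidden_dim if self.hidden_dim is not None else int(np.ceil(n_genes / 2))


@dataclass
class AdaeModel:
    """Trained encoder/decoder (and optionally adversary) with bookkeeping."""

    spec: AdaeSpec
    encoder: MLP
    decoder: MLP
    adversary: MLP | None
    gene_ids: list[str]
    gene_mean: np.ndarray
    gene_scale: np.ndarray
    classes: list[str] | None
    history: dict = field(default_factory=dict)

    def _check_genes(self, bundle: ExpressionBundle) -> None:
        if bundle.gene_ids != self.gene_ids:
            raise ValueError(
                "bundle gene IDs/order do not match the model's training genes "
                "(no silent reordering)")

    def _standardized(self, bundle: ExpressionBundle) -> np.ndarray:
        X = bundle.matrix.to_numpy(dtype=float).T  # samples x genes
        return (X - self.gene_mean) / self.gene_scale

    def encode(self, bundle: ExpressionBundle) -> pd.DataFrame:
        """Deterministic forward pass -> samples x D embedding table."""
        self._check_genes(bundle)
        Z = self.encoder.forward(self._standardized(bundle), cache=False)
        cols = [f"dim_{i + 1}" for i in range(Z.shape[1])]
        return pd.DataFrame(Z, index=bundle.sample_ids, columns=cols)

    def reconstruct(self, bundle: ExpressionBundle) -> ExpressionBundle:
        """Decode the embedding back to the expression scale."""
        self._check_genes(bundle)
        Z = self.encoder.forward(self._standardized(bundle), cache=False)
        Xh = self.decoder.forward(Z, cache=False) * self.gene_scale + self.gene_mean
        unit = bundle.unit if bundle.is_reconstructed else f"reconstructed:{bundle.base_unit}"
        return ExpressionBundle(
            matrix=pd.DataFrame(Xh.T, index=bundle.matrix.index, columns=bundle.matrix.columns),
            sample_meta=bundle.sample_meta.copy(),
            unit=unit,
        )

    def adversary_proba(self, bundle: ExpressionBundle) -> pd.DataFrame:
        if self.adversary is None:
            raise ValueError("model has no adversary (trained with lambda_adv = 0)")
        Z = self.encoder.forward(self._standardized(bundle), cache=False)
        P = softmax(self.adversary.forward(Z, cache=False))
        return pd.DataFrame(P, index=bundle.sample_ids, columns=self.classes)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "AdaeModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _prepare(bundle: ExpressionBundle, spec: AdaeSpec):
    X = bundle.matrix.to_numpy(dtype=float).T  # samples x genes
    if not np.all(np.isfinite(X)):
        raise ValueError("expression matrix contains non-finite values")
    spec.validate(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def _labels_to_onehot(bundle: ExpressionBundle, labels: dict[str, str]):
    missing = [s for s in bundle.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"confounder label missing for sample(s): {missing[:5]}")
    classes = sorted(set(labels[s] for s in bundle.sample_ids))
    index = {c: i for i, c in enumerate(classes)}
    y = np.array([index[labels[s]] for s in bundle.sample_ids])
    onehot = np.eye(len(classes))[y]
    return y, onehot, classes


def _spawn_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def train_autoencoder(bundle: ExpressionBundle, spec: AdaeSpec) -> AdaeModel:
    """Plain autoencoder (the lambda = 0 special case).

    80/20 train/validation split; the returned weights are from the epoch
    minimizing validation reconstruction loss.
    """
    return _train(bundle, labels=None, spec=replace(spec, lambda_adv=0.0))


def train_adae(bundle: ExpressionBundle, labels: dict[str, str], spec: AdaeSpec) -> AdaeModel:
    """Adversarial training against the confounder labels."""
    if spec.lambda_adv == 0:
        return _train(bundle, labels=labels, spec=spec)
    classes = set(labels.get(s) for s in bundle.sample_ids)
    if len(classes) < 2:
        warnings.warn("single confounder class: adversarial term is vacuous, "
                      "training a plain autoencoder", stacklevel=2)
        return _train(bundle, labels=labels, spec=spec)
    return _train(bundle, labels=labels, spec=spec)


def _train(bundle: ExpressionBundle, labels: dict[str, str] | None, spec: AdaeSpec) -> AdaeModel:
    if spec.restarts > 1:
        # narrow rectified bottlenecks occasionally die at init; keep the
        # restart with the best validation reconstruction
        fits = [
            _train(bundle, labels, replace(
                spec, restarts=1,
                seed=int(np.random.SeedSequence([spec.seed, r]).generate_state(1)[0] % (2 ** 31))))
            for r in range(spec.restarts)
        ]
        return min(fits, key=lambda m: m.history["best_val_mse"])
    Xs, mean, scale = _prepare(bundle, spec)
    n, m = Xs.shape
    hidden = spec.resolved_hidden(m)

    # fixed stream layout so the lambda=0 trajectory is independent of
    # whether an adversary is present
    rng_split, rng_enc, rng_dec, rng_adv, rng_ae_shuf, rng_adv_shuf = _spawn_rngs(spec.seed, 6)

    encoder = MLP([m, hidden, spec.embedding_dim],
                  ["relu", spec.embedding_activation], rng_enc)
    decoder = MLP([spec.embedding_dim, hidden, m], ["relu", "linear"], rng_dec)

    adversary = None
    classes = None
    onehot = None
    if labels is not None:
        y, onehot, classes = _labels_to_onehot(bundle, labels)
        h1, h2 = spec.adversary_hidden
        adversary = MLP([spec.embedding_dim, h1, h2, len(classes)],
                        ["relu", "relu", "linear"], rng_adv)

    n_val = int(round(n * 0.2))
    order = rng_split.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xtr, Xval = Xs[train_idx], Xs[val_idx]
    if onehot is not None:
        Ytr, Yval = onehot[train_idx], onehot[val_idx]

    opt_ae = Adam(encoder.params + decoder.params, lr=spec.learning_rate)
    opt_adv = (Adam(adversary.params, lr=spec.learning_rate * 10)
               if adversary is not None else None)

    history: dict[str, list[float]] = {
        "train_mse": [], "val_mse": [], "adversary_ce": [], "adversary_val_acc": [],
    }
    best_val = np.inf
    best_state = None
    stale = 0
    adversarial = spec.lambda_adv > 0 and adversary is not None

    def eval_mse(X: np.ndarray) -> float:
        return float(np.mean(
            (decoder.forward(encoder.forward(X, cache=False), cache=False) - X) ** 2))

    for rnd in range(spec.max_epochs):
        lam = spec.lambda_adv if (adversarial and rnd >= spec.warmup_rounds) else 0.0

        # (a) adversary frozen, autoencoder pass over shuffled minibatches
        perm = rng_ae_shuf.permutation(len(Xtr))
        for start in range(0, len(Xtr), spec.minibatch_size):
            idx = perm[start:start + spec.minibatch_size]
            xb = Xtr[idx]
            Z = encoder.forward(xb)
            Xh = decoder.forward(Z)
            dXh = 2.0 * (Xh - xb) / xb.size
            dZ = decoder.backward(dXh)
            if lam > 0:
                logits = adversary.forward(Z)
                P = softmax(logits)
                dlogits = (P - Ytr[idx]) / len(idx)
                dZ_adv = adversary.backward(dlogits, accumulate=False)
                dZ = dZ - lam * dZ_adv
            encoder.backward(dZ)
            opt_ae.step(encoder.grads + decoder.grads)

        # (b) autoencoder frozen, adversary trained for a full epoch
        if adversary is not None:
            perm = rng_adv_shuf.permutation(len(Xtr))
            for start in range(0, len(Xtr), spec.minibatch_size):
                idx = perm[start:start + spec.minibatch_size]
                Z = encoder.forward(Xtr[idx], cache=False)
                logits = adversary.forward(Z)
                P = softmax(logits)
                dlogits = (P - Ytr[idx]) / len(idx)
                adversary.backward(dlogits)
                opt_adv.step(adversary.grads)

        train_mse = eval_mse(Xtr)
        monitor = Xval if len(Xval) else Xtr
        val_mse = eval_mse(monitor)
        history["train_mse"].append(train_mse)
        history["val_mse"].append(val_mse)
        if adversary is not None:
            Zmon = encoder.forward(monitor, cache=False)
            Pmon = softmax(adversary.forward(Zmon, cache=False))
            Ymon = Yval if len(Xval) else Ytr
            history["adversary_ce"].append(cross_entropy(Pmon, Ymon))
            history["adversary_val_acc"].append(
                float((Pmon.argmax(axis=1) == Ymon.argmax(axis=1)).mean()))

        # early stopping on validation reconstruction; during adversarial
        # training only rounds past warmup compete for the snapshot so the
        # still-confounded warmup model cannot win
        eligible = rnd >= spec.warmup_rounds if adversarial else True
        if eligible:
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_state = (encoder.get_state(), decoder.get_state(),
                              adversary.get_state() if adversary is not None else None)
                stale = 0
            else:
                stale += 1
                if stale >= spec.patience:
                    break

    if best_state is not None:
        encoder.set_state(best_state[0])
        decoder.set_state(best_state[1])
        if adversary is not None and best_state[2] is not None:
            adversary.set_state(best_state[2])
    history["best_val_mse"] = best_val
    history["final_mse"] = eval_mse(Xs)

    return AdaeModel(
        spec=spec, encoder=encoder, decoder=decoder, adversary=adversary,
        gene_ids=bundle.gene_ids, gene_mean=mean, gene_scale=scale,
        classes=classes, history=history,
    )


def encode(model: AdaeModel, bundle: ExpressionBundle) -> pd.DataFrame:
    return model.encode(bundle)


def reconstruct(model: AdaeModel, bundle: ExpressionBundle) -> ExpressionBundle:
    return model.reconstruct(bundle)


# ---------------------------------------------------------------------------
# probes and hyperparameter selection
# ---------------------------------------------------------------------------

def probe_accuracy(embedding: pd.DataFrame, labels: dict[str, str],
                   seed: int = 0, test_fraction: float = 0.2) -> float:
    """Held-out accuracy of a fresh logistic probe predicting ``labels``
    from the embedding — the operational test of what information the
    embedding still carries."""
    y = np.array([labels[s] for s in embedding.index])
    X = embedding.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_test = max(int(round(len(y) * test_fraction)), 1)
    test, train = order[:n_test], order[n_test:]
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X[train], y[train])
    return float((clf.predict(X[test]) == y[test]).mean())


def chance_level(labels: dict[str, str]) -> float:
    values = list(labels.values())
    return 1.0 / len(set(values))


def select_hyperparameters(
    bundle: ExpressionBundle,
    labels: dict[str, str] | None,
    grid: list[AdaeSpec],
    *,
    accuracy_margin: float = 0.10,
    mse_rtol: float = 0.05,
    mse_atol: float = 0.02,
    seed: int = 0,
) -> AdaeSpec:
    """Fivefold CV over samples; pick the grid point minimizing mean held-out
    reconstruction MSE subject to the probe staying within ``accuracy_margin``
    of chance.  Near-ties go to the smaller embedding dimension: a wide
    autoencoder can approximate the identity map and reconstruct held-out
    noise, so MSE differences within ``mse_rtol`` relative or ``mse_atol``
    absolute (standardized units) are treated as immaterial and parsimony
    wins."""
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if bundle.n_samples < 5:
        raise ValueError("need at least 5 samples for fivefold cross validation")
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    sample_ids = bundle.sample_ids
    chance = chance_level(labels) if labels else None

    results = []
    for spec in grid:
        fold_mse, fold_acc = [], []
        for fold, (train_idx, test_idx) in enumerate(kf.split(sample_ids)):
            train_b = bundle.subset_samples([sample_ids[i] for i in train_idx])
            test_b = bundle.subset_samples([sample_ids[i] for i in test_idx])
            fold_spec = replace(spec, seed=spec.seed + fold)
            if labels is not None and spec.lambda_adv > 0:
                model = train_adae(train_b, labels, fold_spec)
            else:
                model = train_autoencoder(train_b, fold_spec)
            Xh = model.reconstruct(test_b).matrix.to_numpy()
            X = test_b.matrix.to_numpy()
            scale = model.gene_scale[:, None]
            fold_mse.append(float(np.mean(((Xh - X) / scale) ** 2)))
            if labels is not None:
                Z = model.encode(test_b)
                fold_acc.append(probe_accuracy(Z, labels, seed=seed, test_fraction=0.5))
        results.append({
            "spec": spec,
            "mean_mse": float(np.mean(fold_mse)),
            "mean_probe_acc": float(np.mean(fold_acc)) if fold_acc else None,
        })

    def admissible(r) -> bool:
        if chance is None or r["mean_probe_acc"] is None:
            return True
        return r["mean_probe_acc"] <= chance + accuracy_margin

    pool = [r for r in results if admissible(r)]
    if not pool:
        logger.warning("no grid point met the adversary-accuracy constraint; "
                       "falling back to unconstrained reconstruction loss")
        pool = results
    best = min(r["mean_mse"] for r in pool)
    cutoff = best + max(best * mse_rtol, mse_atol)
    near = [r for r in pool if r["mean_mse"] <= cutoff]
    near.sort(key=lambda r: (r["spec"].embedding_dim, r["mean_mse"]))
    return near[0]["spec"]
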