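import dataclasses

import numpy as np
import pandas as pd
import pytest

from tissuenet._nn import MLP, fit_autoencoder, softmax
from tissuenet.adae import (
    AdaeSpec,
    chance_level,
    probe_accuracy,
    select_hyperparameters,
    train_adae,
    train_autoencoder,
)
from tissuenet.preprocess import log2_transform
from tissuenet.simulate import SimConfig, simulate_bundle

from conftest import make_bundle

FAST = dict(learning_rate=1e-3, minibatch_size=64, max_epochs=40, patience=10)


def _confounded_bundle(seed=11, n_sources=4, confounder_effect=1.0):
    cfg = SimConfig(n_genes=200, n_tissues=4, samples_per_group=60, n_sources=n_sources,
                    confounder_effect=confounder_effect, platform="intensity_like",
                    noise_dispersion=0.3, n_specific_per_tissue=25, specific_effect=8.0,
                    seed=seed)
    bundle, truth, _ = simulate_bundle(cfg)
    return log2_transform(bundle), truth


class TestPlainAutoencoder:
    def test_linear_subspace_recoverable(self):
        # PCA-bound oracle: data on a 3-dim linear subspace must reconstruct
        # to well under 1% of its variance with a 3-dim embedding
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 3)) @ rng.normal(size=(3, 40))
        ae = fit_autoencoder(X, embedding_dim=3, learning_rate=3e-3,
                             max_epochs=2000, patience=100, seed=1)
        mse = np.mean((ae.reconstruct(X) - X) ** 2)
        assert mse / X.var() < 0.01

    def test_constant_dataset(self):
        b = make_bundle(np.full((30, 20), 5.0), unit="intensity")
        model = train_autoencoder(b, AdaeSpec(embedding_dim=2, **FAST, seed=0))
        recon = model.reconstruct(b).matrix.to_numpy()
        np.testing.assert_allclose(recon, 5.0, atol=1e-6)
        z = model.encode(b).to_numpy()
        assert np.allclose(z, z[0], atol=1e-9)

    def test_same_seed_identical_history(self, small_log2):
        bundle, _ = small_log2
        spec = AdaeSpec(embedding_dim=4, **FAST, seed=5)
        h1 = train_autoencoder(bundle, spec).history
        h2 = train_autoencoder(bundle, spec).history
        assert h1["val_mse"] == h2["val_mse"]
        assert h1["train_mse"] == h2["train_mse"]

    def test_embedding_dim_must_be_below_gene_count(self, small_log2):
        bundle, _ = small_log2
        with pytest.raises(ValueError, match="embedding_dim"):
            train_autoencoder(bundle, AdaeSpec(embedding_dim=10**4, **FAST))

    def test_nonfinite_input_rejected(self):
        b = make_bundle(np.ones((10, 8)), unit="intensity")
        b.matrix.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_autoencoder(b, AdaeSpec(embedding_dim=2, **FAST))


@pytest.fixture(scope="module")
def trained(small_log2):
    bundle, _ = small_log2
    model = train_autoencoder(bundle, AdaeSpec(embedding_dim=4, **FAST, seed=3))
    return model, bundle


class TestEncodeReconstruct:

    def test_reconstruct_bookkeeping(self, trained):
        model, bundle = trained
        recon = model.reconstruct(bundle)
        assert recon.is_reconstructed
        assert recon.gene_ids == bundle.gene_ids
        assert recon.sample_ids == bundle.sample_ids
        X = bundle.matrix.to_numpy().T
        mse = np.mean((((recon.matrix.to_numpy().T - X) / model.gene_scale)) ** 2)
        assert mse == pytest.approx(model.history["final_mse"], rel=1e-9)

    def test_sample_permutation_permutes_embedding(self, trained):
        model, bundle = trained
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(bundle.sample_ids))
        z = model.encode(bundle)
        z_perm = model.encode(bundle.subset_samples(perm))
        pd.testing.assert_frame_equal(z.loc[perm], z_perm)

    def test_zero_sample_is_finite(self, trained):
        model, bundle = trained
        zeroed = bundle.matrix.copy()
        zeroed.iloc[:, 0] = 0.0
        b0 = dataclasses.replace(bundle, matrix=zeroed)
        assert np.isfinite(model.encode(b0).to_numpy()).all()
        assert np.isfinite(model.reconstruct(b0).matrix.to_numpy()).all()

    def test_gene_order_mismatch_is_error(self, trained):
        model, bundle = trained
        shuffled = bundle.matrix.iloc[::-1]
        b = dataclasses.replace(bundle, matrix=shuffled)
        with pytest.raises(ValueError, match="gene IDs"):
            model.encode(b)


class TestAdversarialTraining:
    def test_lambda_zero_equals_plain_autoencoder(self, small_log2):
        bundle, truth = small_log2
        spec = AdaeSpec(embedding_dim=4, lambda_adv=0.0, **FAST, seed=9)
        m_plain = train_autoencoder(bundle, spec)
        m_adv = train_adae(bundle, truth.source_of_sample, spec)
        assert m_plain.history["train_mse"] == m_adv.history["train_mse"]
        z1 = m_plain.encode(bundle).to_numpy()
        z2 = m_adv.encode(bundle).to_numpy()
        np.testing.assert_array_equal(z1, z2)

    def test_combined_gradient_reduces_at_lambda_zero(self):
        # direct gradient check: with lambda=0 the encoder gradient of the
        # joint objective is exactly the reconstruction gradient
        rng = np.random.default_rng(4)
        enc = MLP([6, 4, 2], ["relu", "relu"], np.random.default_rng(1))
        dec = MLP([2, 4, 6], ["relu", "linear"], np.random.default_rng(2))
        adv = MLP([2, 5, 3], ["relu", "linear"], np.random.default_rng(3))
        xb = rng.normal(size=(8, 6))
        onehot = np.eye(3)[rng.integers(0, 3, size=8)]

        def encoder_grads(lam):
            Z = enc.forward(xb)
            Xh = dec.forward(Z)
            dXh = 2.0 * (Xh - xb) / xb.size
            dZ = dec.backward(dXh)
            if lam > 0:
                P = softmax(adv.forward(Z))
                dZ = dZ - lam * adv.backward((P - onehot) / len(xb), accumulate=False)
            enc.backward(dZ)
            return [g.copy() for g in enc.grads]

        g0 = encoder_grads(0.0)
        g_pure = encoder_grads(0.0)
        for a, b in zip(g0, g_pure):
            np.testing.assert_array_equal(a, b)
        g1 = encoder_grads(1.0)
        assert any(not np.allclose(a, b) for a, b in zip(g0, g1))

    def test_single_confounder_class_warns(self, small_log2):
        bundle, _ = small_log2
        labels = {s: "only" for s in bundle.sample_ids}
        with pytest.warns(UserWarning, match="single confounder"):
            train_adae(bundle, labels, AdaeSpec(embedding_dim=4, lambda_adv=1.0,
                                                **FAST, seed=0))

    def test_adversary_outputs_probability_simplex(self, small_log2):
        bundle, truth = small_log2
        spec = AdaeSpec(embedding_dim=4, lambda_adv=1.0, warmup_rounds=2,
                        learning_rate=1e-3, minibatch_size=64, max_epochs=10,
                        patience=5, seed=2)
        model = train_adae(bundle, truth.source_of_sample, spec)
        proba = model.adversary_proba(bundle).to_numpy()
        assert (proba >= 0).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_deconfounding_removes_source_keeps_tissue(self):
        # the central contract: lambda=1 drives a fresh source probe to
        # chance while tissue stays decodable; lambda=0 leaves source exposed
        bundle, truth = _confounded_bundle()
        tissue = bundle.sample_meta["tissue"].to_dict()
        spec = AdaeSpec(embedding_dim=10, lambda_adv=1.0, learning_rate=1e-3,
                        minibatch_size=64, max_epochs=300, patience=40,
                        warmup_rounds=5, seed=3)
        m1 = train_adae(bundle, truth.source_of_sample, spec)
        m0 = train_autoencoder(bundle, dataclasses.replace(spec, lambda_adv=0.0))
        z1, z0 = m1.encode(bundle), m0.encode(bundle)
        chance = chance_level(truth.source_of_sample)
        assert probe_accuracy(z1, truth.source_of_sample, seed=0) <= chance + 0.10
        assert probe_accuracy(z1, tissue, seed=0) >= 0.8
        assert probe_accuracy(z0, truth.source_of_sample, seed=0) >= 0.60

    def test_adversary_accuracy_decreases_with_lambda(self):
        # monotone on average over seeds across lambda in {0, 0.1, 1}
        accs = {0.0: [], 0.1: [], 1.0: []}
        for seed in range(5):
            bundle, truth = _confounded_bundle(seed=20 + seed)
            for lam in accs:
                spec = AdaeSpec(embedding_dim=10, lambda_adv=lam, learning_rate=1e-3,
                                minibatch_size=64, max_epochs=80, patience=20,
                                warmup_rounds=5, seed=seed)
                if lam == 0:
                    model = train_autoencoder(bundle, spec)
                else:
                    model = train_adae(bundle, truth.source_of_sample, spec)
                accs[lam].append(probe_accuracy(model.encode(bundle),
                                                truth.source_of_sample, seed=0))
        means = {lam: np.mean(a) for lam, a in accs.items()}
        assert means[1.0] < means[0.1] < means[0.0]


class TestHyperparameterSelection:
    def test_single_point_grid_returned(self, small_log2):
        bundle, truth = small_log2
        spec = AdaeSpec(embedding_dim=3, **FAST, seed=1)
        chosen = select_hyperparameters(bundle, None, [spec], seed=0)
        assert chosen == spec

    def test_selection_deterministic(self, small_log2):
        bundle, _ = small_log2
        grid = [AdaeSpec(embedding_dim=d, **FAST, seed=1) for d in (2, 4)]
        c1 = select_hyperparameters(bundle, None, grid, seed=0)
        c2 = select_hyperparameters(bundle, None, grid, seed=0)
        assert c1 == c2

    def test_low_dim_structure_prefers_small_embedding(self):
        # two positive latent factors with disjoint feature blocks: D=2
        # reconstructs to the noise floor, D=50 cannot do materially better,
        # and the smaller-D near-tie rule must pick 2.  The grid uses a
        # softplus bottleneck: what is under test is the CV selection logic,
        # and a 2-unit hard-zero ReLU bottleneck stalls on a plateau for
        # roughly half of all seeds, which would only measure trainability.
        rng = np.random.default_rng(6)
        scores = np.abs(rng.normal(size=(150, 2))) + 0.5
        loadings = np.zeros((2, 60))
        loadings[0, :30] = np.abs(rng.normal(size=30)) + 0.5
        loadings[1, 30:] = np.abs(rng.normal(size=30)) + 0.5
        X = scores @ loadings + rng.normal(scale=0.05, size=(150, 60))
        b = make_bundle(np.clip(X.T, 0, None), unit="intensity")
        grid = [AdaeSpec(embedding_dim=2, embedding_activation="softplus",
                         learning_rate=3e-3, minibatch_size=32,
                         max_epochs=600, patience=60, restarts=2, seed=1),
                AdaeSpec(embedding_dim=50, embedding_activation="softplus",
                         learning_rate=3e-3, minibatch_size=32,
                         max_epochs=600, patience=60, restarts=2, seed=1)]
        chosen = select_hyperparameters(b, None, grid, seed=0)
        assert chosen.embedding_dim == 2

    def test_too_few_samples_rejected(self):
        b = make_bundle(np.ones((10, 4)), unit="intensity")
        with pytest.raises(ValueError, match="5 samples"):
            select_hyperparameters(b, None, [AdaeSpec(embedding_dim=2, **FAST)])
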