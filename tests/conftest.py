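import numpy as np
import pandas as pd
import pytest

from tissuenet.preprocess import ExpressionBundle
from tissuenet.simulate import SimConfig, simulate_bundle
from tissuenet.preprocess import log2_transform


def make_bundle(values, gene_ids=None, sample_ids=None, unit="counts",
                tissues=None, sources=None, groups=None):
    """Hand-rolled bundle for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "tissue": tissues or ["leaf"] * n_samples,
            "source": sources or ["src0"] * n_samples,
            "platform": ["rnaseq"] * n_samples,
            "group": groups or ["case"] * n_samples,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionBundle(
        matrix=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        sample_meta=meta,
        unit=unit,
    )


@pytest.fixture(scope="session")
def small_sim():
    """One small deterministic simulation shared across read-only tests."""
    config = SimConfig(n_genes=200, n_tissues=4, samples_per_group=30, n_sources=2,
                       n_specific_per_tissue=10, specific_effect=8.0,
                       confounder_effect=0.3, n_tfs=5, targets_per_tf=3,
                       n_diff_pairs=5, platform="count_like", seed=42)
    bundle, truth, lengths = simulate_bundle(config)
    return config, bundle, truth, lengths


@pytest.fixture(scope="session")
def small_log2(small_sim):
    _, bundle, truth, _ = small_sim
    return log2_transform(bundle), truth
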