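"""Tissue-specific regulatory network inference on compressed expression.

Each tissue's genes x samples matrix is first compressed along the sample
axis with the same autoencoder machinery used for specificity scoring, but
with a 64-dimensional embedding (32 when the tissue has 64 or fewer
samples), giving genes x latent-pseudo-sample matrices.  Edges are then
scored GENIE3-style: for every target gene, a random-forest regression of
its latent profile on the candidate regulators' profiles, with the edge
weight being the regulator's total impurity-reduction importance (target
standardized to unit variance; per-tree importances left unnormalized, as
in the reference implementation).  Hub TFs are ranked by degree in the
retained top-k network.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .specificity import CompressionSpec, compress_tissue

logger = logging.getLogger(__name__)

#: dimension rule: 64 latent columns when samples allow, else fall back to 32
DIM_LARGE = 64
DIM_SMALL = 32


@dataclass
class RegulatorList:
    """Candidate transcription-factor gene IDs."""

    tf_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise ValueError("regulator list contains duplicate IDs")

    @classmethod
    def from_file(cls, path: str | Path, provenance: str = "") -> "RegulatorList":
        ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
        return cls(tf_ids=ids, provenance=provenance or str(path))

    def intersect(self, gene_ids: Iterable[str]) -> "RegulatorList":
        genes = set(gene_ids)
        return RegulatorList(tf_ids=[t for t in self.tf_ids if t in genes],
                            provenance=self.provenance)


@dataclass
class WeightedEdgeList:
    """Ranked regulator -> target edges with non-negative weights."""

    edges: pd.DataFrame  # columns: regulator, target, weight
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["regulator", "target", "weight"]
        if list(self.edges.columns[:3]) != required:
            raise ValueError(f"edge frame must have columns {required}")
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")
        w = self.edges["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ValueError("edge weights must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.edges)

    def scores(self) -> dict[tuple[str, str], float]:
        return {(r, t): w for r, t, w in
                self.edges[["regulator", "target", "weight"]].itertuples(index=False)}

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def auto_embedding_dim(n_samples: int) -> int:
    if n_samples > DIM_LARGE:
        return DIM_LARGE
    if n_samples > DIM_SMALL:
        return DIM_SMALL
    # tiny cohorts (toy simulations): half the samples, at least 2
    return max(2, n_samples // 2)


def compress_samples(
    matrix: pd.DataFrame,
    embedding_dim: int | None = None,
    spec: CompressionSpec | None = None,
) -> pd.DataFrame:
    """Compress the sample axis to ``embedding_dim`` latent pseudo-samples.

    Default dimension follows the sample-count rule (64 above 64 samples,
    else 32).  Raises when the requested dimension is not below the sample
    count, suggesting the 32 fallback.
    """
    n_samples = matrix.shape[1]
    if embedding_dim is None:
        embedding_dim = auto_embedding_dim(n_samples)
    if embedding_dim >= n_samples:
        raise ValueError(
            f"embedding_dim {embedding_dim} must be < sample count {n_samples}; "
            f"consider the {DIM_SMALL}-dimension fallback")
    base = spec or CompressionSpec()
    return compress_tissue(matrix, spec=CompressionSpec(
        **{**base.__dict__, "embedding_dim": embedding_dim}))


def infer_grn(
    compressed: pd.DataFrame,
    regulators: RegulatorList,
    n_trees: int = 1000,
    seed: int = 0,
    normalize_per_target: bool = False,
) -> WeightedEdgeList:
    """GENIE3-style edge scoring on a genes x latent-columns matrix.

    For each target gene, a random forest regresses its profile on all
    candidate regulators other than itself (sqrt feature subsetting,
    ``n_trees`` trees, per-target seed derived from the master seed).  Edge
    weight is the regulator's mean total impurity reduction across trees;
    with ``normalize_per_target`` each target's importances are rescaled to
    sum to one.
    """
    regs = regulators.intersect(compressed.index)
    if len(regs.tf_ids) < 2:
        raise ValueError("need at least 2 regulators present in the matrix")
    X_all = compressed.loc[regs.tf_ids].to_numpy(dtype=float)  # regulators x latent
    reg_index = {t: i for i, t in enumerate(regs.tf_ids)}

    records: list[tuple[str, str, float]] = []
    for target in compressed.index:
        y = compressed.loc[target].to_numpy(dtype=float)
        sd = y.std()
        if sd == 0:
            logger.warning("target %s skipped: zero variance in latent profile", target)
            continue
        y = y / sd  # unit-variance target so importances are comparable
        if target in reg_index:
            keep = [i for i in range(len(regs.tf_ids)) if i != reg_index[target]]
        else:
            keep = list(range(len(regs.tf_ids)))
        if not keep:
            continue
        X = X_all[keep].T  # latent-samples x regulators
        # seed keyed by target ID, not position: permuting the gene order of
        # the input permutes edge endpoints and nothing else
        target_key = zlib.crc32(str(target).encode())
        rf_seed = int(np.random.SeedSequence([seed, target_key]).generate_state(1)[0]) % (2 ** 31)
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=rf_seed,
            n_jobs=1,
        )
        rf.fit(X, y)
        importances = np.mean(
            [tree.tree_.compute_feature_importances(normalize=False)
             for tree in rf.estimators_], axis=0)
        if normalize_per_target and importances.sum() > 0:
            importances = importances / importances.sum()
        for i, imp in zip(keep, importances):
            records.append((regs.tf_ids[i], target, float(imp)))

    edges = pd.DataFrame(records, columns=["regulator", "target", "weight"])
    edges = edges.sort_values(
        by=["weight", "regulator", "target"], ascending=[False, True, True],
        kind="stable").reset_index(drop=True)
    return WeightedEdgeList(edges=edges, metadata={
        "n_trees": n_trees, "seed": seed, "n_regulators": len(regs.tf_ids),
        "embedding_dim": compressed.shape[1],
        "normalized_per_target": normalize_per_target,
    })


def top_edges(network: WeightedEdgeList, k: int = 1000) -> WeightedEdgeList:
    """Keep the k highest-weight edges; boundary ties resolved by
    (regulator, target) lexicographic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = network.edges.sort_values(
        by=["weight", "regulator", "target"], ascending=[False, True, True],
        kind="stable").head(k).reset_index(drop=True)
    return WeightedEdgeList(edges=edges, metadata={**network.metadata, "top_k": k})


def rank_hub_tfs(network: WeightedEdgeList, degree_view: str = "out") -> pd.DataFrame:
    """Rank regulators by degree in the retained network.

    ``degree_view='out'`` (default) counts a regulator's outgoing edges;
    ``'undirected'`` counts all incident edges for every node.
    """
    if len(network) == 0:
        return pd.DataFrame(columns=["gene_id", "degree"])
    if degree_view == "out":
        counts = network.edges["regulator"].value_counts()
    elif degree_view == "undirected":
        counts = pd.concat([network.edges["regulator"],
                            network.edges["target"]]).value_counts()
    else:
        raise ValueError(f"unknown degree_view {degree_view!r}")
    table = counts.rename("degree").reset_index().rename(columns={"index": "gene_id"})
    table.columns = ["gene_id", "degree"]
    return table.sort_values(by=["degree", "gene_id"], ascending=[False, True],
                             kind="stable").reset_index(drop=True)
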