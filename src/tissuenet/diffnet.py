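"""Tissue-vs-control differential co-expression networks.

For every unordered gene pair, Pearson correlations are computed in the
tissue and control matrices, Fisher z-transformed (z = arctanh(rho)), and
compared with

    dz = (z1 - z2) / sqrt(1/(n1 - 3) + 1/(n2 - 3))

with a two-sided normal p-value, Benjamini-Hochberg adjustment over all
pairs, and an optional pooled permutation null (group labels reshuffled,
add-one empirical p).  The top adjusted-p pairs form an undirected network
(edge sign = gained/lost correlation in the tissue); hub genes are ranked
by their average correlation change, and modules come from greedy
modularity maximization.

Note the denominator: the sum of the two z-variances, the standard Fisher
convention (a printed absolute-difference form would vanish for equal group
sizes and leave the statistic undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

_RHO_CLAMP = 1.0 - 1e-6


def fisher_z(rho):
    """arctanh of a correlation; |rho| >= 1 is clamped with a warning."""
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        logger.warning("correlation(s) with |rho| >= 1 clamped to +/-%g", _RHO_CLAMP)
        rho = np.clip(rho, -_RHO_CLAMP, _RHO_CLAMP)
    out = np.arctanh(rho)
    return float(out) if out.ndim == 0 else out


def diff_z(z1, n1: int, z2, n2: int):
    """Difference of Fisher z-scores and its two-sided normal p-value."""
    if n1 <= 3:
        raise ValueError(f"group 1 needs n > 3 samples, got {n1}")
    if n2 <= 3:
        raise ValueError(f"group 2 needs n > 3 samples, got {n2}")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    dz = (np.asarray(z1, dtype=float) - np.asarray(z2, dtype=float)) / se
    p = 2.0 * norm.sf(np.abs(dz))
    if np.ndim(dz) == 0:
        return float(dz), float(p)
    return dz, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _pair_correlations(matrix: pd.DataFrame) -> np.ndarray:
    """Upper-triangle Pearson correlations of the rows of a genes x samples
    matrix; zero-variance genes are an error (filter upstream)."""
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        bad = list(matrix.index[sd == 0][:5])
        raise ValueError(f"zero-variance gene(s) reached correlation stage: {bad}")
    corr = np.corrcoef(values)
    iu = np.triu_indices(len(values), k=1)
    return corr[iu]


def pairwise_diffcorr(tissue: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """DiffCorrTable over all unordered gene pairs of a shared gene universe.

    Columns: gene_a, gene_b, rho_tissue, rho_control, z1, z2, dz, p, p_adj;
    n1/n2 (the matrices' column counts) are stored in ``attrs``.
    """
    if not tissue.index.equals(control.index):
        raise ValueError("tissue and control matrices must share the same gene universe")
    n1, n2 = tissue.shape[1], control.shape[1]
    if n1 < 5 or n2 < 5:
        raise ValueError("each matrix needs at least 5 columns")
    genes = tissue.index.to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    rho1 = _pair_correlations(tissue)
    rho2 = _pair_correlations(control)
    z1 = fisher_z(rho1)
    z2 = fisher_z(rho2)
    dz, p = diff_z(z1, n1, z2, n2)
    table = pd.DataFrame({
        "gene_a": genes[iu[0]],
        "gene_b": genes[iu[1]],
        "rho_tissue": rho1,
        "rho_control": rho2,
        "z1": z1,
        "z2": z2,
        "dz": dz,
        "p": p,
        "p_adj": bh_adjust(p),
    })
    table.attrs["n1"] = n1
    table.attrs["n2"] = n2
    return table


def permutation_null(
    tissue: pd.DataFrame,
    control: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    pooled: bool = True,
) -> pd.Series:
    """Empirical p-values from a column-permutation null.

    The two matrices' columns are pooled and reassigned to groups of the
    original sizes ``n_perm`` times; |dz| is recomputed for all pairs.  With
    ``pooled=True`` (default) the null distribution pools permuted values
    across pairs and permutations — making 100 permutations informative —
    and p = (1 + #{null >= observed}) / (1 + n_perm * n_pairs).  With
    ``pooled=False`` each pair is compared only to its own permuted values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = pairwise_diffcorr(tissue, control)
    obs_abs = np.abs(observed["dz"].to_numpy())
    n1 = tissue.shape[1]
    combined = pd.concat([tissue, control], axis=1)
    values = combined.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def perm_dz() -> np.ndarray:
        order = rng.permutation(values.shape[1])
        g1, g2 = values[:, order[:n1]], values[:, order[n1:]]
        r1 = np.corrcoef(g1)
        r2 = np.corrcoef(g2)
        iu = np.triu_indices(len(values), k=1)
        z1 = np.arctanh(np.clip(r1[iu], -_RHO_CLAMP, _RHO_CLAMP))
        z2 = np.arctanh(np.clip(r2[iu], -_RHO_CLAMP, _RHO_CLAMP))
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (values.shape[1] - n1 - 3))
        return np.abs(z1 - z2) / se

    if pooled:
        null = np.sort(np.concatenate([perm_dz() for _ in range(n_perm)]))
        n_ge = len(null) - np.searchsorted(null, obs_abs, side="left")
        emp = (1.0 + n_ge) / (1.0 + len(null))
    else:
        counts = np.zeros(len(obs_abs))
        for _ in range(n_perm):
            counts += perm_dz() >= obs_abs
        emp = (1.0 + counts) / (1.0 + n_perm)
    return pd.Series(emp, index=observed.index, name="p_perm")


@dataclass
class DifferentialNetwork:
    """Retained top differential pairs as an undirected signed graph."""

    graph: nx.Graph
    edges: pd.DataFrame
    modules: dict[str, int] = field(default_factory=dict)

    def module_partition(self) -> list[set[str]]:
        if not self.modules:
            return []
        out: dict[int, set[str]] = {}
        for node, mod in self.modules.items():
            out.setdefault(mod, set()).add(node)
        return [out[k] for k in sorted(out)]


def build_network(table: pd.DataFrame, cap: int = 1000) -> DifferentialNetwork:
    """Top ``cap`` pairs by adjusted p (ties: |dz| descending, then IDs);
    edge sign is positive when correlation is gained in the tissue."""
    if len(table) == 0:
        raise ValueError("empty differential-correlation table")
    ranked = table.assign(_absdz=table["dz"].abs()).sort_values(
        by=["p_adj", "_absdz", "gene_a", "gene_b"],
        ascending=[True, False, True, True], kind="stable",
    ).head(cap).drop(columns="_absdz").reset_index(drop=True)
    ranked["sign"] = np.sign(ranked["dz"]).astype(int)
    g = nx.Graph()
    for row in ranked.itertuples(index=False):
        g.add_edge(row.gene_a, row.gene_b, dz=row.dz, sign=int(np.sign(row.dz)),
                   p_adj=row.p_adj)
    return DifferentialNetwork(graph=g, edges=ranked)


def hub_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Average correlation change per gene over all its partners, ranked by
    magnitude; sign reports gain vs loss in the tissue."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for a, b, dz in table[["gene_a", "gene_b", "dz"]].itertuples(index=False):
        sums[a] = sums.get(a, 0.0) + dz
        counts[a] = counts.get(a, 0) + 1
        sums[b] = sums.get(b, 0.0) + dz
        counts[b] = counts.get(b, 0) + 1
    rows = [{"gene_id": g, "score": sums[g] / counts[g],
             "direction": "gain" if sums[g] >= 0 else "loss"} for g in sums]
    df = pd.DataFrame(rows)
    df["abs_score"] = df["score"].abs()
    df = df.sort_values(by=["abs_score", "gene_id"], ascending=[False, True],
                        kind="stable").drop(columns="abs_score").reset_index(drop=True)
    return df


def detect_modules(network: DifferentialNetwork) -> dict[str, int]:
    """Greedy modularity maximization on the unweighted edge set.

    Edgeless graphs degrade to one singleton module per node (warned).
    Module IDs are assigned in order of decreasing module size, ties broken
    by smallest member ID.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        logger.warning("edgeless graph: every node becomes its own module")
        communities = [{n} for n in sorted(g.nodes)]
    else:
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(g, weight=None)]
    communities.sort(key=lambda c: (-len(c), min(c)))
    modules = {node: i for i, c in enumerate(communities) for node in c}
    network.modules = modules
    return modules
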