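"""Tissue-specificity scoring via 1-D autoencoder compression and tau.

Each condition's genes x samples matrix is compressed gene-by-gene to a
single non-negative value (softplus embedding of a one-hidden-layer
autoencoder whose training instances are gene profiles).  Because the
per-condition autoencoders are trained independently, their embeddings are
affinely calibrated onto each condition's mean-expression scale before
being combined.  Tau is then

    tau = sum_i (1 - y_i / max_i y_i) / (n - 1)

over the n conditions (tissues plus the control mixture): 1 means expressed
in a single condition, 0 means uniform.  Genes pass selection when tau
reaches the 3rd quantile (75th percentile, linear interpolation) of all tau
values and their maximal condition is a tissue rather than the control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

from ._nn import fit_autoencoder
from .preprocess import ExpressionBundle, as_condition_matrices

logger = logging.getLogger(__name__)

CONTROL_LABEL = "control"


@dataclass(frozen=True)
class CompressionSpec:
    """Gene-profile autoencoder settings (instances = genes).

    The hidden layer defaults to half the sample number; the embedding uses
    a softplus activation so compressed values are non-negative.
    """

    embedding_dim: int = 1
    hidden_dim: int | None = None
    minibatch_size: int = 12
    learning_rate: float = 1e-4
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0


def compress_tissue(matrix: pd.DataFrame, spec: CompressionSpec = CompressionSpec()) -> pd.DataFrame:
    """Compress each gene's across-sample profile to ``embedding_dim`` values.

    ``matrix`` is genes x samples for one condition; each gene's N-sample
    profile is one training instance.  Returns a genes x embedding_dim frame
    of non-negative embeddings.
    """
    n_samples = matrix.shape[1]
    if n_samples < 2:
        raise ValueError("compression needs at least 2 samples")
    if spec.embedding_dim >= n_samples:
        raise ValueError(
            f"embedding_dim {spec.embedding_dim} must be < sample count {n_samples}")
    hidden = spec.hidden_dim if spec.hidden_dim is not None else int(np.ceil(n_samples / 2))
    ae = fit_autoencoder(
        matrix.to_numpy(dtype=float),
        embedding_dim=spec.embedding_dim,
        hidden_dim=hidden,
        embedding_activation="softplus",
        learning_rate=spec.learning_rate,
        minibatch_size=spec.minibatch_size,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        seed=spec.seed,
    )
    Z = ae.encode(matrix.to_numpy(dtype=float))
    cols = [f"dim_{i + 1}" for i in range(spec.embedding_dim)]
    return pd.DataFrame(Z, index=matrix.index, columns=cols)


def calibrate_across_conditions(
    embeddings: dict[str, pd.Series],
    condition_means: dict[str, pd.Series],
) -> pd.DataFrame:
    """Map each condition's 1-D embedding onto the expression scale.

    Per condition, a least-squares affine fit of mean expression on the
    embedding gives slope/intercept; calibrated values are the fitted means
    with negatives clipped to zero.  This puts independently trained
    embeddings on a common scale (and fixes their arbitrary orientation)
    before tau is computed.
    """
    if set(embeddings) != set(condition_means):
        raise ValueError("embeddings and condition_means must cover the same conditions")
    conditions = list(embeddings)
    genes = embeddings[conditions[0]].index
    out = pd.DataFrame(index=genes, columns=conditions, dtype=float)
    for cond in conditions:
        z = embeddings[cond]
        if not z.index.equals(genes):
            raise ValueError(f"gene universe mismatch in condition {cond!r}")
        m = condition_means[cond].loc[genes]
        if float(np.std(z)) == 0.0:
            raise ValueError(
                f"zero-variance embedding for condition {cond!r}; "
                "consider the mean-expression fallback")
        fit = linregress(z.to_numpy(dtype=float), m.to_numpy(dtype=float))
        out[cond] = np.clip(fit.slope * z.to_numpy(dtype=float) + fit.intercept, 0.0, None)
    return out


def compute_tau(values: np.ndarray) -> float:
    """Tau specificity of one gene's per-condition values (all >= 0)."""
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("tau needs a 1-D vector of at least 2 conditions")
    if (y < 0).any():
        raise ValueError("tau requires non-negative values")
    ymax = y.max()
    if ymax == 0:
        return float("nan")
    yhat = y / ymax
    return float((1.0 - yhat).sum() / (len(y) - 1))


@dataclass
class TauTable:
    """Per-gene compressed values, tau score, and maximal condition."""

    values: pd.DataFrame  # genes x conditions, calibrated, >= 0
    control_label: str = CONTROL_LABEL
    tau: pd.Series = field(init=False)
    argmax: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError("TauTable values must be non-negative")
        taus = np.array([compute_tau(row) if row.max() > 0 else np.nan for row in v])
        self.tau = pd.Series(taus, index=self.values.index, name="tau")
        self.argmax = pd.Series(self.values.columns[np.argmax(v, axis=1)],
                                index=self.values.index, name="argmax")
        n_flagged = int(np.isnan(taus).sum())
        if n_flagged:
            logger.warning("%d all-zero gene(s) have undefined tau and are "
                           "excluded from selection", n_flagged)

    @property
    def tissues(self) -> list[str]:
        return [c for c in self.values.columns if c != self.control_label]

    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.columns = [f"y_{c}" for c in df.columns]
        df["tau"] = self.tau
        df["argmax"] = self.argmax
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class TissueGeneSets:
    """Selected tissue-specific genes with per-gene tau and platform tags."""

    sets: dict[str, set[str]]
    tau: pd.Series
    threshold: float
    provenance: dict[str, str] = field(default_factory=dict)  # gene -> platform tag

    def tissue_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for tissue, genes in self.sets.items():
            for g in genes:
                out[g] = tissue
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tissue in sorted(self.sets):
            for g in sorted(self.sets[tissue]):
                rows.append({
                    "gene_id": g,
                    "tissue": tissue,
                    "tau": self.tau.get(g, np.nan),
                    "platform": self.provenance.get(g, ""),
                })
        return pd.DataFrame(rows, columns=["gene_id", "tissue", "tau", "platform"])


def select_specific_genes(table: TauTable, platform: str = "") -> TissueGeneSets:
    """3rd-quantile tau threshold; a gene joins tissue t iff tau >= threshold
    and its maximal condition is t (never the control)."""
    scored = table.tau.dropna()
    if len(scored) < 4:
        raise ValueError("need tau for at least 4 genes to set a quantile threshold")
    threshold = float(np.percentile(scored.to_numpy(), 75))  # linear interpolation
    sets: dict[str, set[str]] = {t: set() for t in table.tissues}
    for gene, tau in scored.items():
        cond = table.argmax[gene]
        if tau >= threshold and cond != table.control_label:
            sets[cond].add(gene)
    provenance = {g: platform for genes in sets.values() for g in genes} if platform else {}
    return TissueGeneSets(sets=sets, tau=table.tau, threshold=threshold, provenance=provenance)


def combine_platforms(microarray: TissueGeneSets, rnaseq: TissueGeneSets) -> TissueGeneSets:
    """Per-tissue union of the two platform sets.

    Genes claimed by different tissues on different platforms have no
    platform-agreement tissue, so they are dropped and logged.
    """
    if set(microarray.sets) != set(rnaseq.sets):
        raise ValueError("platform gene sets must be indexed by the same tissue labels")
    ma_tissue = microarray.tissue_of()
    rs_tissue = rnaseq.tissue_of()
    conflicts = {g for g in set(ma_tissue) & set(rs_tissue)
                 if ma_tissue[g] != rs_tissue[g]}
    for g in sorted(conflicts):
        logger.warning("gene %s dropped: %s-specific on microarray but %s-specific "
                       "on rnaseq", g, ma_tissue[g], rs_tissue[g])
    sets: dict[str, set[str]] = {}
    provenance: dict[str, str] = {}
    for tissue in microarray.sets:
        merged = (microarray.sets[tissue] | rnaseq.sets[tissue]) - conflicts
        sets[tissue] = merged
        for g in merged:
            in_ma = g in microarray.sets[tissue]
            in_rs = g in rnaseq.sets[tissue]
            provenance[g] = "both" if (in_ma and in_rs) else ("microarray" if in_ma else "rnaseq")
    tau = microarray.tau.combine_first(rnaseq.tau)
    return TissueGeneSets(sets=sets, tau=tau,
                          threshold=float("nan"), provenance=provenance)


def condition_summaries(
    matrices: dict[str, pd.DataFrame],
    method: str = "autoencoder",
    spec: CompressionSpec = CompressionSpec(),
) -> pd.DataFrame:
    """Per-gene, per-condition summary values ready for TauTable.

    ``method='autoencoder'`` compresses each condition to 1-D and calibrates
    across conditions; ``method='mean'`` is the built-in mean-expression
    baseline.
    """
    conditions = list(matrices)
    genes = matrices[conditions[0]].index
    for cond, m in matrices.items():
        if not m.index.equals(genes):
            raise ValueError(f"gene universe mismatch in condition {cond!r}")
    means = {cond: m.mean(axis=1) for cond, m in matrices.items()}
    if method == "mean":
        values = pd.DataFrame({cond: np.clip(means[cond], 0.0, None) for cond in conditions})
    elif method == "autoencoder":
        embeddings = {}
        for i, cond in enumerate(conditions):
            z = compress_tissue(matrices[cond],
                                spec=CompressionSpec(**{**spec.__dict__, "seed": spec.seed + i}))
            embeddings[cond] = z["dim_1"]
        values = calibrate_across_conditions(embeddings, means)
    else:
        raise ValueError(f"unknown method {method!r}")
    return values


def score_tissue_specificity(
    bundle: ExpressionBundle,
    method: str = "autoencoder",
    spec: CompressionSpec = CompressionSpec(),
    control_label: str = CONTROL_LABEL,
) -> TauTable:
    """End-to-end: split a bundle into condition matrices, summarize, tau."""
    matrices = as_condition_matrices(bundle, control_label=control_label)
    values = condition_summaries(matrices, method=method, spec=spec)
    return TauTable(values=values, control_label=control_label)
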