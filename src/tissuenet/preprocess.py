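"""Expression-bundle data model, normalization, filtering, and TSV I/O.

An :class:`ExpressionBundle` couples a genes x samples matrix with aligned
per-sample metadata and a unit tag; every pipeline stage consumes and
produces bundles.  Normalization covers TPM (length- and library-size
normalized, columns summing to one million) and a log2(x + pseudocount)
transform; filtering removes low-variance genes either by a drop fraction
(lowest ``floor(fraction * n_genes)`` variances removed) or by an explicit
variance cutoff (idempotent).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = {"counts", "tpm", "log2", "intensity"}
NONNEGATIVE_UNITS = {"counts", "tpm", "intensity"}
META_COLUMNS = ["tissue", "source", "platform", "group"]

EXPRESSION_FILE = "expression.tsv"
META_FILE = "sample_meta.tsv"
ATTRS_FILE = "bundle_attrs.json"
LENGTHS_FILE = "gene_lengths.tsv"
TRUTH_FILE = "truth.json"


class BundleError(ValueError):
    """Raised when a bundle or its inputs violate the data contract."""


@dataclass
class ExpressionBundle:
    """Genes x samples expression matrix with aligned sample metadata.

    ``matrix`` is indexed by gene ID with sample IDs as columns;
    ``sample_meta`` is indexed by sample ID with at least the columns
    tissue, source, platform and group (case/control).  ``unit`` records
    what the values mean; reconstructed output is tagged with a
    ``reconstructed:`` prefix.
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        genes = self.matrix.index
        samples = self.matrix.columns
        dup_genes = genes[genes.duplicated()].unique()
        if len(dup_genes):
            raise BundleError(f"duplicate gene ID(s): {list(dup_genes)[:5]}")
        dup_samples = samples[samples.duplicated()].unique()
        if len(dup_samples):
            raise BundleError(f"duplicate sample ID(s): {list(dup_samples)[:5]}")
        missing = [s for s in samples if s not in self.sample_meta.index]
        if missing:
            raise BundleError(f"sample(s) missing from metadata: {missing[:5]}")
        extra = [s for s in self.sample_meta.index if s not in set(samples)]
        if extra:
            raise BundleError(f"metadata row(s) without matrix column: {extra[:5]}")
        lacking = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if lacking:
            raise BundleError(f"metadata missing column(s): {lacking}")
        base_unit = self.base_unit
        if base_unit not in VALID_UNITS:
            raise BundleError(f"unknown unit tag {self.unit!r}")
        values = self.matrix.to_numpy()
        if not np.all(np.isfinite(values)):
            raise BundleError("matrix contains non-finite values")
        if base_unit in NONNEGATIVE_UNITS and not self.is_reconstructed and (values < 0).any():
            raise BundleError(f"negative values not allowed for unit {self.unit!r}")
        # metadata rows follow matrix column order; canonical index names
        self.sample_meta = self.sample_meta.loc[self.matrix.columns]
        self.matrix.index.name = "gene_id"
        self.matrix.columns.name = None
        self.sample_meta.index.name = "sample_id"

    @property
    def is_reconstructed(self) -> bool:
        return self.unit.startswith("reconstructed:")

    @property
    def base_unit(self) -> str:
        return self.unit.split(":", 1)[-1]

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionBundle":
        return ExpressionBundle(
            matrix=self.matrix[sample_ids].copy(),
            sample_meta=self.sample_meta.loc[sample_ids].copy(),
            unit=self.unit,
        )

    def condition_samples(self, condition: str, control_label: str = "control") -> list[str]:
        """Sample IDs for one condition: case samples of a tissue, or all
        control-group samples when ``condition`` is the control label."""
        meta = self.sample_meta
        if condition == control_label:
            mask = meta["group"] == "control"
        else:
            mask = (meta["tissue"] == condition) & (meta["group"] == "case")
        return list(meta.index[mask])


@dataclass
class GeneLengthTable:
    """Gene ID -> transcript length in base pairs."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][:5]
            raise BundleError(f"non-positive gene length(s): {list(bad)}")

    def for_genes(self, gene_ids: list[str]) -> np.ndarray:
        missing = [g for g in gene_ids if g not in self.lengths.index]
        if missing:
            raise BundleError(f"gene length missing for: {missing[:5]}")
        return self.lengths.loc[gene_ids].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# normalization / transformation / filtering
# ---------------------------------------------------------------------------

def tpm_normalize(bundle: ExpressionBundle, lengths: GeneLengthTable) -> ExpressionBundle:
    """Transcripts-per-million: per sample, rate = count/length, scaled so
    each column sums to 1e6."""
    if bundle.base_unit != "counts":
        raise BundleError(f"tpm_normalize expects counts, got {bundle.unit!r}")
    L = lengths.for_genes(bundle.gene_ids)
    counts = bundle.matrix.to_numpy(dtype=float)
    rates = counts / L[:, None]
    col_sums = rates.sum(axis=0)
    zero_cols = np.flatnonzero(col_sums == 0)
    if len(zero_cols):
        bad = [bundle.sample_ids[i] for i in zero_cols]
        raise BundleError(f"all-zero sample column(s): {bad[:5]}")
    tpm = rates / col_sums * 1e6
    return ExpressionBundle(
        matrix=pd.DataFrame(tpm, index=bundle.matrix.index, columns=bundle.matrix.columns),
        sample_meta=bundle.sample_meta.copy(),
        unit="tpm",
    )


def log2_transform(bundle: ExpressionBundle, pseudocount: float = 1.0) -> ExpressionBundle:
    """value -> log2(value + pseudocount); monotone per sample."""
    if pseudocount <= 0:
        raise BundleError(f"pseudocount must be > 0, got {pseudocount}")
    if bundle.base_unit == "log2":
        raise BundleError("bundle is already log2 transformed")
    return ExpressionBundle(
        matrix=np.log2(bundle.matrix + pseudocount),
        sample_meta=bundle.sample_meta.copy(),
        unit="log2",
    )


def filter_low_variance(
    bundle: ExpressionBundle,
    drop_fraction: float | None = 0.25,
    min_variance: float | None = None,
) -> ExpressionBundle:
    """Drop low-variance genes.

    With ``drop_fraction`` f, the genes with the ``floor(f * n_genes)``
    smallest across-sample variances are removed (ties broken by original
    order).  With ``min_variance`` v, genes with variance < v are removed —
    that mode is idempotent.  Survivor order is preserved.
    """
    if bundle.n_samples < 2:
        raise BundleError("variance filter needs at least 2 samples")
    variances = bundle.matrix.var(axis=1, ddof=1).to_numpy()
    if min_variance is not None:
        keep = variances >= min_variance
    else:
        if not (0 <= drop_fraction < 1):
            raise BundleError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
        k = int(np.floor(drop_fraction * bundle.n_genes))
        keep = np.ones(bundle.n_genes, dtype=bool)
        if k > 0:
            drop_idx = np.argsort(variances, kind="stable")[:k]
            keep[drop_idx] = False
    if not keep.any():
        raise BundleError("variance filter would remove every gene")
    return ExpressionBundle(
        matrix=bundle.matrix.loc[keep].copy(),
        sample_meta=bundle.sample_meta.copy(),
        unit=bundle.unit,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_bundle(bundle: ExpressionBundle, out_dir: str | Path,
                 lengths: GeneLengthTable | None = None) -> Path:
    """Write expression TSV + metadata TSV (+ optional gene lengths) plus a
    small attrs JSON carrying the unit tag.  Floats use shortest round-trip
    repr, so read_bundle reproduces the matrix exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr = bundle.matrix.copy()
    expr.index.name = "gene_id"
    # 17 significant digits guarantee exact float64 round-trip
    expr.to_csv(out_dir / EXPRESSION_FILE, sep="\t",
                float_format=lambda v: format(v, ".17g"))
    meta = bundle.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(out_dir / META_FILE, sep="\t")
    (out_dir / ATTRS_FILE).write_text(json.dumps({"unit": bundle.unit}, indent=2))
    if lengths is not None:
        lt = lengths.lengths.copy()
        lt.index.name = "gene_id"
        lt.rename("length_bp").to_csv(out_dir / LENGTHS_FILE, sep="\t")
    return out_dir


def read_bundle(in_dir: str | Path) -> ExpressionBundle:
    in_dir = Path(in_dir)
    expr_path = in_dir / EXPRESSION_FILE
    meta_path = in_dir / META_FILE
    if not expr_path.exists():
        raise BundleError(f"missing expression matrix: {expr_path}")
    if not meta_path.exists():
        raise BundleError(f"missing sample metadata: {meta_path}")
    matrix = pd.read_csv(expr_path, sep="\t", index_col="gene_id",
                         float_precision="round_trip").astype(float)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id", dtype=str)
    attrs_path = in_dir / ATTRS_FILE
    unit = "counts"
    if attrs_path.exists():
        unit = json.loads(attrs_path.read_text()).get("unit", "counts")
    return ExpressionBundle(matrix=matrix, sample_meta=meta, unit=unit)


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    return GeneLengthTable(lengths=table["length_bp"].astype(int))


def as_condition_matrices(bundle: ExpressionBundle, tissues: list[str] | None = None,
                          control_label: str = "control") -> dict[str, pd.DataFrame]:
    """Split a bundle into per-condition matrices: one per tissue (case
    samples) plus the pooled control mixture."""
    if tissues is None:
        case = bundle.sample_meta[bundle.sample_meta["group"] == "case"]
        tissues = sorted(case["tissue"].unique())
    out: dict[str, pd.DataFrame] = {}
    for cond in [*tissues, control_label]:
        samples = bundle.condition_samples(cond, control_label=control_label)
        if samples:
            out[cond] = bundle.matrix[samples]
    return out
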