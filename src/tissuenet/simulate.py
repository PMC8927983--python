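"""Synthetic expression bundles with planted ground truth.

Generates toy multi-tissue, multi-source compendia carrying every kind of
structure the downstream stages look for: per-gene Gaussian log2 baselines,
tissue-specific fold changes, per-source additive log-scale confounder
shifts, TF->target regulatory couplings, and gene pairs whose correlation
differs between the case tissues and the control mixture.  Counts are drawn
negative-binomially around the exponentiated log2 mean (``count_like``);
intensities are log-normal (``intensity_like``).  A fixed seed yields a
bit-identical bundle and truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .preprocess import ExpressionBundle, GeneLengthTable, TRUTH_FILE, write_bundle

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ["leaf", "root", "seed", "nodule"]
CONTROL_LABEL = "control"

#: baseline log2 mean distribution and within-group sample noise
_BASE_MEAN_LOC = 6.0
_BASE_MEAN_SCALE = 1.5
_SAMPLE_NOISE_SD = 0.5
#: TF latent signal / target coupling on the log2 scale
_TF_SIGNAL_SD = 1.0
_TARGET_COUPLING = 0.9
#: planted differential pairs sit at a high baseline so platform noise does
#: not drown the correlation signal
_DIFF_PAIR_MEAN = 8.0


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic bundle."""

    n_genes: int = 300
    n_tissues: int = 4
    samples_per_group: int = 40
    n_sources: int = 2
    n_specific_per_tissue: int = 20
    specific_effect: float = 8.0
    confounder_effect: float = 0.5
    n_tfs: int = 10
    targets_per_tf: int = 5
    n_diff_pairs: int = 10
    diff_rho_tissue: float = 0.8
    diff_rho_control: float = 0.0
    platform: str = "count_like"
    noise_dispersion: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tissues", "samples_per_group",
                     "n_specific_per_tissue", "n_tfs", "targets_per_tf", "n_diff_pairs"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be a positive integer")
        if self.n_sources < 1:
            raise SimConfigError("n_sources must be >= 1")
        if self.n_specific_per_tissue * self.n_tissues > self.n_genes:
            raise SimConfigError(
                "n_specific_per_tissue * n_tissues exceeds n_genes")
        if self.n_tfs >= self.n_genes:
            raise SimConfigError("n_tfs must be < n_genes")
        if self.specific_effect < 1:
            raise SimConfigError("specific_effect must be >= 1")
        if self.confounder_effect < 0:
            raise SimConfigError("confounder_effect must be >= 0")
        if not (-1 <= self.diff_rho_tissue <= 1 and -1 <= self.diff_rho_control <= 1):
            raise SimConfigError("diff_rho_tissue/diff_rho_control must be in [-1, 1]")
        if self.diff_rho_tissue == self.diff_rho_control:
            raise SimConfigError("diff_rho_tissue must differ from diff_rho_control")
        if self.platform not in {"count_like", "intensity_like"}:
            raise SimConfigError(f"platform must be count_like or intensity_like, got {self.platform!r}")
        if self.noise_dispersion <= 0:
            raise SimConfigError("noise_dispersion must be > 0")
        needed = (self.n_tfs * (1 + self.targets_per_tf)
                  + 2 * self.n_diff_pairs
                  + self.n_specific_per_tissue * self.n_tissues)
        if needed > self.n_genes:
            raise SimConfigError(
                f"n_genes={self.n_genes} too small for the planted structure "
                f"(needs >= {needed}; reduce n_tfs/targets_per_tf/n_diff_pairs/"
                f"n_specific_per_tissue)")


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated bundle, used as recovery oracle."""

    specific_genes: dict[str, set[str]]
    source_of_sample: dict[str, str]
    planted_edges: set[tuple[str, str]]
    diff_pairs: dict[tuple[str, str], tuple[float, float]]
    tf_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "specific_genes": {t: sorted(g) for t, g in self.specific_genes.items()},
            "source_of_sample": self.source_of_sample,
            "planted_edges": sorted(map(list, self.planted_edges)),
            "diff_pairs": [[a, b, rt, rc] for (a, b), (rt, rc) in sorted(self.diff_pairs.items())],
            "tf_ids": self.tf_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            specific_genes={t: set(g) for t, g in payload["specific_genes"].items()},
            source_of_sample=payload["source_of_sample"],
            planted_edges={tuple(e) for e in payload["planted_edges"]},
            diff_pairs={(a, b): (rt, rc) for a, b, rt, rc in payload["diff_pairs"]},
            tf_ids=payload["tf_ids"],
        )


def tissue_labels(n_tissues: int) -> list[str]:
    if n_tissues <= len(DEFAULT_TISSUES):
        return DEFAULT_TISSUES[:n_tissues]
    return DEFAULT_TISSUES + [f"tissue_{i}" for i in range(len(DEFAULT_TISSUES), n_tissues)]


def simulate_bundle(config: SimConfig) -> tuple[ExpressionBundle, SyntheticTruth, GeneLengthTable]:
    """Generate one bundle plus its ground truth and gene lengths.

    The matrix has ``n_genes`` rows and ``(n_tissues + 1) * samples_per_group``
    columns (the extra group is the control mixture, which carries no tissue
    effect).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tissues = tissue_labels(config.n_tissues)
    conditions = tissues + [CONTROL_LABEL]
    genes = [f"G{i:05d}" for i in range(config.n_genes)]

    # --- sample bookkeeping ---------------------------------------------
    sample_ids: list[str] = []
    tissue_of: list[str] = []
    group_of: list[str] = []
    for cond in conditions:
        for i in range(config.samples_per_group):
            sample_ids.append(f"{cond}_{i:03d}")
            tissue_of.append(cond)
            group_of.append("control" if cond == CONTROL_LABEL else "case")
    n_samples = len(sample_ids)

    # balanced source assignment within each condition
    sources = np.empty(n_samples, dtype=object)
    for cond in conditions:
        idx = [i for i, t in enumerate(tissue_of) if t == cond]
        labels = np.array([f"src{j % config.n_sources}" for j in range(len(idx))], dtype=object)
        rng.shuffle(labels)
        sources[idx] = labels

    # --- gene role layout -----------------------------------------------
    cursor = 0
    tf_idx = list(range(cursor, cursor + config.n_tfs)); cursor += config.n_tfs
    target_idx: dict[int, list[int]] = {}
    for k in tf_idx:
        target_idx[k] = list(range(cursor, cursor + config.targets_per_tf))
        cursor += config.targets_per_tf
    pair_idx: list[tuple[int, int]] = []
    for _ in range(config.n_diff_pairs):
        pair_idx.append((cursor, cursor + 1)); cursor += 2
    specific_idx: dict[str, list[int]] = {}
    for t in tissues:
        specific_idx[t] = list(range(cursor, cursor + config.n_specific_per_tissue))
        cursor += config.n_specific_per_tissue

    # --- log2-scale signal ----------------------------------------------
    mu = rng.normal(_BASE_MEAN_LOC, _BASE_MEAN_SCALE, size=config.n_genes)
    for a, b in pair_idx:
        mu[a] = mu[b] = _DIFF_PAIR_MEAN
    log2x = mu[:, None] + rng.normal(0.0, _SAMPLE_NOISE_SD, size=(config.n_genes, n_samples))

    # TF -> target couplings: targets follow the TF's per-sample deviation
    for k in tf_idx:
        delta = rng.normal(0.0, _TF_SIGNAL_SD, size=n_samples)
        log2x[k] += delta
        for j in target_idx[k]:
            log2x[j] += _TARGET_COUPLING * delta

    # differential pairs: bivariate deviations replacing the baseline noise
    case_mask = np.array([g == "case" for g in group_of])
    for (a, b), rho_by_group in zip(
            pair_idx,
            [(config.diff_rho_tissue, config.diff_rho_control)] * len(pair_idx)):
        rho_t, rho_c = rho_by_group
        dev = np.empty((2, n_samples))
        for mask, rho in ((case_mask, rho_t), (~case_mask, rho_c)):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            dev[:, mask] = rng.multivariate_normal(
                np.zeros(2), cov, size=int(mask.sum()), method="cholesky").T
        log2x[a] = mu[a] + dev[0]
        log2x[b] = mu[b] + dev[1]

    # tissue-specific fold change in the home tissue only (case samples)
    effect = np.log2(config.specific_effect)
    for t in tissues:
        home = np.array([tt == t for tt in tissue_of]) & case_mask
        for g in specific_idx[t]:
            log2x[g, home] += effect

    # per-source additive shift on the log scale, drawn per (source, gene)
    shift = {f"src{s}": rng.normal(0.0, config.confounder_effect, size=config.n_genes)
             for s in range(config.n_sources)}
    if config.confounder_effect == 0:
        shift = {k: np.zeros(config.n_genes) for k in shift}
    for j, src in enumerate(sources):
        log2x[:, j] += shift[src]

    # --- platform observation model -------------------------------------
    if config.platform == "count_like":
        mean_counts = np.exp2(log2x)
        alpha = config.noise_dispersion
        r = 1.0 / alpha
        p = r / (r + mean_counts)
        values = rng.negative_binomial(r, p).astype(float)
        unit = "counts"
        platform_label = "rnaseq"
    else:
        noisy = log2x + rng.normal(0.0, config.noise_dispersion,
                                   size=log2x.shape)
        values = np.exp2(noisy)
        unit = "intensity"
        platform_label = "microarray"

    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "tissue": tissue_of,
            "source": list(sources),
            "platform": platform_label,
            "group": group_of,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    bundle = ExpressionBundle(matrix=matrix, sample_meta=meta, unit=unit)

    lengths = GeneLengthTable(
        lengths=pd.Series(rng.integers(500, 5001, size=config.n_genes),
                          index=pd.Index(genes, name="gene_id"), name="length_bp"))

    no_signal = config.specific_effect == 1.0
    truth = SyntheticTruth(
        specific_genes={t: (set() if no_signal else {genes[g] for g in specific_idx[t]})
                        for t in tissues},
        source_of_sample=dict(zip(sample_ids, sources)),
        planted_edges={(genes[k], genes[j]) for k in tf_idx for j in target_idx[k]},
        diff_pairs={(genes[a], genes[b]): (config.diff_rho_tissue, config.diff_rho_control)
                    for a, b in pair_idx},
        tf_ids=[genes[k] for k in tf_idx],
    )
    return bundle, truth, lengths


def write_simulation(config: SimConfig, out_dir: str | Path) -> Path:
    """Simulate and write the standard bundle layout plus truth JSON."""
    bundle, truth, lengths = simulate_bundle(config)
    out_dir = write_bundle(bundle, out_dir, lengths=lengths)
    truth.to_json(out_dir / TRUTH_FILE)
    return out_dir


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def set_recovery(predicted: set, truth: set) -> dict:
    """Precision/recall of a predicted set; undefined ratios become None."""
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(truth) if truth else None
    return {"precision": precision, "recall": recall, "n_predicted": len(predicted),
            "n_truth": len(truth), "n_hit": tp}


def ranking_auroc(scores: Mapping, positives: Iterable) -> float | None:
    """AUROC of a full ranking (key -> score) against a positive set.

    Returns None when one of the classes is empty.
    """
    positives = set(positives)
    keys = list(scores.keys())
    y = np.array([k in positives for k in keys], dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        return None
    s = np.array([scores[k] for k in keys], dtype=float)
    return float(roc_auc_score(y, s))


def truth_recovery_report(predicted: Mapping, truth: SyntheticTruth) -> dict:
    """Score predicted structure against the planted truth.

    ``predicted`` may contain any of:

    - ``specific_genes``: map tissue -> set of gene IDs
    - ``edge_scores``: map (regulator, target) -> weight (full ranking)
    - ``edges``: iterable of (regulator, target) kept edges
    - ``pair_scores``: map sorted (gene, gene) -> |dz| or similar score
    """
    report: dict = {}
    if "specific_genes" in predicted:
        per_tissue = {}
        all_pred: set[str] = set()
        all_true: set[str] = set()
        for t, true_set in truth.specific_genes.items():
            pred = set(predicted["specific_genes"].get(t, set()))
            per_tissue[t] = set_recovery(pred, true_set)
            all_pred |= pred
            all_true |= true_set
        per_tissue["overall"] = set_recovery(all_pred, all_true)
        report["specific_genes"] = per_tissue
    if "edge_scores" in predicted:
        report["edge_auroc"] = ranking_auroc(predicted["edge_scores"], truth.planted_edges)
    if "edges" in predicted:
        report["edges"] = set_recovery({tuple(e) for e in predicted["edges"]},
                                       truth.planted_edges)
    if "pair_scores" in predicted:
        canon = {tuple(sorted(k)): v for k, v in predicted["pair_scores"].items()}
        positives = {tuple(sorted(k)) for k in truth.diff_pairs}
        report["pair_auroc"] = ranking_auroc(canon, positives)
    return report
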