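"""End-to-end orchestration: simulate -> preprocess -> deconfound -> tau ->
grn -> diffnet, with derived per-stage seeds and a machine-readable run
report (parameters as resolved, output digests, counts, and recovery
metrics whenever planted truth is available)."""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adae, diffnet, grn, simulate, specificity
from .preprocess import (
    ExpressionBundle,
    TRUTH_FILE,
    as_condition_matrices,
    filter_low_variance,
    log2_transform,
    read_bundle,
    read_gene_lengths,
    tpm_normalize,
    write_bundle,
)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "deconfound", "tau", "grn", "diffnet"]

#: full config schema with defaults; validate_config rejects unknown keys
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "runs/out",
    "in_dir": None,
    "stages": {stage: True for stage in STAGES},
    "simulate": {
        "n_genes": 300, "n_tissues": 4, "samples_per_group": 40, "n_sources": 2,
        "n_specific_per_tissue": 20, "specific_effect": 8.0, "confounder_effect": 0.5,
        "n_tfs": 10, "targets_per_tf": 5, "n_diff_pairs": 10,
        "diff_rho_tissue": 0.8, "diff_rho_control": 0.0,
        "platform": "count_like", "noise_dispersion": 0.05,
    },
    "preprocess": {"tpm": True, "log2": True, "pseudocount": 1.0, "drop_fraction": 0.0},
    "deconfound": {
        "embedding_dim": 16, "lambda_adv": 1.0, "learning_rate": 1e-3,
        "minibatch_size": 64, "max_epochs": 60, "patience": 10, "warmup_rounds": 5,
        "confounder": "source", "use_reconstructed": False,
    },
    "tau": {"method": "autoencoder", "learning_rate": 1e-3, "minibatch_size": 12,
            "max_epochs": 60, "patience": 10},
    "grn": {"n_trees": 100, "top_k": 1000, "embedding_dim": None,
            "tf_file": None, "restrict_regulators_to_specific": False,
            "learning_rate": 1e-3, "max_epochs": 60, "drop_fraction": 0.1},
    "diffnet": {"cap": 1000, "n_perm": 0, "compress": False, "embedding_dim": None,
                "learning_rate": 1e-3, "max_epochs": 60, "drop_fraction": 0.1},
}

class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def validate_config(source: str | Path | dict) -> dict:
    """Parse and validate a run configuration.

    Accepts a YAML path or an already-loaded mapping; unknown keys are
    rejected and every error is collected before raising, so one pass
    reports all problems.  Returns the config with defaults filled in.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = copy.deepcopy(dict(source))
    errors: list[str] = []
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(defaults: dict, incoming: dict, prefix: str) -> None:
        for key, value in incoming.items():
            path = f"{prefix}{key}"
            if key not in defaults:
                errors.append(f"unknown key: {path}")
                continue
            if isinstance(defaults[key], dict) and not isinstance(defaults[key], type(None)):
                if not isinstance(value, dict):
                    errors.append(f"{path}: expected a mapping")
                    continue
                merge(defaults[key], value, prefix=f"{path}.")
            else:
                defaults[key] = value

    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    merge(config, raw, prefix="")

    if not isinstance(config["seed"], int):
        errors.append("seed: expected an integer")
    sim = config["simulate"]
    try:
        simulate.SimConfig(**sim, seed=0).validate()
    except (TypeError, simulate.SimConfigError) as exc:
        errors.append(f"simulate: {exc}")
    if config["preprocess"]["pseudocount"] <= 0:
        errors.append("preprocess.pseudocount: must be > 0")
    if not (0 <= config["preprocess"]["drop_fraction"] < 1):
        errors.append("preprocess.drop_fraction: must be in [0, 1)")
    if config["deconfound"]["lambda_adv"] < 0:
        errors.append("deconfound.lambda_adv: must be >= 0")
    if config["tau"]["method"] not in {"autoencoder", "mean"}:
        errors.append("tau.method: must be 'autoencoder' or 'mean'")
    if config["grn"]["top_k"] < 1:
        errors.append("grn.top_k: must be >= 1")
    if config["diffnet"]["cap"] < 1:
        errors.append("diffnet.cap: must be >= 1")
    if errors:
        raise ConfigError(errors)
    return config


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunReport:
    seed: int
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, params: dict, outputs: dict[str, Path],
            counts: dict | None = None, recovery: dict | None = None) -> None:
        self.stages.append({
            "stage": name,
            "params": params,
            "output_digests": {k: _sha256(Path(v)) for k, v in outputs.items()},
            "counts": counts or {},
            "recovery": recovery or {},
        })

    def to_dict(self) -> dict:
        return {"seed": self.seed, "stages": self.stages}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=str))

    @staticmethod
    def load(path: str | Path) -> "RunReport":
        payload = json.loads(Path(path).read_text())
        report = RunReport(seed=payload["seed"])
        report.stages = payload["stages"]
        return report


def run_pipeline(config: dict) -> RunReport:
    """Execute the enabled stages in order; see DEFAULT_CONFIG for knobs."""
    config = validate_config(config)
    master = config["seed"]
    out_root = Path(config["out_dir"])
    out_root.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=master)
    stages = config["stages"]

    truth: simulate.SyntheticTruth | None = None
    bundle: ExpressionBundle | None = None
    lengths = None

    # ----- simulate ------------------------------------------------------
    if stages["simulate"]:
        sim_cfg = simulate.SimConfig(**config["simulate"], seed=_stage_seed(master, "simulate"))
        sim_dir = out_root / "sim"
        simulate.write_simulation(sim_cfg, sim_dir)
        bundle = read_bundle(sim_dir)
        truth = simulate.SyntheticTruth.from_json(sim_dir / TRUTH_FILE)
        lengths = read_gene_lengths(sim_dir / "gene_lengths.tsv")
        report.add("simulate", config["simulate"],
                   {"expression": sim_dir / "expression.tsv",
                    "truth": sim_dir / TRUTH_FILE},
                   counts={"n_genes": bundle.n_genes, "n_samples": bundle.n_samples})
    else:
        in_dir = Path(config["in_dir"] or out_root / "sim")
        if not in_dir.exists():
            raise FileNotFoundError(
                f"missing input bundle at {in_dir}; run the simulate stage or set in_dir")
        bundle = read_bundle(in_dir)
        truth_path = in_dir / TRUTH_FILE
        truth = simulate.SyntheticTruth.from_json(truth_path) if truth_path.exists() else None
        lengths_path = in_dir / "gene_lengths.tsv"
        lengths = read_gene_lengths(lengths_path) if lengths_path.exists() else None

    # ----- preprocess ----------------------------------------------------
    if stages["preprocess"]:
        pp = config["preprocess"]
        if pp["tpm"] and bundle.base_unit == "counts":
            if lengths is None:
                raise FileNotFoundError("TPM normalization requested but no gene "
                                        "length table found; rerun simulate")
            bundle = tpm_normalize(bundle, lengths)
        if pp["log2"] and bundle.base_unit != "log2":
            bundle = log2_transform(bundle, pseudocount=pp["pseudocount"])
        if pp["drop_fraction"] > 0:
            bundle = filter_low_variance(bundle, drop_fraction=pp["drop_fraction"])
        proc_dir = write_bundle(bundle, out_root / "processed")
        report.add("preprocess", pp, {"expression": proc_dir / "expression.tsv"},
                   counts={"n_genes": bundle.n_genes})

    # ----- deconfound ----------------------------------------------------
    if stages["deconfound"]:
        dc = config["deconfound"]
        labels = bundle.sample_meta[dc["confounder"]].to_dict()
        spec = adae.AdaeSpec(
            embedding_dim=dc["embedding_dim"], lambda_adv=dc["lambda_adv"],
            learning_rate=dc["learning_rate"], minibatch_size=dc["minibatch_size"],
            max_epochs=dc["max_epochs"], patience=dc["patience"],
            warmup_rounds=dc["warmup_rounds"], seed=_stage_seed(master, "deconfound"),
        )
        model = adae.train_adae(bundle, labels, spec)
        embedding = model.encode(bundle)
        emb_path = out_root / "embedding.tsv"
        emb = embedding.copy()
        emb.index.name = "sample_id"
        emb.to_csv(emb_path, sep="\t")
        recovery = {
            "confounder_probe_accuracy": adae.probe_accuracy(embedding, labels, seed=spec.seed),
            "chance_level": adae.chance_level(labels),
        }
        if dc["use_reconstructed"]:
            bundle = model.reconstruct(bundle)
            write_bundle(bundle, out_root / "deconfounded")
        report.add("deconfound", dc, {"embedding": emb_path},
                   counts={"rounds": len(model.history["val_mse"]),
                           "final_mse": model.history["final_mse"]},
                   recovery=recovery)

    # ----- tau -----------------------------------------------------------
    gene_sets: specificity.TissueGeneSets | None = None
    if stages["tau"]:
        tau_cfg = config["tau"]
        spec = specificity.CompressionSpec(
            learning_rate=tau_cfg["learning_rate"], minibatch_size=tau_cfg["minibatch_size"],
            max_epochs=tau_cfg["max_epochs"], patience=tau_cfg["patience"],
            seed=_stage_seed(master, "tau"),
        )
        table = specificity.score_tissue_specificity(bundle, method=tau_cfg["method"], spec=spec)
        gene_sets = specificity.select_specific_genes(table)
        tau_path = out_root / "tau.tsv"
        table.to_tsv(tau_path)
        sets_path = out_root / "tissue_gene_sets.tsv"
        gene_sets.to_frame().to_csv(sets_path, sep="\t", index=False)
        recovery = {}
        if truth is not None:
            recovery = simulate.truth_recovery_report(
                {"specific_genes": gene_sets.sets}, truth)
        report.add("tau", tau_cfg, {"tau": tau_path, "gene_sets": sets_path},
                   counts={t: len(s) for t, s in gene_sets.sets.items()},
                   recovery=recovery)

    # ----- grn -----------------------------------------------------------
    if stages["grn"]:
        g_cfg = config["grn"]
        if g_cfg["tf_file"]:
            regulators = grn.RegulatorList.from_file(g_cfg["tf_file"])
        elif truth is not None and truth.tf_ids:
            regulators = grn.RegulatorList(tf_ids=list(truth.tf_ids),
                                           provenance="simulated truth")
        else:
            raise FileNotFoundError("grn stage needs a TF list (grn.tf_file) "
                                    "or simulated truth with TF IDs")
        matrices = as_condition_matrices(bundle)
        grn_counts: dict[str, int] = {}
        grn_recovery: dict[str, float | None] = {}
        outputs: dict[str, Path] = {}
        seed = _stage_seed(master, "grn")
        for tissue, matrix in matrices.items():
            if tissue == "control":
                continue
            genes = set(regulators.tf_ids)
            if gene_sets is not None:
                genes |= gene_sets.sets.get(tissue, set())
            if truth is not None:
                genes |= {t for _, t in truth.planted_edges}
            sub = matrix.loc[[g for g in matrix.index if g in genes]]
            if g_cfg["restrict_regulators_to_specific"] and gene_sets is not None:
                specific_tfs = [t for t in regulators.tf_ids
                                if t in gene_sets.sets.get(tissue, set())]
                if len(specific_tfs) >= 2:
                    regs = grn.RegulatorList(tf_ids=specific_tfs)
                else:
                    logger.warning("tissue %s: <2 tissue-specific TFs, using all TFs", tissue)
                    regs = regulators
            else:
                regs = regulators
            if len(sub) < 3 or len(regs.intersect(sub.index).tf_ids) < 2:
                logger.warning("tissue %s: too few genes/regulators for GRN, skipped", tissue)
                continue
            cspec = specificity.CompressionSpec(
                learning_rate=g_cfg["learning_rate"], max_epochs=g_cfg["max_epochs"],
                seed=seed)
            compressed = grn.compress_samples(sub, embedding_dim=g_cfg["embedding_dim"],
                                             spec=cspec)
            if g_cfg["drop_fraction"] > 0:
                var = compressed.var(axis=1)
                k = int(np.floor(g_cfg["drop_fraction"] * len(compressed)))
                if k > 0:
                    drop = var.sort_values(kind="stable").index[:k]
                    compressed = compressed.drop(index=drop)
            network = grn.infer_grn(compressed, regs, n_trees=g_cfg["n_trees"], seed=seed)
            top = grn.top_edges(network, k=g_cfg["top_k"])
            hubs = grn.rank_hub_tfs(top)
            edge_path = out_root / f"grn_{tissue}_edges.tsv"
            top.to_tsv(edge_path)
            hub_path = out_root / f"grn_{tissue}_hubs.tsv"
            hubs.to_csv(hub_path, sep="\t", index=False)
            outputs[f"{tissue}_edges"] = edge_path
            outputs[f"{tissue}_hubs"] = hub_path
            grn_counts[tissue] = len(top)
            if truth is not None and truth.planted_edges:
                auroc = simulate.ranking_auroc(network.scores(), truth.planted_edges)
                grn_recovery[f"{tissue}_edge_auroc"] = auroc
        report.add("grn", g_cfg, outputs, counts=grn_counts, recovery=grn_recovery)

    # ----- diffnet -------------------------------------------------------
    if stages["diffnet"]:
        d_cfg = config["diffnet"]
        matrices = as_condition_matrices(bundle)
        if "control" not in matrices:
            raise ValueError("diffnet stage needs control-group samples")
        seed = _stage_seed(master, "diffnet")
        outputs = {}
        dn_counts: dict[str, int] = {}
        dn_recovery: dict[str, float | None] = {}
        for tissue, matrix in matrices.items():
            if tissue == "control":
                continue
            genes = matrix.index
            if gene_sets is not None and gene_sets.sets.get(tissue):
                keep = sorted(gene_sets.sets[tissue])
                if truth is not None:
                    planted = {g for pair in truth.diff_pairs for g in pair}
                    keep = sorted(set(keep) | (planted & set(genes)))
                genes = pd.Index([g for g in matrix.index if g in set(keep)])
            if len(genes) < 3:
                logger.warning("tissue %s: too few genes for diffnet, skipped", tissue)
                continue
            if d_cfg["compress"]:
                cspec = specificity.CompressionSpec(
                    learning_rate=d_cfg["learning_rate"], max_epochs=d_cfg["max_epochs"],
                    seed=seed)
                t_comp = grn.compress_samples(matrix.loc[genes],
                                              embedding_dim=d_cfg["embedding_dim"], spec=cspec)
                c_comp = grn.compress_samples(matrices["control"].loc[genes],
                                              embedding_dim=d_cfg["embedding_dim"], spec=cspec)
            else:
                # independently trained per-condition compressions do not share
                # a latent basis and wash out pair correlations; raw matrices
                # are the default comparison space
                t_comp = matrix.loc[genes]
                c_comp = matrices["control"].loc[genes]
            # drop latent-zero-variance genes from both before correlating
            ok = (t_comp.var(axis=1) > 0) & (c_comp.var(axis=1) > 0)
            t_comp, c_comp = t_comp.loc[ok], c_comp.loc[ok]
            if d_cfg["drop_fraction"] > 0:
                var = (t_comp.var(axis=1) + c_comp.var(axis=1))
                k = int(np.floor(d_cfg["drop_fraction"] * len(t_comp)))
                if k > 0:
                    drop = var.sort_values(kind="stable").index[:k]
                    t_comp, c_comp = t_comp.drop(index=drop), c_comp.drop(index=drop)
            table = diffnet.pairwise_diffcorr(t_comp, c_comp)
            if d_cfg["n_perm"] > 0:
                table["p_perm"] = diffnet.permutation_null(
                    t_comp, c_comp, n_perm=d_cfg["n_perm"], seed=seed)
            net = diffnet.build_network(table, cap=d_cfg["cap"])
            modules = diffnet.detect_modules(net)
            hubs = diffnet.hub_scores(table)
            table_path = out_root / f"diffcorr_{tissue}.tsv"
            table.to_csv(table_path, sep="\t", index=False)
            mod_path = out_root / f"modules_{tissue}.tsv"
            pd.Series(modules, name="module").rename_axis("gene_id").to_csv(mod_path, sep="\t")
            hub_path = out_root / f"diff_hubs_{tissue}.tsv"
            hubs.to_csv(hub_path, sep="\t", index=False)
            outputs[f"{tissue}_table"] = table_path
            outputs[f"{tissue}_modules"] = mod_path
            outputs[f"{tissue}_hubs"] = hub_path
            dn_counts[f"{tissue}_edges"] = len(net.edges)
            dn_counts[f"{tissue}_modules"] = len(set(modules.values()))
            if truth is not None and truth.diff_pairs:
                scores = {(a, b): abs(dz) for a, b, dz in
                          table[["gene_a", "gene_b", "dz"]].itertuples(index=False)}
                dn_recovery[f"{tissue}_pair_auroc"] = simulate.truth_recovery_report(
                    {"pair_scores": scores}, truth).get("pair_auroc")
        report.add("diffnet", d_cfg, outputs, counts=dn_counts, recovery=dn_recovery)

    report_path = out_root / "run_report.json"
    report.save(report_path)
    return report
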