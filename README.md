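# tissuenet

Adversarial deconfounding, tissue-specificity scoring, and tissue-specific
network inference for multi-source expression compendia — with a bundled
synthetic-data generator that plants ground truth for every stage.

The pipeline mirrors a common integrative-transcriptomics workflow:

1. **simulate** — generate a genes × samples bundle (counts or intensities)
   with tissue signal, per-source confounder shifts, planted TF→target
   regulation, and gene pairs whose correlation differs between case
   tissues and the control mixture (`tissuenet.simulate`).
2. **preprocess** — TPM normalization, log2(x+1) transform, low-variance
   gene filtering, TSV bundle I/O (`tissuenet.preprocess`).
3. **deconfound** — an adversarial deconfounding autoencoder: the encoder
   learns a sample embedding that reconstructs expression while an
   adversary network cannot predict the data source from it
   (`tissuenet.adae`; pure-numpy MLP/Adam engine in `tissuenet._nn`).
4. **tau** — per-condition 1-D autoencoder compression of each gene's
   profile, affine calibration across conditions, and the tau specificity
   index with 3rd-quantile selection (`tissuenet.specificity`).
5. **grn** — GENIE3-style random-forest regulator importances on
   64/32-dimension sample-compressed matrices, top-k edge retention, and
   degree-ranked hub TFs (`tissuenet.grn`).
6. **diffnet** — tissue-vs-control differential co-expression via the
   Fisher z difference statistic, Benjamini-Hochberg adjustment, an
   optional pooled permutation null, average-change hub genes, and greedy
   modularity modules (`tissuenet.diffnet`).

Every stochastic stage is seeded; a fixed master seed reproduces every
output file byte-for-byte.

## Run the tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: tau and Fisher-z
closed-form oracles, type-I-error calibration, deconfounding and
planted-structure recovery on the simulator, exhaustive-modularity module
checks, and plumbing exactness (BH step-up vs statsmodels, TPM column sums,
bundle round-trips, digest-identical pipeline reruns).

## CLI

One subcommand per stage plus `run-all`; common flags `--config` (YAML),
`--seed`, `--out`, `--log-level`.

```sh
tissuenet simulate --seed 7 --out runs/demo
tissuenet preprocess --in runs/demo/sim --out runs/demo
tissuenet deconfound --in runs/demo/sim --confounder source --lambda 1.0 --out runs/demo
tissuenet tau --in runs/demo/sim --out runs/demo
tissuenet grn --in runs/demo/sim --trees 100 --top 1000 --out runs/demo
tissuenet diffnet --in runs/demo/sim --cap 1000 --perms 100 --out runs/demo
tissuenet run-all --seed 7 --out runs/demo
```

Configuration keys and defaults live in
`tissuenet.pipeline.DEFAULT_CONFIG`; unknown keys are rejected with all
errors reported at once. Each run writes a `run_report.json` with resolved
parameters, sha256 digests of every output, per-stage counts, and recovery
metrics against the planted truth when a `truth.json` is present.

Example YAML:

```yaml
seed: 7
out_dir: runs/demo
simulate:
  n_genes: 500
  n_tissues: 4
  samples_per_group: 40
  n_sources: 2
  specific_effect: 8.0
deconfound:
  embedding_dim: 16
  lambda_adv: 1.0
diffnet:
  n_perm: 100
```

## Layout

```
src/tissuenet/
  _nn.py          dense-layer / Adam / autoencoder training engine (numpy)
  preprocess.py   ExpressionBundle, TPM, log2, variance filter, TSV I/O
  simulate.py     SimConfig, planted-truth simulator, recovery metrics
  adae.py         adversarial deconfounding autoencoder + probes + CV selection
  specificity.py  1-D compression, calibration, tau, gene-set selection
  grn.py          sample-axis compression, random-forest GRN, hubs
  diffnet.py      Fisher z, BH, permutation null, network, hubs, modules
  pipeline.py     config validation, orchestration, run report
  cli.py          click interface
```
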