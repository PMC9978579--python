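# debatch

Batch-effect normalization for multi-batch untargeted metabolomics intensity
tables, based on adversarial training of an autoencoder against a batch
classifier. The autoencoder objective combines three terms:

```
L = lambda_g * (reconstruction + r_g) - lambda_d * L_d + lambda_v * L_v
```

* **reconstruction** — mean squared error on log-standardized intensities;
* **r_g** — a clustering reward in [0, 1] that is zero when all samples of
  the same reference group co-cluster after UMAP flattening and HDBSCAN
  clustering of the latent space (a differentiable latent-distance
  alternative is available via `grouping_method: distance`);
* **L_d** — the batch classifier's cross-entropy, subtracted so that
  separable batches penalize the autoencoder;
* **L_v** — the mean variation coefficient (sd/mean) of reconstructed
  replicate intensities per (reference group, batch, feature), countering
  the variance inflation many normalizers produce.

The bottleneck width defaults to the number of principal components needed
to explain 90% of the preprocessed data variance. Training includes early
stopping (runaway classifier loss, output collapse), a randomized
hyperparameter grid search, and rank-sum model selection over four quality
criteria: between-batch replicate correlation, mean batch VC, VC-inflation
fraction, and a batch-mixing probe. Outputs are mapped back to the intensity
scale and are strictly positive.

The package also ships a synthetic multi-batch data generator with known
ground truth (per-(batch, feature) multiplicative effects, log-normal base
intensities, multiplicative noise, detection-limit censoring), ablation
helpers (batch removal, feature removal, missing-value injection), and the
full evaluation-metric suite.

## Input formats

* **Intensity matrix** (CSV/TSV): header row of feature IDs, first column
  sample IDs, rows = samples (set `transpose: true` for the other
  orientation). Empty cells, `NA` or `NaN` denote missing values.
* **Batch info** (CSV/TSV): columns `sample,batch,group`; empty `group`
  marks a non-reference sample. At least one reference group must span two
  or more batches.
* **Run configuration**: one YAML file; every key has a default (see
  `debatch.data_io.RunConfig`). Missing and sub-threshold cells are replaced
  by `min_relevant_intensity` (default 1000 counts).

## CLI

```sh
debatch simulate --design design.yaml --out-dir sim/        # synthetic data
debatch normalize --config run.yaml                         # full pipeline
debatch train-one --config run.yaml --lambda-d 0.3          # single run
debatch evaluate --before raw.csv --after norm.csv --info info.csv
```

`normalize` validates the inputs, runs the randomized grid search, selects
the best model, and writes `normalized.csv`, `ranking.csv`, per-run history
CSVs, `evaluation.json` and a `manifest.json` with seeds and versions.

Minimal `run.yaml`:

```yaml
data_path: data.csv
info_path: batch_info.csv
out_dir: out
grid_size: 20
epochs: 100
seed: 1
```

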