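# pglscan

Phylogenetic generalized least squares (PGLS) scanning of strain-by-feature
phenotype matrices against replicative-lifespan measures, for comparative
analyses across closely related yeast isolates (or any tip-labeled taxa).

The package provides:

- **`pglscan.phylo`** — Newick parsing and tree geometry: the MRCA-depth
  (shared-path) and patristic-distance matrices that all covariance models
  consume. Trees may be non-ultrametric and contain polytomies.
- **`pglscan.pgls`** — GLS regression under four trait-evolution covariance
  models (Null, Brownian motion, Pagel's lambda, fixed-root
  Ornstein–Uhlenbeck), with ML estimation of the model parameter, ML model
  selection, two-sided slope t tests, and leave-one-out robustness
  p-values.
- **`pglscan.preprocess`** — per-feature standardization (mean 0, sample
  s.d. 1), missing-value filtering for metabolite-style matrices, case-wise
  kNN imputation (exp(−distance) weights over complete neighbor rows),
  peptide-to-gene aggregation of standardized profiles, centered PCA with
  top-contributor export, and Pearson/Spearman correlation helpers.
- **`pglscan.coverage`** — relative mitochondrial DNA coverage from
  per-base depth tracks (mean mito depth over mean nuclear depth), with the
  rDNA window chrXII:45,000–50,000 (1-based, inclusive) excluded by
  default; reads bedGraph and per-base TSV tracks, and BED exclusion lists.
- **`pglscan.synthetic`** — deterministic generators for every input:
  pure-birth trees, traits drawn under any of the evolution models, feature
  matrices with planted linear effects and configurable missingness,
  Poisson depth profiles with an optional coverage spike — plus the bundled
  per-strain phenotype table (22 natural isolates + the BY4743 reference).
- **`pglscan.pipeline`** — orchestration: builds the four lifespan measures
  (mean, max, log mean, log max), scans every feature × measure with model
  selection and leave-one-out checks, and calls top hits (significant slope
  under ≥ 2 measures, strict `p < alpha`).

## Command line

```sh
# synthetic dataset (tree, lifespan table, features, truth table)
pglscan simulate --n-tips 30 --n-features 200 --n-planted 10 --seed 1 --out-dir demo/

# standardize / filter / impute a matrix
pglscan preprocess --matrix demo/features.tsv --impute-k 10 --out demo/features_std.tsv

# PGLS association scan (all four models, ML selection, LOO)
pglscan scan --tree demo/tree.nwk --lifespan demo/lifespan.tsv \
             --block synthetic=demo/features_std.tsv --out demo/associations.tsv

# top-hit calling
pglscan tophits --records demo/associations.tsv --out demo/tophits.tsv

# relative mtDNA coverage from a depth track
pglscan coverage --bedgraph depth.bedgraph

# config-driven end-to-end run
pglscan report --config config.json --out-dir report/
```

A minimal end-to-end config:

```json
{"synthetic": {"seed": 3, "n_tips": 30, "n_features": 200, "n_planted": 10, "beta": 3.0}}
```

or, to compute only the bundled strain-table summary statistics:

```json
{"fixture_only": true}
```

Matrices are TSV with strains as rows (first column `strain`); association
records and top-hit tables are TSV; gene lists are newline-delimited text.

## Notes on conventions

- Likelihoods are ML (not REML); model selection compares raw maximized
  log-likelihoods, ties broken toward the simpler model.
- Slope p-values use a two-sided t test with n − 2 degrees of freedom and
  no multiple-testing correction.
- Natural logs are used for the log-lifespan measures; slope-test p-values
  are invariant to the log base.
- The top-hit caller can additionally require leave-one-out stability
  (`require_robust`), which the config-driven runner enables by default.
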