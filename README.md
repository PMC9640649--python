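# nodesig

A tested, reusable pipeline for label-free proteomics biomarker studies of
binary clinical outcomes (positive vs. negative nodal status). It covers the
full discovery-to-verification path on quantitation matrices:

- **`nodesig.simulate`** — synthetic data with recorded ground truth: log2
  LFQ-style matrices with left-censored (MNAR) missingness, planted two-group
  effects, correlated peptide/protein/transcript marker panels, paired
  tumor/node tables, and Skyline-style transition reports with blanks.
- **`nodesig.preprocess`** — log2 transform and down-shifted-normal
  imputation (per sample column: `Normal(mu - 1.8*sigma, (0.3*sigma)^2)`),
  plus per-group detection statistics.
- **`nodesig.differential`** — equal-variance two-sided Student's t,
  Benjamini-Hochberg step-up correction, the exclusive-detection rule (any
  exclusive detection at the p-level; >= 50% detection in the exclusive group
  at the FDR level), log2 ratios as differences of group means, and PCA
  segregation summaries.
- **`nodesig.cluster_assoc`** — hierarchical clustering over a 3-method x
  22-metric grid with per-cell failure isolation, two-group cluster cutting
  (C1 = larger cluster), and two-sided Fisher-exact association of clusters
  with categorical covariates.
- **`nodesig.emt`** — per-sample epithelial/mesenchymal scores
  (mean Mes − mean Epi over observed values) and a Shapiro-Wilk-guided paired
  comparison (paired t or Wilcoxon signed-rank).
- **`nodesig.sigsearch`** — exhaustive signature enumeration (all variable
  subsets of size 1..N), a 10-family classifier sweep, repeated stratified
  K-fold cross-validation (one pooled ROC AUC per repetition), top-1 +
  t-test-equivalence selection, label-permutation validation, the
  high-performance filter (mean AUC >= 0.85 and permutation p <= 0.05), and
  marker-frequency summaries.
- **`nodesig.targeted_qc`** — SRM/PRM quantification math: light/heavy ratios
  from summed transition areas, dotp/rdotp with decision gates
  (include >= 0.9 / exclude <= 0.8 / review between), carryover %, ppm mass
  error with the strict < 10 ppm gate, qPCR efficiency
  `E = 10^(-1/slope) - 1` with the 95–105% gate, and efficiency-corrected
  (Pfaffl-style) relative quantification with multi-reference support.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the two
simulation-heavy criteria (signature recovery and null suppression) take
several minutes combined. The rest of the suite finishes in seconds.

## CLI

```sh
nodesig impute table.tsv imputed.tsv --shift 1.8 --width 0.3 --seed 1
nodesig differential table.tsv labels.tsv out.tsv --fdr
nodesig cluster-grid imputed.tsv grid.json --k 2 --mask table.tsv
nodesig emt-score --signature sig.tsv --paired tumor.tsv node.tsv emt.json
nodesig sigsearch-run --panel panel.tsv --labels labels.tsv \
    --max-size 5 --classifiers all --reps 10 --perms 100 --seed 1 report.json
nodesig tqc srm transitions.csv srm.tsv
nodesig tqc carryover transitions.csv carryover.tsv
nodesig tqc pfaffl --e-target 1.0 --e-ref 1.0 --dcq-target 3 --dcq-ref 1
```

Quantitation tables are TSV (rows = features, columns = samples, first
column the feature id, empty cell = missing). Labels are a two-column TSV
(sample id, group; `pN+`/`pN0`, `pos`/`neg` and similar aliases accepted).
Transition reports are long CSV with columns
`run_id,peptide,isotope_label,transition_id,area`.

## Reproducibility notes

- All generators and analyses are deterministic given their seeds; imputation
  draws are seeded per sample column so edits elsewhere in a table do not
  perturb a column's values.
- Cross-validation fold partitions are derived from `(base_seed, repetition)`
  and shared across signature-classifier pairs, so AUC distributions are
  directly comparable; permutation p-values use the add-one estimator
  `(1 + #{perm >= obs}) / (n + 1)`.
- Binary set metrics in the clustering grid run on the detection mask
  (observed = 1) rather than continuous log2 values; two metrics dropped by
  newer SciPy (kulsinski, sokalmichener) are implemented locally.
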