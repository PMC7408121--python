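# omicspair

Phenotype-dependent metabolome–transcriptome integration. For every
gene–metabolite pair the package fits the linear model

```
m = b1 + b2*g + b3*p + b4*(g*p) + e
```

where `m` is a log metabolite abundance, `g` an adjusted gene expression
value and `p` a binary phenotype (e.g. breed, or high/low feed
efficiency). A significant interaction coefficient `b4` flags pairs
whose gene–metabolite slope differs between the phenotype groups.
Around this engine the package provides:

- **preprocessing** — low-count gene removal, median-of-ratios size
  factors + `log2(x/sf + 1)` normalization, relative-standard-deviation
  filtering and natural-log transform of metabolites, lowest-variance
  and negativity screens, and a k·SD phenotype classifier;
- **covariate adjustment** — per-feature fixed-effect OLS against
  configurable designs (pen, batch, RIN, age, …), with the phenotype
  under test always kept out of its own adjustment;
- **pair integration** — blocked, fully vectorized OLS over every
  gene × metabolite combination, two-tailed interaction p-values,
  Benjamini–Hochberg FDR across the whole model family, per-group
  Spearman correlations and their signed difference, and the
  significance screens (FDR ≤ 0.1, |diff| > 0.1, optional raw-p cutoff);
- **clustering** — partition of significant pairs by the sign of the
  reference-group correlation, unique gene/metabolite summaries, and a
  deterministic heatmap ordering;
- **enrichment** — hypergeometric over-representation (upper tail,
  P(X ≥ k)) against a GMT set library, with optional
  relative-betweenness topology impact;
- **simulation** — a seeded generator of negative-binomial counts,
  log-normal abundances, covariates and planted interaction pairs, so
  the entire pipeline is testable offline.

Two small published worked-example pair tables ship as plain TSV
(`omicspair.datasets`) and back the deterministic worked-example tests.

## CLI

Every stage is a subcommand; options can also come from a YAML config
(`--config`, flags win). All stochastic stages take `--seed`.

```sh
omicspair simulate   --out-dir demo --seed 7 --n-genes 200 --n-metabolites 50
omicspair preprocess --counts demo/counts.tsv --metabolites demo/metabolites.tsv --out-dir demo
omicspair adjust     --genes demo/genes_normalized.tsv --metabolites demo/metabolites_log.tsv \
                     --metadata demo/metadata.tsv --mode breed --out-dir demo
omicspair integrate  --genes demo/genes_adjusted.tsv --metabolites demo/metabolites_adjusted.tsv \
                     --metadata demo/metadata.tsv --phenotype-column breed --out demo/pairs_all.tsv
omicspair cluster    --pairs demo/pairs_all.tsv --out-dir demo
omicspair ora        --hits-file hits.txt --universe-file universe.txt \
                     --gmt demo/pathways.gmt --out demo/ora.tsv
```

or end to end:

```sh
omicspair pipeline --config demo.yaml
```

with a config such as

```yaml
simulate: true
n_genes: 200
n_metabolites: 50
n_samples: 40
group_sizes: [12, 28]
n_planted: 20
delta_slope: 1.5
seed: 7
mode: breed
phenotype_column: breed
out_dir: demo
```

File formats are deliberately plain: UTF-8 TSV matrices
(first column `feature_id`, round-trip exact float serialization),
a TSV sample table keyed by `sample_id`, and standard GMT for set
libraries.

## Notes on conventions

- `diff_corr = cor_group1 − cor_group0`, signed; group0 is the
  reference group of the phenotype coding (e.g. Duroc, or high FE).
- The variance filter removes `ceil(fraction · n)` lowest-variance
  features, ties broken lexically by feature ID.
- BH-FDR is computed across *all* fitted pairs, not per metabolite.
- The count normalization is a documented stand-in for a variance
  stabilizing transform: size factors by median-of-ratios, then
  `log2(x/sf + 1)`.
- The hypergeometric tail is P(X ≥ k) — zero overlap gives p = 1.
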