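# genematch

Covariate-matched null gene sets for enrichment analysis.

Gene-set overlap tests are easily confounded by transcript covariates:
candidate lists and target lists both tend to be enriched for long, highly
expressed genes. `genematch` builds sampling weights from the ratio of two
kernel density estimates — one fit on a target set's covariates, one on the
whole gene universe — and draws random gene sets *matched* to the target's
expression and/or coding-sequence-length distribution. Overlaps between
matched null sets and candidate lists are then scored with exact right-tail
hypergeometric tests, producing a resampling null distribution against which
the target set's own enrichment can be judged. A companion regression module
quantifies how much CLIP tag depth is predictable from expression and length
alone.

## Modules

| module | what it does |
| --- | --- |
| `genematch.universe` | read/validate the per-gene covariate TSV and gene-set files; expression/length/count filters; top-N selections |
| `genematch.sampling` | exact Gaussian KDEs (1D/2D), density-ratio weights, weighted sampling without replacement (exponential keys), replicate draws |
| `genematch.enrichment` | 2×2 contingency tables, exact right-tail p (log-factorial accumulation), odds ratio + Woolf 95% CI, null summaries |
| `genematch.regression` | Pearson correlation, OLS fits of log2 tag count on log2 covariates, the full model-family table |
| `genematch.synthetic` | generator for universes/targets/candidates with known covariance structure and closed-form expected r² |
| `genematch.pipeline` / `genematch.cli` | config-driven orchestration of all stages with a reproducibility manifest |

## Input formats

* **Gene table**: TSV with a header; default columns `symbol`, `logCPM`,
  `cds_length`, `tx_length`, `clip_count` (names remappable via
  `column_map`). Lengths may be pre-log2 (default) or raw nucleotides with
  `log_transform_lengths: true`. Missing covariates stay missing — a record
  only survives filters that require what it has.
* **Gene sets**: plain text, one symbol per line, `#` comments allowed.
  Symbols are uppercased and stripped before any set operation.

## CLI

All verbs take a YAML config; `run` executes every stage:

```yaml
# config.yaml
gene_table: genes.tsv
target_set: target.txt
candidate_sets: [sfari.txt, rdnv.txt]
out_dir: out/
min_log_expr: 2.0          # strict: logCPM > 2
require_cds_len: true
require_tx_len: true
modes: [expression, cds_length, both_2d]
variants: [include_all, exclude_target, top_excluded]
n_replicates: 1000
genome_size: null           # null -> N = filtered universe size
clip_filters: [1, 17]       # count >= 1 and count > 16
seed: 1
```

```sh
genematch validate config.yaml     # config + path check
genematch weights  config.yaml     # density-ratio weight TSVs only
genematch sample   config.yaml     # matched replicate draws
genematch enrich   config.yaml     # target vs candidates, exact tests
genematch regress  config.yaml     # tag-depth regression table
genematch run      config.yaml --seed 1 --out out/
```

`run` writes the filtered universe, per-mode weight tables (symbol,
raw_ratio, probability), replicate draws (long-format TSV), enrichment rows
(cells, p, OR, CI), per-comparison null p-value TSVs and histograms
(TSV + PNG), the regression table, and `manifest.json` with every count,
bandwidth, and derived seed. Reruns with the same config are byte-identical
on all numeric outputs.

## Reproducibility notes

* One top-level seed governs a run; replicate r uses the splittable seed
  `SeedSequence(entropy=seed, spawn_key=(r,))`, so replicates are identical
  regardless of generation order.
* KDE bandwidths default to the normal-reference rule
  `0.9 * min(sd, IQR/1.34) * n^(-1/5)` per dimension and are recorded in the
  weight metadata and run manifest; pass explicit bandwidths to reproduce
  other conventions (some environments scale the 2D default by a constant).
* The odds ratio is the sample cross-product estimate (with Haldane–Anscombe
  0.5 correction when a cell is zero), not the conditional-MLE estimate some
  tools report; small numeric differences from those tools are expected.
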