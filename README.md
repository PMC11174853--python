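# nbshift

Negative-binomial count modeling and ECDF cumulative-shift statistics for
diurnal RNA-seq time courses, built around a two-genotype (CS vs DS), four
time-point, three-replicate design.

The package implements, as reusable and tested components:

- **`nbshift.synthetic`** — a fully specified synthetic-data generator: NB2
  counts with a log-linear mean→theta dispersion trend, per-gene diurnal
  profiles, injectable per-time-point differential expression with truth
  labels, replicate outliers, a global per-time-point genotype shift, a flat
  housekeeping gene, and annotation maps (chromosomes, BP/pathway terms,
  paralog triplet clusters). Also emits alignment-interval tables that
  round-trip through the quantifier.
- **`nbshift.quantify`** — read QC trimming (terminal-window quality rule,
  length filter), greatest-depth-of-coverage transcript counting from
  alignment intervals (unique + complete filters), housekeeping-gene
  normalization, and median-of-ratios size factors as a sanity check.
- **`nbshift.count_model`** — NB2 machinery: abundance-binned pooling of
  counts (rounded mean ≥ 8, bins of ≥ 30 members merged upward), per-bin
  theta MLE, a gamma log-linear theta-on-log-mean trend, and an iterative
  outlier-trimmed mean estimator that maximizes the smallest two-sided tail
  probability of the replicates (with degrees-of-freedom bookkeeping: at
  most one removal for three replicates, otherwise exclusion).
- **`nbshift.diffexpr`** — the Wald test of zero log fold change between two
  trimmed estimates under a fixed trend theta (means below 8 floored),
  Benjamini–Hochberg correction, DEG calling with the abundance and
  |log2FC| ≥ 0.9 filters, a time-point-association test (≥ 2-fold vs every
  other point, three BH-adjusted p-values < 0.05), and
  enhancement/weakening/inversion classification of DE events relative to
  each line's mean diurnal expression.
- **`nbshift.shiftstats`** — the cumulative shift (sum of signed ECDF
  differences over pooled values) with exact permutation p-values (10,000
  resamples, floored at 1e-4; paired and unpaired label permutation),
  per-time-point diurnal variance, gene-set activity and differential
  activity shifts, and standardized expression profiles.
- **`nbshift.coexpression`** — gene-pair correlation from simulated NB2
  counts (30 draws per time point, log2 with the ≥ 8 floor, 4 independent
  simulations per gene aggregated over 16 cross pairings), per-time-point
  correlation, coexpression calls at r ≥ 0.7, and cross-line preservation /
  coregulation analysis.
- **`nbshift.enrichment`** — directional Fisher's exact over-/under-
  representation with per-family BH filtering, and paralog-per-gene
  statistics with the ≥ 1-paralog universe adjustment.
- **`nbshift.pipeline`** — end-to-end orchestration with a manifest,
  deterministic seeding, and report computations (UP/DOWN ratios, DEG
  chromosome distributions, cluster preservation, MAD activity curves).

## Command line

```sh
nbshift synth    --seed 1 --n-genes 300 --outdir out/synth
nbshift quantify --intervals out/synth/alignments.tsv --hk-gene gene0000 --outdir out/quant
nbshift model    --counts out/synth/counts.tsv --outdir out/model
nbshift de       --estimates out/model/estimates.tsv --trend out/model/theta_trend.json --outdir out/de
nbshift activity --estimates out/model/estimates.tsv --terms out/synth/bp_terms.tsv --seed 1 --outdir out/act
nbshift coexpr   --estimates out/model/estimates.tsv --trend out/model/theta_trend.json --seed 1 --outdir out/cx
nbshift enrich   --de-table out/de/de_table.tsv --terms out/synth/bp_terms.tsv --universe genes.txt --outdir out/enr
nbshift run      --seed 1 --outdir out/run      # full pipeline on synthetic data
nbshift report   --rundir out/run
```

All tables are TSV; the theta trend serializes as JSON; each `run` directory
contains a `manifest.json` of completed stages and a `report.json` of
summary statistics.

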