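# budclock

Analysis toolkit for a seasonal RNA-seq time series of developing buds:

- **io_formats** — readers/writers for count tables (merged or per-sample
  featureCounts-style), sample sheets, daily weather series, functional
  annotations, gene-family lists and GFF3-derived exon-union gene lengths,
  plus replicate-completeness filtering of the design.
- **normalization** — CPM and RPKM matrices and the expression-sum gene
  filter (inclusive `>=` threshold on per-gene CPM sums).
- **envcorrelation** — keyword-defined gene sets (case-insensitive substring
  match over annotation text), per-sample median/mean aggregation, Spearman
  rank correlation against the daily mean temperature, and calibration
  against random gene sets of matched size drawn from the same
  expression-cutoff pool (add-one empirical p).
- **reference_genes** — qRT-PCR reference-gene candidates: CPM-sum filter
  (default 500), SD/median stability score, deterministic top-N ranking.
- **profiles** — per-gene replicate mean/min/max time courses, TF-family
  heatmap matrices (RPKM values behind a CPM detectability filter), and a
  closed-form day-length model (solar declination + hour angle at −0.833°
  altitude; within ~10 min of almanac values at temperate latitudes).
- **synthetic_data** — a seeded generator for dated, replicated
  negative-binomial count matrices with planted gene classes
  (temperature-coupled, housekeeping, mid-season switch, transient peak,
  background, low) and a matching AR(1)-noise temperature series, so every
  stage is testable without external data.
- **cli / pipeline** — `budclock` command with `simulate`, `normalize`,
  `envcor`, `refgenes`, `profiles`, `heatmap` and `run` subcommands; `run`
  executes the whole pipeline from a YAML config and writes deterministic
  TSV/JSON outputs plus an auditable run report.

## Quick start

```sh
# generate a synthetic dataset (18 time points x 3 replicates)
budclock simulate --out data --seed 1

# gene set vs. temperature with a 200-draw matched null
budclock envcor --counts data/counts.tsv --samples data/samples.tsv \
    --weather data/weather.csv --annotation data/annotation.tsv \
    --keywords heat,shock --min-cpm-sum 10 --null-draws 200 --seed 1 \
    --out results/envcor

# reference-gene candidates
budclock refgenes --counts data/counts.tsv --annotation data/annotation.tsv \
    --min-cpm-sum 500 --top-n 20 --out results/refgenes.tsv

# full pipeline from a config file
budclock run --config run.yaml
```

A minimal `run.yaml`:

```yaml
counts: data/counts.tsv
samples: data/samples.tsv
weather: data/weather.csv
annotation: data/annotation.tsv
outdir: results/run
null_draws: 200
seed: 1
```

Reruns with identical config and seed produce byte-identical outputs.

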