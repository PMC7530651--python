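# txrank

Expression-based ranking of transcript isoforms across tissues, for GTEx-like
transcript-level TPM matrices. Given a GCT matrix, a sample→tissue map, and a
transcript annotation (GENCODE-style GTF or flat TSV), txrank:

- collapses samples to per-tissue mean TPM and removes never-expressed
  transcripts;
- ranks each gene's isoforms by expression — overall (cross-tissue average)
  and per tissue — with a deterministic tie-break cascade (TPM, then CDS
  length, then transcript length, then transcript ID);
- computes per-transcript fractions of gene expression, coefficient-of-
  variation scores across tissues, and summary tables (mean TPM per rank
  class, dominance by isoform-count class, per-tissue rank fractions);
- detects **rank1 switch events**: genes whose per-tissue dominant isoform
  differs from the overall rank1 isoform in some tissues, filtered by tissue
  count, CV, and rank1-fraction thresholds;
- cross-tabulates MANE-select transcripts against the computed rank classes;
- simulates GTEx-like datasets with known ground truth (skewed Dirichlet
  isoform usage, injected tissue switches, noncoding isoforms, zero rows) for
  validation and fixtures.

## CLI

```sh
# synthetic fixture bundle (GCT + annotation TSV/GTF + sample map + truth)
txrank simulate --n-genes 200 --n-tissues 54 --n-switch-genes 20 --seed 1 --out fixture/

# rank isoforms; writes download.tsv, rank_summary.tsv, dominance_by_class.tsv,
# tissue_distribution.tsv, dataset_summary.tsv and a cached rank_table/
txrank rank --gct fixture/expression.gct --annotation fixture/annotation.tsv \
    --already-collapsed --out out/

# switch events (defaults to the tissue-count window [T-4, T-1])
txrank switch --rank-dir out/rank_table --min-count 53 --max-count 53 --out switches.tsv

# MANE-select concordance
txrank mane --rank-dir out/rank_table --mane MANE.summary.txt --out concordance.tsv
```

For sample-level matrices drop `--already-collapsed` and pass
`--sample-map samples.tsv` (GTEx `SAMPID`/`SMTSD` attribute files are accepted
directly). All commands exit 0 on success, 1 on validation errors, 2 on
unexpected failures, and are deterministic for fixed inputs and seed.

## Library

```python
from txrank import (SimConfig, simulate, filter_expressed, build_rank_table,
                    detect_switch_events)

matrix, truth = simulate(SimConfig(n_genes=100, n_switch_genes=10, seed=7))
expressed, removed = filter_expressed(matrix)
table = build_rank_table(expressed, truth.annotation)
events = detect_switch_events(table, min_count=53, max_count=53)
```

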