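# progenet

A tested, reusable pipeline from differential-expression tables to
disease-genetics conclusions:

- **programs** — expression filtering (cpm ≥ 1 in ≥ 1/3 of samples),
  Bonferroni DEG calling, classification of genes into four timecourse
  transcriptional programs (early-transient / early-stable /
  early-increasing / late) by set algebra on three up-regulation sets, a
  knockout down-regulation split, and partitioning of reference sets (e.g.
  loss-of-function-intolerant genes) against program segments.
- **genesets** — ontology parent propagation (is_a/part_of), inversion into
  term → gene sets with a 20–2000 size filter, and top-fraction selection of
  genes ranked by a specificity score.
- **overrep** — Fisher's-exact over-representation against an expressed-gene
  background plus an iterative refinement loop that yields a semi-independent
  subset of enriched terms (select largest odds ratio, strip its genes from
  the other terms, re-test, Bonferroni-drop, repeat).
- **gsea** — competitive gene-set enrichment: OLS of gene-level association
  Z-scores on a set indicator with conditioning sets/covariates
  (Frisch–Waugh–Lovell-equivalent to residualize-then-regress), a
  coefficient-difference z-test, and partition-wide scans with Bonferroni
  control. Gene–gene correlation (LD) is deliberately not modeled; genes are
  treated as independent.
- **denovo** — expected de novo LoF counts from per-gene mutation rates
  (2·N·μ), and an exact two-sided Poisson rate-ratio test (conditional
  binomial, minimum-likelihood convention) of gene-set segments versus all
  other expressed genes.
- **sc_profiles** — single-cell stage profiling: cell/gene filters (5%
  rules), per-gene z-scoring, per-cell-type averages, program mean ± SEM
  profiles, paired t-tests between successive stages, and expressed-gene set
  builders.
- **synthetic** — a linked synthetic-data generator with known ground truth:
  DEG tables whose set algebra encodes true program labels, Z-scores with
  injected set effects, de novo counts with cohort-specific rate ratios, and
  a stage-labeled single-cell matrix with program-shaped profiles.
- **io_formats** — GMT, OBO (1.2 subset), headered TSV, dense-TSV/MTX cell
  matrices, JSON results bundle.
- **pipeline / cli** — one-config orchestration with deterministic,
  byte-identical re-runs.

## CLI

```sh
progenet simulate --seed 1 --outdir out          # synthetic inputs + truth
progenet run-all  --seed 1 --outdir out          # full pipeline
progenet programs --deg-dir out/inputs --out out/stage
progenet overrep  --query q.txt --terms terms.gmt --background bg.txt --out r.tsv
progenet gsea     --stats out/inputs/gene_stats.tsv --segments seg.tsv --out r.tsv
progenet denovo   --counts c.tsv --cohorts n.tsv --rates mu.tsv \
                  --segments seg.tsv --universe bg.txt --out r.tsv
progenet genesets --obo go.obo --annotations ann.tsv --out terms.gmt
progenet scprofile --matrix m.tsv --genes g.txt --cells c.txt \
                   --labels l.tsv --programs p.gmt --out out/sc
```

A YAML config (`--config`) can set every stage parameter; `--seed` and
`--outdir` override it. Logs go to stderr as key=value lines; results only
ever land in files. Re-running the same config reproduces byte-identical
result tables.

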