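# cistra

Integrative cistrome / transcriptome / clinical-outcome analysis toolkit.

`cistra` re-implements, as a tested and fully offline-reproducible pipeline,
a common integrative analysis pattern in regulatory genomics: compare
ChIP-seq peak sets across factors and cell lines, test overlap enrichment
under explicit null models, relate peaks to genes by TSS distance, derive
concordantly regulated gene sets from overexpression/knockdown expression
contrasts, join binding with regulation, and stratify patient outcome with
survival statistics. A seeded synthetic-data generator produces every input
class with planted, recoverable structure, so the whole pipeline can be
exercised and validated without any external download.

## Modules

| Module | What it does |
| --- | --- |
| `cistra.intervals` | BED 0-based half-open interval model, BED3+ I/O, merge/intersect, two-caller consensus peaks, pairwise overlap-percentage matrices, average-linkage clustering (1 − Pearson) with deterministic leaf order |
| `cistra.enrichment` | Hypergeometric tail, Benjamini–Hochberg FDR, length-preserving genomic permutation ("proximity") test with add-one p-values, region-fraction binomial test, gene-set hypergeometric |
| `cistra.annotation` | Gene-annotation TSV model (strand-aware TSS), windowed peak→gene assignment (strict `< window`), closest feature, TSS-distance profiles over `[0,5k) [5,50k) [50,500k) [500k,∞)` |
| `cistra.expression` | Quantile normalisation, moderated two-group t (fixed-prior variance shrinkage; a documented stand-in, not empirical Bayes), concordant OE-up/KD-down core sets, set-overlap summaries, signature projection with adjusted Rand index |
| `cistra.integration` | Fraction-bound summaries over a window ladder, gene-panel regulation check (bound `< 25 kb` AND concordant DE), multi-set concordance report bundle |
| `cistra.survival` | H-scores, median-unbiased (Hyndman–Fan 8) quantiles, first-quartile dichotomisation (`≤ cut` → low), Kaplan–Meier with Greenwood/log–log CIs, log-rank, maximally selected log-rank cutpoint (optional permutation-adjusted p), Cox PH with Efron ties by Newton iteration |
| `cistra.synthetic` | Seeded generators: genome/gene annotation, promoter-biased peak sets, peak sets with planted overlap fraction, expression with planted concordant effects, survival with planted hazard ratio |
| `cistra.pipeline` / `cistra.cli` | Config-driven orchestration with manifest, config-hash-stamped outputs and deterministic reruns |

## CLI

```sh
cistra simulate --seed 1 --out inputs/          # synthetic input directory
cistra overlap inputs/peaks_a.bed inputs/peaks_b.bed
cistra annotate inputs/peaks_a.bed inputs/annotation.tsv --window 50000
cistra de inputs/expression.tsv inputs/groups.tsv --condition OE
cistra survival inputs/clinical.tsv
cistra run-all --config config.yaml             # everything, serialized
cistra report run_out/                          # print the run manifest
```

The config file is a plain `key: value` mapping (YAML-compatible); see
`cistra.pipeline.RunConfig` for keys and defaults (window ladder
5/10/25/50 kb, DE threshold 0.05, integrative threshold 0.1). Exit codes:
0 ok, 2 config error, 3 data error, 4 convergence error.

## Conventions worth knowing

- All genomic coordinates are BED-style 0-based half-open; "overlap" means
  at least one shared base, so touching intervals do not overlap.
- Overlap-percentage matrices are row-oriented (percentage of the row set)
  and carry that orientation in the object to keep plots honest.
- Permutation p-values use the add-one estimator and are never zero; ties
  with the observed statistic count as exceedances.
- Every generator and every pipeline run is deterministic given its seed;
  a master seed is expanded into independent per-stream child seeds.
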