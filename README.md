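# omicweave

Integrative genomic–epigenetic subtyping pipeline for tumor cohorts. From
raw-format inputs (CNV segment tables, methylation probe matrices,
expression matrices, mutation tables, clinical tables) it builds gene-level
matrices, screens for copy-number-driven and methylation-driven gene
signatures by cis correlation, derives molecular subtypes by consensus NMF
and by joint latent-variable integrative clustering, quantifies per-sample
aberration burdens, and tests subtype associations with clinical features,
mutations and survival. A coupled multi-omics simulator with planted
structure makes every stage testable without external data.

## Modules

| module | role |
| --- | --- |
| `omicweave.omics_io` | readers/writers for SEG-like, matrix, MAF-like, clinical and annotation TSVs; shared domain types |
| `omicweave.preprocess` | CNV segment merge + gene aggregation, methylation probe filter / KNN imputation / promoter mapping, expression and mutation filters |
| `omicweave.cis_signature` | per-gene Spearman screen (CNV→expr, MET→expr), log-ratio z transform, sign-constrained signature selection |
| `omicweave.nmf_subtyping` | from-scratch multiplicative-update KL NMF, multi-restart consensus clustering, rank selection with a minimum-subclass rule |
| `omicweave.integrative_clustering` | lasso-penalized EM for a shared Gaussian latent factor model across modalities; k-means labels; lambda grid and cluster-count stability selection |
| `omicweave.aberration_burden` | per-sample Gain/Loss/MetHyper/MetHypo counts (strict thresholds 0.3 / −0.3 / 0.8 / 0.2) and burden correlations |
| `omicweave.association_survival` | chi-square contingency tests, Fisher-exact mutation spectrum with BH FDR, Kaplan–Meier + log-rank, marker reports, rank-sum DE screen |
| `omicweave.synthetic_data` | seeded generator of coupled CNV/MET/EXPR/mutation/clinical data with planted subtypes, cis drivers and hazards |

## CLI

```bash
omicweave simulate --seed 1 --out data/                 # synthetic dataset
omicweave preprocess --segments data/segments.tsv \
    --probe-beta data/probe_beta.tsv --probe-manifest data/probe_manifest.tsv \
    --expr-fpkm data/expr_fpkm.tsv --maf data/mutations.tsv \
    --annotation data/annotation.tsv --out pre/
omicweave signature --gene-cnv pre/gene_cnv.tsv --gene-met pre/gene_met.tsv \
    --expr-fpkm pre/expr_fpkm_filtered.tsv --out sig/
omicweave nmf --matrix expr_subset.tsv --k-min 2 --k-max 10 --out nmf/
omicweave icluster --cnv ... --met ... --expr ... --clusters 3 --out ic/
omicweave burden / associate / survival / markers / mutspec ...
omicweave run-all --seed 1 --out run/                   # full wiring
```

Every stage writes TSV outputs plus a JSON run manifest (parameters, seed,
timings). `run-all --quick` uses reduced clustering settings for smoke
runs.

## Conventions

- Genomic coordinates are 1-based closed intervals throughout (SEG
  convention).
- Missing methylation values are the literal TSV token `NA`.
- Promoter windows are 2 kb upstream to 200 bp downstream of the TSS in
  transcription direction (strand-aware).
- Subtype labels are ordered by decreasing cluster size (`iC1` largest).
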