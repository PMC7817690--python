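# sh2ascreen

Screening pipeline for aberrant short-H2A (sH2A) histone-variant expression
in tumor transcriptomes. Given gene-level TPM matrices, sample metadata,
gene annotation, percent-spliced-in (Psi) tables and MAF-like somatic
mutation tables, the package:

* classifies per-sample sH2A paralogue expression status
  (positive > 1.5 TPM, negative < 0.5 TPM, intermediate in between) and
  tabulates per-cancer-type reactivation frequencies and paralogue
  co-expression;
* runs group differential expression with a Mann–Whitney U rank test
  (exact enumeration-equivalent p for small tie-free groups, tie-corrected
  normal approximation otherwise), including TMM (trimmed mean of M values)
  scaling factors, paralogue fold-change concordance, cross-cancer common
  gene sets, marker-panel comparisons, X:autosome transcript ratios and
  locus-neighborhood checks;
* computes a composite cancer-testis-antigen (CTA) score per sample — the
  sum of Z-normalized log expression of the top 40 most variably expressed
  CTA genes within each cancer type — and compares it between groups;
* performs class-resolved differential splicing on Psi tables (call = one-
  sided rank test p < 0.05 AND |ΔPsi| > 0.1), with per-class tallies;
* collates recurrent protein changes pooled across histone gene classes
  (recurrent = at least 5 occurrences), cross-tabulates panel mutations
  against sH2A status, and maps recurrent canonical-H2A mutation sites onto
  variant sequences through a gapped protein alignment (e.g. the R29Q
  substitution and the C-terminal truncation removing E121 carried by
  wild-type short H2As);
* generates synthetic TCGA-like cohorts with known planted ground truth
  (log-normal TPM background, beta-distributed Psi, sparse mutations with a
  recurrent hotspot) so every stage is testable without external data.

All thresholds above are the pipeline defaults and are configurable.

## Command-line usage

Each stage writes TSV/JSON outputs plus a `provenance.json` under
`<out>/<stage>/`:

```bash
sh2ascreen simulate --seed 7 --out run/                 # synthetic cohort
sh2ascreen classify  --expr run/simulate/expression.tsv \
    --annotation run/simulate/annotation.tsv \
    --samples run/simulate/samples.tsv --out run/
sh2ascreen diffexp   --expr ... --annotation ... --out run/
sh2ascreen ctascore  --expr ... --annotation ... --samples ... --out run/
sh2ascreen splicing  --psi run/simulate/psi.tsv --expr ... --annotation ... --out run/
sh2ascreen mutations --muts run/simulate/mutations.tsv --out run/
sh2ascreen oncofeatures --out run/       # uses the packaged H2A alignment
sh2ascreen report    --run-dir run/
```

Exit codes: 0 success, 2 validation error, 64 unknown subcommand.
Thresholds can be overridden with `--config config.yaml` (see
`sh2ascreen.config.RunConfig` for keys and defaults).

## Data formats

Tab-delimited UTF-8 with header rows throughout. Expression: gene rows ×
sample columns, first column `gene_id`. Psi: `event_id`, `event_class`
(SE, RI, A3SS, A5SS, MXE, TandemUTR, AFE, ALE, constitutive), then one Psi
column per sample — an empty cell is missing, never zero. Mutations:
minimal MAF dialect (`sample_id`, `gene_symbol`, `protein_change`,
`cancer_type`; extra columns ignored). Annotation coordinates are 1-based
inclusive. Alignments are gapped FASTA of equal-length protein records.

## Notes on conventions

* Gene identity is keyed on `gene_id`; symbols are display-only.
* Log expression means log2(TPM + 1); variance/SD use ddof = 1.
* Fold changes add a 0.1 TPM pseudocount to group means.
* P-values are raw by default; Benjamini–Hochberg is available as a flag.
* The synthetic cohort's distributional choices (log-normal TPM,
  Beta(μκ, (1−μ)κ) Psi) are modeling choices of this package, documented in
  `sh2ascreen/simulate.py`.
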