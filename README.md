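# editscan

Toolkit for detecting and quantifying A-to-I RNA editing from RNA-Seq
variant calls:

- **Realignment-based artifact removal** (`editscan.raar`): realigns every
  variant-supporting read against candidate loci found by k-mer seeding,
  scores ungapped / one-indel / one-intron placements with a local
  dynamic program, and adjudicates each variant as `PASS` or a named
  artifact class (`raar_multi`, `raar_splice`, `raar_indel`,
  `raar_lowsupport`).
- **Editing quantification** (`editscan.editing_quant`): stringent site
  calling (>= 5 supporting reads and >= 5% allele frequency), paired-DNA
  filtering (DNA AF >= 5% removes), substitution spectra, editing-level
  histograms (5-point bins, window-3 smoothing), and relaxed re-retrieval
  of events at confident sites (depth >= 10, zero-level events kept).
- **Cohort statistics** (`editscan.cohort_analysis`): cross-sample
  recurrence, cohort validation (real / likely / insufficient /
  unsupported), paired t-tests with Benjamini-Hochberg FDR, per-site
  direction calls across tumor types, and per-gene direction summaries.
- **miRNA regulation** (`editscan.mir_regulation`): seed-region
  intersection, seed-complementarity re-evaluation under A->G editing
  (optional G:U wobble), editing/expression delta correlation with
  CNV-sample exclusion, correlation-group comparison, and the
  four-subtype regulatory model.
- **Synthetic data** (`editscan.synthetic_data`): seeded generators for
  every input shape (genome with paralog duplications and gene models,
  reads with planted editing and planted artifacts, paired tumor/normal
  editing matrices, expression coupled to editing at a target Pearson r),
  each with a machine-readable truth table.
- **I/O and domain types** (`editscan.core_model`): VCF (VarScan-style
  dialect, configurable), SAM/BAM, BED3-6, PSL, RADAR-style catalogs,
  FASTA, and TSV editing matrices. All internal coordinates are 0-based
  half-open.

## CLI

```sh
editscan simulate --seed 1 --outdir fx/          # seeded fixture + truth
editscan raar --vcf fx/candidates.vcf --bam fx/reads.sam \
    --ref fx/genome.fa --annotation fx/exons.bed \
    --out out.vcf --report report.tsv
editscan call --vcf sample1.vcf --vcf sample2.vcf --out sites.tsv
editscan spectrum --vcf calls.vcf --out spectrum.tsv
editscan hist --matrix fx/editing_matrix.tsv --out hist.tsv
editscan diff --matrix fx/editing_matrix.tsv --pairs fx/pairs.tsv \
    --tumor-type SIM --out diff.tsv
editscan direction --results diff.tsv --out genes.tsv
editscan mirna --sites sites.tsv --targets seeds.bed --utr utr.fa \
    --out effects.tsv
editscan correlate --editing delta_edit.tsv --expression delta_expr.tsv \
    --groups groups.tsv --out corr.tsv
```

External realignments in Blat PSL format can be supplied to
`editscan raar --psl hits.psl`; they override the internal realigner for
the reads they cover.

## Notes

- Thresholds are inclusive exactly as documented on each function
  (`>= 5` reads, `>= 5%` AF, DNA AF `>= 5%` removes, relaxed depth
  `>= 10`, validation at depth `>= 10` / alt `>= 1` / AF `>= 1%`).
- The realigner's alignment space is one or two pure-match blocks
  separated by at most one small indel (affine cost) or one intron gap
  (flat cost); scoring defaults live in
  `editscan.raar.ScoringScheme` and are fully configurable.
- Determinism: identical inputs, config and seeds produce byte-identical
  outputs everywhere.
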