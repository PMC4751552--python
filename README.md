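# editscreen

A rigorously filtered screen for mRNA editing from matched genomic-DNA
and mRNA sequencing. Given per-sample DNA and RNA alignments against
the same reference, the pipeline:

1. **detects** per-sample DNA→RNA base differences by strict allele
   counting (DNA strictly homozygous, RNA supporting exactly one
   alternative allele, ≥15× coverage on both sources, no indels,
   no triallelic sites);
2. **filters** candidates with six independent artifact filters —
   read-extremity bias, strand bias, splice-junction proximity,
   homopolymer context, simple-sequence-repeat (SSR) context, and a
   multimapping check that searches a 40 bp edited-allele consensus in
   the sample's raw DNA reads (including unaligned ones);
3. **merges** unbiased candidates per tissue, applies a
   biological-replication threshold (≥3 of 8 samples by default), and
   computes the 12-class substitution spectrum with canonical
   collapsing (A→G / T→C / C→T / G→A);
4. **localizes** retained events against gene models (coding
   missense/synonymous, noncoding exon, intron, 5 kb flanks,
   intergenic with 10 kb nearest-gene naming);
5. **quantifies** editing levels (DNA-standardized edited-allele
   fractions) and tests factor effects with a two-sided unpaired
   homoscedastic Student t-test.

A fully deterministic simulator generates matched DNA/RNA cohorts with
planted edits, genomic SNPs, paralog duplications and one site per
artifact class, together with a truth table, so the entire pipeline is
testable end-to-end without external data.

## CLI

```sh
editscreen simulate   --out-dir data --seed 101      # synthetic cohort
editscreen detect     --data-dir data --out-dir out  # candidates.tsv
editscreen filter     --data-dir data --out-dir out  # flags.tsv
editscreen replicate  --data-dir data --out-dir out  # events_<tissue>.tsv
editscreen annotate   --data-dir data --out-dir out  # localizations
editscreen report     --data-dir data --out-dir out  # full run + attrition
editscreen quantify   --levels levels.tsv --out tests.tsv
editscreen check-table2                              # published-table checks
```

A dataset directory holds `genome.fa`, `genes.gff3`,
`<sample>.dna.sam`, `<sample>.dna.fastq` and
`<sample>.<tissue>.rna.sam` (the simulator writes this layout).

## Package layout

| module                      | contents                                       |
|-----------------------------|------------------------------------------------|
| `editscreen.io_formats`     | FASTA/GFF3/SAM/FASTQ/TSV readers, per-base observation extraction |
| `editscreen.pileup`         | pileup columns, counting genotyper, candidate detection |
| `editscreen.filters`        | the six artifact filters, SSR finder, consensus builder |
| `editscreen.replication`    | event merging, replication filter, substitution spectrum |
| `editscreen.annotation`     | feature localization and coding consequences   |
| `editscreen.quantification` | editing levels and pooled t-tests              |
| `editscreen.simulate`       | truth-table-backed cohort simulator            |
| `editscreen.pipeline`       | end-to-end orchestration, attrition reporting, table checks |
| `editscreen.cli`            | `editscreen` command group                     |
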