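# troutatlas

A post-assembly toolkit for building a multi-tissue transcriptome expression
atlas from de novo assembly outputs. It implements, as tested reusable
components:

- **io_formats** — FASTA, 12-column tabular homology hit tables, 9-column
  GTF, TSV expression matrices, and the half-up percentage formatter used by
  all reports.
- **assembly_post** — contig length filtering and N50 statistics, selection
  of one representative transcript per contig component, proteome-coverage
  and reciprocal-unmatched hit-table summaries, alignment coverage tiers.
- **orf_tools** — six-frame ORF scanning and the interior-ORF full-length
  cDNA rule (an ORF that neither begins at the first base nor ends at the
  last base of its contig marks a full-length cDNA).
- **atlas** — RPKM normalization, replicate pooling, and the two
  classification rules: housekeeping (RPKM ≥ 1 in every tissue) and
  tissue-specific (one tissue ≥ 8-fold the maximum of all others).
- **complexity** — expressed-gene counts over an RPKM threshold ladder,
  cumulative abundance curves, tissue-specific mRNA fractions, and PCA
  coordinates for tissue clustering.
- **loci_compare** — two-stage novel-locus detection against a genome
  annotation (nucleotide homology, then coordinate overlap), merging of
  novel sets with redundancy removal, and alternative-splicing summaries.
- **synthgen** — a synthetic-data generator that emulates the 13-tissue
  non-normalized RNA-seq design with planted truth labels, so every stage
  has a parameter-recovery test without any real reads.

## Test

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests for the
stated invariants, and `tests/test_acceptance.py`, which checks synthetic
truth recovery, brute-force oracle equivalence on randomized instances, rule
boundaries, structural invariants, and printed-number consistency.

## CLI

All stages are exposed through one entry point:

```bash
troutatlas simulate --outdir sim/ --seed 1          # synthetic dataset + truth.json
troutatlas validate sim/contigs.fasta               # format diagnostics
troutatlas asm-stats --fasta sim/contigs.fasta --min-len 500
troutatlas select-reps --fasta sim/contigs.fasta --hits sim/hits.tsv --out reps.txt
troutatlas full-length --fasta sim/orf_contigs.fasta --out fl.tsv
troutatlas orf-scan --fasta sim/orf_contigs.fasta --min-aa 100 --out orfs.tsv
troutatlas classify --counts sim/counts.tsv --lengths sim/lengths.tsv \
    --libsizes sim/libsizes.tsv --out atlas.tsv
troutatlas complexity --rpkm rpkm.tsv --thresholds 5,1,0.5,0.1 --out table.tsv
troutatlas abundance-curve --rpkm rpkm.tsv --tissue white_muscle --out curve.tsv
troutatlas pca --rpkm rpkm.tsv --out pca.tsv
troutatlas novel-loci --predicted sim/predicted.gtf --annotated sim/annotated.gtf \
    --evalue 1e-5 --out novel.tsv
troutatlas splice-stats --gtf sim/predicted.gtf --k 2,5,10
troutatlas merge-novel --novel novel_ids.txt --contigs contig_ids.txt --pairs pairs.tsv
troutatlas coverage-tiers --aln aln.tsv --tiers 1.0,0.9,0.5
```

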