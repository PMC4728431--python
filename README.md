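# cryptomap

Proteogenomic discovery and characterization of **cryptic MHC class
I-associated peptides (MAPs)** — peptides presented at the cell surface that
are encoded outside canonical protein-coding reading frames: in 5′/3′ UTRs,
introns, UTR–exon and intron–exon junctions, antisense or intergenic
sequence, or by out-of-frame translation of exons.

The package is aimed at immunopeptidomics groups who search eluted-peptide
MS/MS data against custom sequence databases and want a complete,
desk-testable implementation of the all-frames discovery workflow: database
construction from raw RNA-seq reads, target–decoy FDR threshold selection,
genomic classification of cryptic peptides, and the downstream source-ORF,
transcript-feature and immunopeptidome statistics.

## Method

Two personalized databases are built from one subject's RNA-seq data:

* **Control database** — the canonical proteome: the subject's ns-SNVs are
  substituted into the reference genome, and every annotated protein-coding
  transcript is translated in its annotated frame.
* **All-frames database** — raw reads are translated in all six reading
  frames through a **33-bp sliding window** (step 1 nt; each window is
  translated in its own frame on both strands, which covers the six frames
  exactly once per frame-window). Products are truncated at stop codons and
  products shorter than 8 residues are dropped, so entries are 8–11-mers.
  Every peptide carries an **S-value** (*seen* count) — the number of window
  products equal to it across all reads — and only peptides with **S ≥ 10**
  are kept, which suppresses sequencing-error products.

PSMs from searches against both databases (with reversed-sequence decoys)
are filtered at a joint threshold on the search score *s* and the minimum
predicted MHC binding affinity over the subject's HLA-A/B allotypes, with

    FDR = 100 × n_decoy / n_target

evaluated on the grid of observed (score, affinity) values; the pair
admitting the most target peptides at FDR ≤ 5% is selected. Peptides
identified by both databases are **conventional** MAPs; peptides identified
only by the all-frames database are **putative cryptic** MAPs and pass a
stringent cascade: unique genomic locus (exhaustive six-frame localization),
spectrum-validation flag, unambiguous source gene (same-strand > antisense >
intergenic), region classification against the most highly expressed
isoform (5UTR, 5UTR/EXON, EXON, INTRON/EXON, INTRON, RETAINED_INTRON, 3UTR,
ANTISENSE, INTERGENIC), and reading-frame validation — in-frame exonic
products are canonical and discarded. Downstream analyses predict source
ORFs (upstream AUG in any Kozak context, else near-cognate start in an
optimal/strong context, else the first codon after the upstream stop; stop =
first in-frame stop after the peptide-coding region), scan 5′UTRs for
upstream ORFs, profile 3′UTR length/introns/stability elements, classify
codons as rare/common against a human usage table, classify SNVs by
mutate-and-translate, and compare C-terminal amino-acid-class signatures,
peptide lengths, presenting allotypes and HLA-restricted detection between
cryptic and conventional MAPs.

A fully deterministic simulator generates toy genomes with one planted
peptide per category plus two decoys (a multi-locus peptide and an in-frame
canonical peptide reported only by the all-frames search), so the entire
pipeline is testable offline against an exact truth table.

## Worked example

```sh
cryptomap simulate --seed 7 -o fx
cryptomap run --genome fx/genome.fa --gtf fx/annot.gtf --variants fx/vars.vcf \
    --reads fx/reads.fq --psms fx/psms.tsv --affinities fx/aff.tsv \
    --fpkm fx/expr.tsv \
    --alleles "HLA-A*03:01,HLA-A*29:02,HLA-B*08:01,HLA-B*44:03" -o out
```

prints the run manifest:

```json
{
  "fdr_percent": 0.0,
  "n_allframes_db_peptides": 16470,
  "n_allframes_identified": 12,
  "n_control_db_proteins": 14,
  "n_conventional": 1,
  "n_discarded_by_reason": {"frame_conventional": 1, "multi_locus": 1},
  "n_putative_cryptic": 11,
  "n_validated_cryptic": 9,
  "thresholds": {"ic50_max_nM": 408.05, "score_min": 35.81}
}
```

Reading: 12 peptides passed the FDR filter against the all-frames database;
1 was shared with the control database (conventional); of the 11 putative
cryptic peptides, 9 were validated — one per planted category — and the two
planted decoys were discarded for the right reasons (the bookkeeping always
reconciles: 11 = 9 + 2). `out/maps.tsv` lists each validated peptide with
its category, source gene/transcript, locus and reading frame:

```text
peptide      kind     cryptic_status  gene     transcript  contig  blocks       strand  reading_frame
CEYQVFRILAP  cryptic  3UTR            GENE007  TX007.1     chrS    9231-9264    -       none
HGRGYKLMNNM  cryptic  EXON            GENE003  TX003.1     chrS    3444-3477    -       out
TQEMGYVEMWT  cryptic  ANTISENSE       GENE008              chrS    10751-10784  -       n/a
```

Per-stage subcommands (`build-control-db`, `build-allframes-db`,
`fdr-filter`, `classify`, `orf`, `uorf`, `utr3`, `codons`, `signature`,
`lengths`, `allotypes`) expose the same stages on user-supplied files.

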