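# Methods

## Model and procedure

The workflow identifies MHC class I-associated peptides (MAPs) that arise
from non-canonical translation. Its central idea is to search eluted-peptide
MS/MS data against a peptide database built directly from raw RNA-seq reads
— without alignment — so that any translated sequence expressed in the cell,
canonical or not, can be matched.

**All-frames database.** Each read is processed with a 33-bp window sliding
1 nt at a time; the window is translated in its own frame on the forward
sequence and on the reverse complement of the window. Because the window
length is a multiple of 3, the 1-nt slide realizes each of the six reading
frames exactly once per frame-aligned window position; this is the only
stepping under which "six frames" and "33-bp sliding window" are
simultaneously satisfied with no frame missed. Translation stops at the
first stop codon and emits the prefix (suffix products are produced anyway
by later windows); products shorter than 8 residues are dropped, so entries
are 8–11-mers, with 8–10-mers present only as stop-truncated products.
Shorter peptides remain reachable by a no-enzyme search as subsequences of
11-mer entries. Windows containing N are skipped; reads shorter than 33 bp
are skipped whole; duplicate reads count (the S-value is a raw seen-count,
and a per-read-unique mode is available behind `unique_per_read`). The
S ≥ 10 retention gate is the database's error filter: at a per-base error
rate e, a window survives intact with probability (1−e)^33, so genuine
peptides retain roughly half their coverage-proportional S-value at e = 0.02
while error-derived peptides stay near S = 1.

**Control database.** ns-SNVs (single-nucleotide only; the upstream caller's
quality filtering is an input contract, with an optional extra quality gate
defaulting to 0) are substituted into the reference genome, and every
annotated coding transcript is translated in its annotated frame; internal
stops truncate with a warning rather than fail, since annotation end-phase
defects occur in real GTFs.

**FDR filtering.** PSMs are collapsed to the best score per (peptide,
database, decoy-flag) — peptide-level counting matches how MAP repertoires
are reported — and a peptide's affinity is the minimum predicted IC50 over
the subject's HLA-A/B allotypes (binding one allotype suffices). FDR =
100 × decoys/targets among records passing a joint (score ≥ s, IC50 ≤ a)
threshold; the grid searched is the set of observed scores × observed
per-peptide minimum affinities (a continuous grid cannot change the admitted
sets). Ties on the admitted-target count break toward lower FDR, then lower
score cut, then higher affinity cut (the most permissive admissible pair).
With no admissible pair the optimizer raises rather than silently relaxing.
The FDR re-evaluated per database at the chosen pair is reported in the
manifest but never used as a gate, since decoy FDR inflates with database
size. Threshold optimization here runs on the pooled PSM set; with separate
decoy populations per search the same machinery applies per database.

**Classification cascade.** Each putative cryptic peptide (all-frames-only)
is located by exhaustively scanning the six frame translations of the genome
for the peptide as an amino-acid substring (equivalent to searching every
nucleotide encoding at once; spliced loci can instead be supplied as BED12
alignment blocks). Multi-locus peptides, spectrum-unvalidated peptides
(optional input flag, defaulting to validated), and peptides overlapping
more than one same-strand gene are discarded — the multi-gene rule is the
stringent reading of "unambiguously assigned to a single gene". Same-strand
overlap takes precedence over antisense, which takes precedence over
intergenic. The source isoform is the most highly expressed (FPKM > 0)
isoform of the gene, ties to the smallest transcript id, falling back to the
longest isoform with a warning. Region status comes from per-base labels of
the PCR against that isoform: junction statuses require ≥ 1 nt on each side
of the boundary; a PCR spanning the CDS/3′UTR boundary is grouped with 3UTR
(the product reads through the canonical stop, so it is non-canonical from
the stop onward); RETAINED_INTRON requires a retained_intron-biotype
isoform and a PCR inside the segment that is intronic in its sibling
isoforms. Exonic statuses then undergo frame validation: a peptide is "in"
frame only when it lies fully inside exonic CDS, its transcript-coordinate
offset from the CDS start is divisible by 3, and the canonical CDS
translation reproduces it — such peptides are canonical and discarded from
the cryptic path. Every input peptide ends as exactly one record or one
discard; the manifest asserts this.

**Source-ORF prediction.** Within the in-frame window bounded by the nearest
upstream stop codon, the start codon is (i) the 5′-most AUG in any Kozak
context, else (ii) the 5′-most near-cognate codon (the nine single-nt
neighbours of AUG) in an optimal (GCC[A/G]CC·start·G) or strong
([A/G]NN·start·G) context, else (iii) the first codon of the window. The
5′-most (not nearest) qualifying codon maximizes ORF length, consistent
with scanning-model initiation. The trailing "[V]" in the published Kozak
patterns is treated as annotation noise: both patterns require +4 = G
(classical Kozak); the optimal pattern additionally needs the
GCC[A/G]CC −6..−1 context, and contexts with fewer than 6 nt upstream or no
+4 base are classed weak with an insufficient-context flag. The stop is the
first in-frame stop after the PCR; the initiator is reported verbatim but
decoded as methionine in the protein (initiator-tRNA decoding), so a
CUG-initiated protein still begins with M. For peptides without a source
transcript (antisense, intronic, intergenic) the prediction runs on a
750-bp genomic flank per side of the PCR, reading the PCR's strand; the
per-side reading of the flank length is the permissive choice and is
configurable via `FLANK_BP`. Upstream-ORF scanning accepts only AUGs in
optimal or strong context starting in the 5′UTR, each extended to its first
in-frame stop; a stop ending at or before the CDS start makes the uORF
contained, otherwise it spans the 5′UTR–exon junction.

**Transcript features and statistics.** 3′UTR length counts exonic UTR
nucleotides; the intron count is the number of annotated introns entirely
within the 3′UTR span. Stability-element scans count all exact motif
occurrences including overlaps (occurrence counting is the simplest reading
of "number of elements"; counts are additive over disjoint motif sets,
which a distinct-type count would not be). The bundled motif list
(`data/utr_elements_toy.tsv`) is a small toy catalogue for tests, not the
published element compendium — users supply their own TSV for real
analyses. Codons are rare when their within-family usage fraction is below
1/family-size and common when above; exact ties (AUG, UGG, and any codon at
exactly the uniform expectation) go to common, the convention under which
the bundled human usage table (Kazusa per-thousand frequencies,
`data/codon_usage_human.tsv`) partitions the 64 codons into 30 rare and 34
common; stop codons form a 3-member family. SNVs in peptide-coding regions
are classified by substituting the alt allele strand-aware, re-translating,
and comparing with the original peptide; per-group ns-SNV densities
deduplicate base pairs shared by overlapping PCRs. Group comparisons use
the two-sided Wilcoxon rank-sum test (lengths, expression), one-sided
rank-sum (element counts, expecting cryptic > conventional), and the
two-sided Fisher exact test for 2×2 tables, with the odds ratio
Haldane-corrected (+0.5 per cell, reporting only) when a cell is zero.
C-terminal signatures compare amino-acid-class usage (hydrophobic/polar ×
large/small-medium; the default residue grouping is an editable
configuration, since published groupings vary) at peptide positions P4–P1
and source-protein positions P1′–P4′; proteins ending at the peptide's C
terminus contribute to P4–P1 only. HLA restriction crosses detection of
each index-subject peptide in the other subjects with carriage of its
presenting allotype, pooled over HLA-A and -B; promiscuous binders are
called at minimum IC50 ≤ 5,000 nM (inclusive).

## Synthetic data

The simulator emulates the workflow's inputs at desk scale: one ~20-kb
contig with ~14 genes (5′UTR 220–320 nt, CDS 70–110 codons, 3′UTR 260–420
nt, 0–2 introns of 120–260 nt with GT..AG ends, both strands), FPKM values
(planted genes 8–30, baseline depth 20 at FPKM 10), substitution-error-only
reads of 100 nt tiling each expressed pre-mRNA (plus the reverse complement
for antisense-carrying genes and windows around intergenic plants), and
search-engine-like PSM/affinity tables. One 11-mer is planted per cryptic
category with the geometry that defines it (e.g. a +1 codon offset inside
the CDS for out-of-frame exonic; 13 nt on the 5′ side of the relevant
boundary for junction categories), plus a conventional in-frame peptide,
a two-locus decoy and an in-frame decoy reported only by the all-frames
search. The 5′UTR plant carries a constructed upstream context (stop,
optimal-context AUG, in-frame stop after the PCR) so the ORF prediction has
an exact planted answer. Reference and personalized genomes differ at two
ns-SNVs backed out of the personalized sequence, so variant application is
exactly invertible. Correct-target scores are Normal(55, 10), incorrect
targets and decoys share Normal(25, 10) and one affinity distribution
(symmetric contamination), which is what makes the decoy-based FDR estimate
comparable to the realized false rate; planted binders receive one allele
with IC50 ≤ 1,200 nM. All outputs are bit-reproducible under a fixed seed.

What the simulator does not emulate: alignment artefacts, GC/positional
coverage bias, base-quality structure, indels (substitution-only errors
keep frame semantics clean), isoform diversity beyond the retained-intron
pair, and real search-engine score semantics. Passing tests therefore
demonstrate algorithmic correctness on ideal-geometry inputs, not
performance on real MS or RNA-seq data.

## Numerical and design choices

* Coordinates are 0-based half-open internally everywhere; GTF and VCF are
  converted on read and back on write, BED is native.
* Database FASTA headers (`pep|SEQ|S=n`, decoys `rev_pep|...`) make
  target/decoy provenance and S-values parseable without sidecar files;
  output order is lexicographic, so builds are invariant to read order.
* The threshold-grid search is evaluated with cumulative 2-D count arrays
  (exact, no sampling); anti-monotonicity of the pass set is a tested
  invariant.
* Codon-usage ties use a 1e-9 absolute tolerance; exact-test p-values are
  scipy's hypergeometric implementation, cross-checked in tests against
  full enumeration for all 2×2 tables with margins ≤ 15.
* Degenerate inputs: empty read sets build an empty database with a
  warning; a peptide with no genomic locus is an explicit error record;
  genes without expressed isoforms fall back to the longest transcript;
  FDR with zero targets is NaN and fails any ≤ bound.
* Problem sizes in the test suite and acceptance script (one planted
  peptide per category at depth 20; 500-PSM calibration over 20 replicates;
  1,000-read and 500-context oracle checks) were chosen as the smallest
  sizes at which every category geometry and the calibration statistics are
  exercised meaningfully.

## Known limitations

Full-scale reproduction of a real subject requires external inputs the
package deliberately treats as upstream contracts: aligned coverage and
FPKM quantification, SNP calling, NetMHC-class affinity predictions and
the MS search itself. Spliced peptide-coding regions are only located via
supplied alignments (the exhaustive scanner finds contiguous encodings);
fusion or trans-spliced PCRs are out of scope. The positional-bias analysis
excludes antisense peptides (no annotated source transcript), and the
simulator plants single-exon-contiguous loci only.
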