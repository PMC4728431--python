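"""Locating peptide-coding regions (PCRs) and classifying cryptic peptides.

A PCR is the genomic nucleotide stretch (possibly spliced) encoding one
MHC-associated peptide.  Putative cryptic peptides flow through a fixed
filtering cascade: unique genomic locus -> spectrum validation flag ->
unambiguous source gene (same-strand beats antisense beats intergenic) ->
region classification against the most highly expressed isoform -> reading
frame validation for exonic peptides (in-frame products are canonical and
discarded from the cryptic path).  Every input peptide ends as exactly one
MapRecord or one DiscardRecord.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .database_build import translate
from .formats_io import (Genome, TranscriptModel, derive_transcript_regions,
                         reverse_complement)

log = logging.getLogger("cryptomap")

CRYPTIC_STATUSES = ("5UTR", "5UTR/EXON", "EXON", "INTRON/EXON", "INTRON",
                    "RETAINED_INTRON", "3UTR", "ANTISENSE", "INTERGENIC")
DISCARD_REASONS = ("multi_locus", "multi_gene", "frame_conventional",
                   "unvalidated_spectrum")


class UnlocatablePeptide(ValueError):
    """Peptide with no exact coding occurrence in the genome."""


class ConsistencyError(RuntimeError):
    """Internal invariant broken (e.g. PCR not overlapping its transcript)."""


@dataclass(frozen=True)
class PcrLocus:
    contig: str
    blocks: tuple[tuple[int, int], ...]     # 0-based half-open, genomic order
    strand: str
    nt_sequence: str                        # 5'->3', translates to the peptide

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def genomic_positions(self) -> list[int]:
        """Genomic positions in 5'->3' (reading) order."""
        pos = [p for s, e in self.blocks for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]


@dataclass(frozen=True)
class MapRecord:
    peptide: str
    kind: str                                # {conventional, cryptic}
    locus: PcrLocus
    cryptic_status: Optional[str] = None
    source_gene_id: Optional[str] = None
    source_transcript_id: Optional[str] = None
    reading_frame: str = "n/a"               # {in, out, none, n/a}


@dataclass(frozen=True)
class DiscardRecord:
    peptide: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in DISCARD_REASONS:
            raise ValueError(f"unknown discard reason {self.reason!r}")


# ---------------------------------------------------------------------------
# PCR location
# ---------------------------------------------------------------------------

class GenomeScanner:
    """Exhaustive six-frame scanner for exact peptide encodings.

    Each contig is translated once per strand and frame; peptides are then
    located by amino-acid substring search, which is equivalent to searching
    all nucleotide encodings at once.
    """

    def __init__(self, genome: Genome):
        self.genome = genome
        self._frames: list[tuple[str, str, int, str, int]] = []
        for contig, seq in genome.items():
            rc = reverse_complement(seq)
            for f in range(3):
                self._frames.append((contig, "+", f, translate(seq[f:]), len(seq)))
                self._frames.append((contig, "-", f, translate(rc[f:]), len(seq)))

    def locate(self, peptide: str) -> list[PcrLocus]:
        loci: list[PcrLocus] = []
        for contig, strand, f, protein, clen in self._frames:
            start = protein.find(peptide)
            while start >= 0:
                nt_start = f + 3 * start
                nt_end = nt_start + 3 * len(peptide)
                if strand == "+":
                    block = (nt_start, nt_end)
                else:
                    block = (clen - nt_end, clen - nt_start)
                seq = self.genome[contig][block[0]:block[1]]
                if strand == "-":
                    seq = reverse_complement(seq)
                loci.append(PcrLocus(contig=contig, blocks=(block,),
                                     strand=strand, nt_sequence=seq))
                start = protein.find(peptide, start + 1)
        return loci


def locate_pcr(peptide: str, genome: Genome | GenomeScanner,
               alignments: Optional[Sequence[tuple[str, str, list[tuple[int, int]]]]] = None
               ) -> list[PcrLocus]:
    """All genomic loci whose six-frame translation encodes the peptide.

    Without alignments, the genome is scanned exhaustively (desk-scale
    path).  With spliced alignments (BED12 blocks), loci are taken from the
    alignment block structure instead; blocks whose translation does not
    match the peptide are ignored, and duplicate loci are merged.
    """
    scanner = genome if isinstance(genome, GenomeScanner) else GenomeScanner(genome)
    if alignments is None:
        loci = scanner.locate(peptide)
    else:
        loci = []
        for contig, strand, blocks in alignments:
            seq = "".join(scanner.genome[contig][s:e] for s, e in blocks)
            if strand == "-":
                seq = reverse_complement(seq)
            if len(seq) == 3 * len(peptide) and translate(seq) == peptide:
                loci.append(PcrLocus(contig=contig, blocks=tuple(blocks),
                                     strand=strand, nt_sequence=seq))
    unique: dict[tuple, PcrLocus] = {}
    for locus in loci:
        unique[(locus.contig, locus.strand, locus.blocks)] = locus
    if not unique:
        raise UnlocatablePeptide(f"peptide {peptide} has no genomic locus")
    return list(unique.values())


def filter_unique_locus(peptide: str, loci: Sequence[PcrLocus]
                        ) -> PcrLocus | DiscardRecord:
    """Keep peptides with a single genomic locus; discard multi-mappers."""
    distinct = {(l.contig, l.strand, l.blocks) for l in loci}
    if len(distinct) > 1:
        return DiscardRecord(peptide=peptide, reason="multi_locus")
    return loci[0]


# ---------------------------------------------------------------------------
# Source gene / isoform assignment
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval index of gene spans (union of each gene's transcripts)."""

    def __init__(self, annotations: Iterable[TranscriptModel]):
        self.transcripts_by_gene: dict[str, list[TranscriptModel]] = {}
        spans: dict[str, tuple[str, str, int, int]] = {}
        for m in annotations:
            self.transcripts_by_gene.setdefault(m.gene_id, []).append(m)
            s, e = m.span
            if m.gene_id in spans:
                contig, strand, s0, e0 = spans[m.gene_id]
                spans[m.gene_id] = (contig, strand, min(s0, s), max(e0, e))
            else:
                spans[m.gene_id] = (m.contig, m.strand, s, e)
        self._trees: dict[str, IntervalTree] = {}
        for gid, (contig, strand, s, e) in spans.items():
            self._trees.setdefault(contig, IntervalTree()).addi(s, e, (gid, strand))

    def overlapping_genes(self, contig: str, start: int, end: int
                          ) -> list[tuple[str, str]]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})


def assign_source_gene(locus: PcrLocus, index: GeneIndex | Iterable[TranscriptModel]
                       ) -> tuple[str, Optional[str]]:
    """(category, gene_id) for a validated unique locus.

    Returns ("gene", id) for exactly one same-strand overlapping gene,
    ("multi_gene", None) for several, ("antisense", id) when only
    opposite-strand genes overlap, ("intergenic", None) for none.
    """
    if not isinstance(index, GeneIndex):
        index = GeneIndex(index)
    hits = index.overlapping_genes(locus.contig, locus.start, locus.end)
    same = [gid for gid, strand in hits if strand == locus.strand]
    if len(same) == 1:
        return "gene", same[0]
    if len(same) > 1:
        return "multi_gene", None
    opposite = [gid for gid, strand in hits if strand != locus.strand]
    if opposite:
        return "antisense", opposite[0]
    return "intergenic", None


def select_source_isoform(gene_id: str, index: GeneIndex | Iterable[TranscriptModel],
                          expression: dict[str, float]) -> TranscriptModel:
    """Most highly expressed isoform (FPKM > 0) of a gene.

    Ties go to the lexicographically smallest transcript_id; with no
    expressed isoform the longest transcript is used with a warning.
    """
    if not isinstance(index, GeneIndex):
        index = GeneIndex(index)
    transcripts = index.transcripts_by_gene[gene_id]
    expressed = [t for t in transcripts
                 if expression.get(t.transcript_id, 0.0) > 0.0]
    if expressed:
        return min(expressed, key=lambda t: (-expression[t.transcript_id],
                                             t.transcript_id))
    log.warning("gene %s: no expressed isoform, falling back to longest", gene_id)
    return min(transcripts, key=lambda t: (-t.length, t.transcript_id))


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------

def _base_label(transcript: TranscriptModel, gpos: int) -> Optional[str]:
    """Label one genomic base relative to a transcript, or None outside it."""
    s0, e0 = transcript.span
    if not (s0 <= gpos < e0):
        return None
    exonic = any(s <= gpos < e for s, e in transcript.exons)
    if not exonic:
        return "intron"
    if transcript.cds_span is None:
        return "ncexon"
    cs, ce = transcript.cds_span
    if cs <= gpos < ce:
        return "CDS"
    if gpos < cs:
        return "5UTR" if transcript.strand == "+" else "3UTR"
    return "3UTR" if transcript.strand == "+" else "5UTR"


def _retained_segment(transcript: TranscriptModel,
                      siblings: Iterable[TranscriptModel]) -> list[tuple[int, int]]:
    """Exonic stretches of a retained_intron isoform lying in sibling introns."""
    segments = []
    for s, e in transcript.exons:
        for sib in siblings:
            if sib.transcript_id == transcript.transcript_id:
                continue
            for a, b in sib.introns():
                lo, hi = max(s, a), min(e, b)
                if lo < hi:
                    segments.append((lo, hi))
    return segments


def classify_region(locus: PcrLocus, transcript: TranscriptModel,
                    siblings: Iterable[TranscriptModel] = ()) -> str:
    """Cryptic status of a PCR relative to its (same-strand) source isoform.

    Junction statuses require at least 1 nt on each side of the boundary.
    A PCR spanning the CDS/3'UTR boundary is grouped with 3UTR (the product
    reads through the canonical stop and is non-canonical from there on).
    """
    positions = [p for s, e in locus.blocks for p in range(s, e)]
    labels = {_base_label(transcript, p) for p in positions}
    labels.discard(None)
    if not labels:
        raise ConsistencyError("PCR does not overlap its assigned transcript")
    if "intron" in labels:
        if labels - {"intron"}:
            return "INTRON/EXON"
        return "INTRON"
    if "ncexon" in labels:
        if transcript.biotype == "retained_intron":
            retained = _retained_segment(transcript, siblings)
            if all(any(a <= p < b for a, b in retained) for p in positions):
                return "RETAINED_INTRON"
        return "EXON"
    if "5UTR" in labels:
        return "5UTR/EXON" if "CDS" in labels else "5UTR"
    if "3UTR" in labels:
        return "3UTR"
    return "EXON"


def validate_reading_frame(locus: PcrLocus, transcript: TranscriptModel,
                           genome: Genome,
                           status: Optional[str] = None) -> str:
    """"in" iff the PCR is a canonical in-frame CDS product of the transcript.

    Requires: all PCR bases inside exonic CDS, transcript-coordinate offset
    from the CDS start divisible by 3, and the canonical translation of that
    CDS stretch equal to the peptide.  Statuses outside the exonic set
    return "none" (frame is meaningless there).
    """
    if status is not None and status not in ("EXON", "5UTR/EXON", "INTRON/EXON"):
        return "none"
    if transcript.cds_span is None:
        return "out"
    regions = derive_transcript_regions(transcript)
    cds_tx = regions["CDS"]
    positions = locus.genomic_positions()
    try:
        tx_positions = [transcript.genomic_to_transcript(p) for p in positions]
    except Exception:
        return "out"                       # some PCR base is not exonic
    tx_start = tx_positions[0]
    if tx_positions != list(range(tx_start, tx_start + len(positions))):
        return "out"                       # not contiguous in the transcript
    if tx_start < cds_tx[0] or tx_positions[-1] >= cds_tx[1]:
        return "out"
    if (tx_start - cds_tx[0]) % 3 != 0:
        return "out"
    from .database_build import cds_sequence   # local import, avoids cycle
    protein = translate(cds_sequence(genome, transcript))
    i = (tx_start - cds_tx[0]) // 3
    peptide = translate(locus.nt_sequence)
    return "in" if protein[i:i + len(peptide)] == peptide else "out"


# ---------------------------------------------------------------------------
# Coverage and positional bias
# ---------------------------------------------------------------------------

def pcr_coverage(locus: PcrLocus,
                 read_alignments: Iterable[tuple[str, int, int, str, str]]) -> int:
    """Number of reads overlapping any PCR block by >= 1 bp (half-open)."""
    count = 0
    for contig, start, end, _name, _strand in read_alignments:
        if contig != locus.contig:
            continue
        if any(max(start, s) < min(end, e) for s, e in locus.blocks):
            count += 1
    return count


def positional_bias(record: MapRecord, transcript: TranscriptModel
                    ) -> Optional[float]:
    """Normalized transcript-coordinate start of the PCR, in [0, 1].

    Intergenic, intronic and antisense peptides carry no source-transcript
    coordinate system and are skipped (None).  For junction PCRs whose
    5'-most base is intronic, the first exonic PCR base is used.
    """
    if record.cryptic_status in ("INTERGENIC", "INTRON", "ANTISENSE"):
        return None
    for gpos in record.locus.genomic_positions():
        if any(s <= gpos < e for s, e in transcript.exons):
            return transcript.genomic_to_transcript(gpos) / transcript.length
    return None


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def classify_peptides(peptides: Iterable[str], genome: Genome,
                      annotations: Sequence[TranscriptModel],
                      expression: dict[str, float],
                      kind: str = "cryptic",
                      alignments: Optional[dict[str, list]] = None,
                      validated: Optional[dict[str, bool]] = None
                      ) -> tuple[list[MapRecord], list[DiscardRecord]]:
    """Run the full filtering cascade over a set of accepted peptides.

    ``kind`` is "cryptic" for the all-frames-only peptides (full cascade) or
    "conventional" for peptides shared with the control database (locus and
    gene assignment only; no cryptic status).  ``alignments`` optionally
    maps peptide -> BED12 block tuples; ``validated`` carries the manual
    spectrum-validation flag (missing peptides default to validated).
    """
    scanner = GenomeScanner(genome)
    index = GeneIndex(annotations)
    maps: list[MapRecord] = []
    discards: list[DiscardRecord] = []

    for peptide in sorted(set(peptides)):
        loci = locate_pcr(peptide, scanner,
                          alignments.get(peptide) if alignments else None)
        result = filter_unique_locus(peptide, loci)
        if isinstance(result, DiscardRecord):
            discards.append(result)
            continue
        locus = result
        if validated is not None and not validated.get(peptide, True):
            discards.append(DiscardRecord(peptide, "unvalidated_spectrum"))
            continue
        category, gene_id = assign_source_gene(locus, index)
        if category == "multi_gene":
            discards.append(DiscardRecord(peptide, "multi_gene"))
            continue
        if category == "antisense":
            maps.append(MapRecord(peptide=peptide, kind=kind, locus=locus,
                                  cryptic_status="ANTISENSE" if kind == "cryptic" else None,
                                  source_gene_id=gene_id, reading_frame="n/a"))
            continue
        if category == "intergenic":
            maps.append(MapRecord(peptide=peptide, kind=kind, locus=locus,
                                  cryptic_status="INTERGENIC" if kind == "cryptic" else None,
                                  reading_frame="n/a"))
            continue
        transcript = select_source_isoform(gene_id, index, expression)
        siblings = index.transcripts_by_gene[gene_id]
        if kind == "conventional":
            maps.append(MapRecord(peptide=peptide, kind="conventional",
                                  locus=locus, source_gene_id=gene_id,
                                  source_transcript_id=transcript.transcript_id,
                                  reading_frame="in"))
            continue
        status = classify_region(locus, transcript, siblings)
        frame = validate_reading_frame(locus, transcript, genome, status)
        if frame == "in":
            discards.append(DiscardRecord(peptide, "frame_conventional"))
            continue
        maps.append(MapRecord(peptide=peptide, kind="cryptic", locus=locus,
                              cryptic_status=status, source_gene_id=gene_id,
                              source_transcript_id=transcript.transcript_id,
                              reading_frame=frame))
    return maps, discards
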