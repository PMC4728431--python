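"""Readers, writers and coordinate plumbing for all external formats.

All coordinates are held internally as 0-based half-open intervals on the
forward genomic strand.  GTF (1-based inclusive) and VCF (1-based) positions
are converted on read and back-converted on write; BED is native.

The transcript container is :class:`TranscriptModel`: a strand-aware list of
exon intervals plus an optional CDS span, from which the 5'UTR/CDS/3'UTR
partition in transcript coordinates is derived.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("cryptomap")

NUCLEOTIDES = set("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed record in an external file (carries line context)."""


class CoordinateError(ValueError):
    """Interval outside the bounds of its contig or transcript."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Genome(dict):
    """Mapping of contig name -> uppercase nucleotide string over {A,C,G,T,N}."""

    def __setitem__(self, name: str, sequence: str) -> None:
        if not sequence:
            raise ValueError(f"contig {name!r}: empty sequence")
        sequence = sequence.upper()
        bad = set(sequence) - NUCLEOTIDES
        if bad:
            raise ValueError(f"contig {name!r}: illegal characters {sorted(bad)}")
        if name in self:
            raise ValueError(f"duplicate contig name {name!r}")
        super().__setitem__(name, sequence)


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide variant, position 0-based internally."""

    contig: str
    position: int          # 0-based
    ref_allele: str
    alt_allele: str
    identifier: str = "."
    quality: float = 0.0

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"variant {self.identifier}: single-nucleotide only")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.identifier}: ref equals alt")
        if self.quality < 0:
            raise ValueError(f"variant {self.identifier}: negative quality")


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` are genomic ``(start, end)`` intervals, 0-based half-open,
    sorted by genomic start and non-overlapping.  ``cds_span`` covers the
    genomic stretch from the start codon to the end of the stop codon.
    """

    transcript_id: str
    gene_id: str
    gene_name: str = ""
    biotype: str = "unknown"
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    contig: str = ""
    cds_span: Optional[tuple[int, int]] = None
    fpkm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    def introns(self) -> list[tuple[int, int]]:
        return [(a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])]

    # -- coordinate conversion ------------------------------------------------

    def genomic_to_transcript(self, gpos: int) -> int:
        """Transcript coordinate (5'->3') of a genomic position inside an exon."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos < e:
                fwd = offset + (gpos - s)
                return fwd if self.strand == "+" else self.length - 1 - fwd
            offset += e - s
        raise CoordinateError(
            f"{self.transcript_id}: genomic position {gpos} not exonic")

    def exonic_positions(self) -> list[int]:
        """Genomic positions of transcript bases in transcript (5'->3') order."""
        pos = [p for s, e in self.exons for p in range(s, e)]
        return pos if self.strand == "+" else pos[::-1]


@dataclass(frozen=True)
class PsmRecord:
    peptide: str
    score: float
    database: str            # {control, allframes, both}
    is_decoy: bool
    modifications: str = ""

    def __post_init__(self) -> None:
        if len(self.peptide) < 1:
            raise ValueError("empty peptide")
        if self.score < 0:
            raise ValueError(f"{self.peptide}: negative score")
        if self.database not in {"control", "allframes", "both"}:
            raise ValueError(f"{self.peptide}: bad database {self.database!r}")


@dataclass(frozen=True)
class AffinityRecord:
    peptide: str
    allele: str
    ic50_nM: float

    def __post_init__(self) -> None:
        if self.ic50_nM <= 0:
            raise ValueError(f"{self.peptide}/{self.allele}: IC50 must be > 0")


@dataclass(frozen=True)
class PeptideDbEntry:
    sequence: str
    s_value: int

    def __post_init__(self) -> None:
        if self.s_value < 1:
            raise ValueError(f"{self.sequence}: S-value must be >= 1")


# ---------------------------------------------------------------------------
# FASTA genome
# ---------------------------------------------------------------------------

def read_genome(path_or_handle) -> Genome:
    genome = Genome()
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        genome[rec.id] = str(rec.seq)
    return genome


def write_genome(genome: Genome, handle) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------------------
# GTF (Ensembl dialect)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(text))
    if not attrs:
        raise FormatError(f"GTF line {lineno}: malformed attribute field {text!r}")
    return attrs


def parse_annotations(lines: Iterable[str]) -> list[TranscriptModel]:
    """Parse Ensembl-dialect GTF text lines into :class:`TranscriptModel`.

    1-based inclusive GTF coordinates become 0-based half-open.  A transcript
    whose CDS falls outside its exon union is excluded with a warning.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    order: list[str] = []

    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"GTF line {lineno}: expected 9 fields, got {len(fields)}")
        contig, _source, feature, start, end, _score, strand, _frame, attr_text = fields
        if feature not in ("exon", "CDS"):
            continue
        attrs = _parse_attributes(attr_text, lineno)
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id")
        if tid is None or gid is None:
            raise FormatError(
                f"GTF line {lineno}: {feature} lacks transcript_id/gene_id")
        try:
            iv = (int(start) - 1, int(end))   # 1-based inclusive -> 0-based half-open
        except ValueError as exc:
            raise FormatError(f"GTF line {lineno}: bad coordinates") from exc
        if tid not in meta:
            order.append(tid)
            meta[tid] = {
                "gene_id": gid,
                "gene_name": attrs.get("gene_name", gid),
                "biotype": attrs.get("transcript_biotype",
                                     attrs.get("gene_biotype", "unknown")),
                "strand": strand,
                "contig": contig,
            }
        (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    models: list[TranscriptModel] = []
    for tid in order:
        m = meta[tid]
        tx_exons = sorted(exons.get(tid, []))
        cds_span = None
        if tid in cds:
            ivs = sorted(cds[tid])
            cds_span = (ivs[0][0], ivs[-1][1])
            covered = all(any(s <= a and b <= e for s, e in tx_exons)
                          for a, b in ivs)
            if not covered:
                log.warning("transcript %s: CDS outside exon union, excluded", tid)
                continue
        models.append(TranscriptModel(
            transcript_id=tid, gene_id=m["gene_id"], gene_name=m["gene_name"],
            biotype=m["biotype"], strand=m["strand"], contig=m["contig"],
            exons=tx_exons, cds_span=cds_span))
    return models


def write_annotations(models: Sequence[TranscriptModel], handle) -> None:
    """Write models back as Ensembl-dialect GTF (exact round-trip partner)."""
    for m in models:
        attrs = (f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                 f'gene_name "{m.gene_name}"; gene_biotype "{m.biotype}"; '
                 f'transcript_biotype "{m.biotype}";')
        for s, e in m.exons:
            handle.write("\t".join([m.contig, "cryptomap", "exon",
                                    str(s + 1), str(e), ".", m.strand, ".",
                                    attrs]) + "\n")
        if m.cds_span is not None:
            cs, ce = m.cds_span
            for s, e in m.exons:
                a, b = max(s, cs), min(e, ce)
                if a < b:
                    handle.write("\t".join([m.contig, "cryptomap", "CDS",
                                            str(a + 1), str(b), ".", m.strand,
                                            ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# Transcript-relative regions
# ---------------------------------------------------------------------------

def derive_transcript_regions(model: TranscriptModel) -> dict[str, tuple[int, int]]:
    """5'UTR/CDS/3'UTR intervals in transcript coordinates (5'->3').

    On the minus strand the 5'UTR is the genomically rightmost segment.
    Non-coding models yield an empty map.  Intervals partition
    ``[0, transcript length)``; empty flanks are omitted.
    """
    if model.cds_span is None:
        return {}
    cs, ce = model.cds_span
    exonic = sum(min(e, ce) - max(s, cs) for s, e in model.exons
                 if max(s, cs) < min(e, ce))
    up = sum(min(e, cs) - s for s, e in model.exons if s < cs)   # genomic left of CDS
    if not any(s <= cs < e for s, e in model.exons) or \
       not any(s < ce <= e for s, e in model.exons):
        raise CoordinateError(
            f"{model.transcript_id}: cds_span not congruent with exon union")
    n = model.length
    if model.strand == "+":
        cds_tx = (up, up + exonic)
    else:
        cds_tx = (n - up - exonic, n - up)
    regions: dict[str, tuple[int, int]] = {}
    if cds_tx[0] > 0:
        regions["5UTR"] = (0, cds_tx[0])
    regions["CDS"] = cds_tx
    if cds_tx[1] < n:
        regions["3UTR"] = (cds_tx[1], n)
    if (cds_tx[1] - cds_tx[0]) % 3 != 0:
        log.warning("transcript %s: CDS length %d not a multiple of 3 "
                    "(annotation end-phase exception)", model.transcript_id,
                    cds_tx[1] - cds_tx[0])
    return regions


def extract_transcript_sequence(genome: Genome, model: TranscriptModel) -> str:
    """Mature spliced transcript sequence read 5'->3'."""
    contig = genome.get(model.contig)
    if contig is None:
        raise CoordinateError(f"{model.transcript_id}: unknown contig {model.contig!r}")
    for s, e in model.exons:
        if s < 0 or e > len(contig):
            raise CoordinateError(
                f"{model.transcript_id}: exon [{s},{e}) outside contig bounds")
    seq = "".join(contig[s:e] for s, e in model.exons)
    return seq if model.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# Peptide database FASTA
# ---------------------------------------------------------------------------

def write_peptide_db(entries: Iterable[PeptideDbEntry], handle,
                     include_decoys: bool = False) -> None:
    """Write peptide entries as FASTA, headers ``>pep|{seq}|S={s}``.

    Decoys (reversed amino-acid sequences, headers ``>rev_pep|...``) follow
    the target block.  Output order is lexicographic by sequence so the file
    is deterministic regardless of input order.
    """
    entries = sorted(entries, key=lambda e: e.sequence)
    seen: set[str] = set()
    for e in entries:
        if e.sequence in seen:
            raise ValueError(f"duplicate peptide sequence {e.sequence!r}")
        seen.add(e.sequence)
        handle.write(f">pep|{e.sequence}|S={e.s_value}\n{e.sequence}\n")
    if include_decoys:
        for e in entries:
            rev = e.sequence[::-1]
            handle.write(f">rev_pep|{rev}|S={e.s_value}\n{rev}\n")


def read_peptide_db(handle) -> tuple[list[PeptideDbEntry], list[PeptideDbEntry]]:
    """Parse a peptide-database FASTA back into (targets, decoys)."""
    targets: list[PeptideDbEntry] = []
    decoys: list[PeptideDbEntry] = []
    for rec in SeqIO.parse(handle, "fasta"):
        kind, seq, svalue = rec.description.split("|")
        entry = PeptideDbEntry(sequence=str(rec.seq),
                               s_value=int(svalue.removeprefix("S=")))
        if seq != entry.sequence:
            raise FormatError(f"header/sequence mismatch for {rec.id}")
        (decoys if kind == "rev_pep" else targets).append(entry)
    return targets, decoys


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------

def read_variants(lines: Iterable[str], genome: Optional[Genome] = None,
                  min_quality: float = 0.0) -> list[Variant]:
    """Minimal VCF reader: CHROM/POS/ID/REF/ALT/QUAL only.

    Multi-allelic rows are split; non-SNV rows are skipped with a warning.
    When a genome is supplied the REF allele is checked against it.  The
    quality gate defaults to 0 (no extra filtering beyond the caller's).
    """
    variants: list[Variant] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"VCF line {lineno}: fewer than 6 fields")
        contig, pos, ident, ref, alts, qual = fields[:6]
        try:
            position = int(pos) - 1
        except ValueError as exc:
            raise FormatError(f"VCF line {lineno}: bad POS {pos!r}") from exc
        quality = 0.0 if qual in (".", "") else float(qual)
        if quality < min_quality:
            continue
        for alt in alts.split(","):
            if len(ref) != 1 or len(alt) != 1 or ref == "." or alt in (".", "*"):
                log.warning("VCF line %d: non-SNV record skipped", lineno)
                continue
            if genome is not None:
                base = genome[contig][position]
                if base != ref:
                    raise FormatError(
                        f"VCF line {lineno}: REF {ref} does not match genome "
                        f"base {base} at {contig}:{position + 1}")
            variants.append(Variant(contig=contig, position=position,
                                    ref_allele=ref, alt_allele=alt,
                                    identifier=ident, quality=quality))
    return variants


def write_variants(variants: Sequence[Variant], handle) -> None:
    handle.write("##fileformat=VCFv4.2\n")
    handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for v in variants:
        handle.write(f"{v.contig}\t{v.position + 1}\t{v.identifier}\t"
                     f"{v.ref_allele}\t{v.alt_allele}\t{v.quality:g}\t.\t.\n")


# ---------------------------------------------------------------------------
# TSV tables (PSMs, affinities, expression) and BED
# ---------------------------------------------------------------------------

def read_psms(path_or_handle) -> list[PsmRecord]:
    df = pd.read_csv(path_or_handle, sep="\t", dtype={"modifications": str})
    required = {"peptide", "score", "database", "is_decoy"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"PSM table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(PsmRecord(
            peptide=row.peptide, score=float(row.score), database=row.database,
            is_decoy=bool(row.is_decoy),
            modifications=getattr(row, "modifications", "") or ""))
    return records


def write_psms(psms: Sequence[PsmRecord], handle) -> None:
    pd.DataFrame([{"peptide": p.peptide, "score": p.score,
                   "database": p.database, "is_decoy": p.is_decoy,
                   "modifications": p.modifications} for p in psms]
                 ).to_csv(handle, sep="\t", index=False)


def read_affinities(path_or_handle) -> list[AffinityRecord]:
    df = pd.read_csv(path_or_handle, sep="\t")
    return [AffinityRecord(peptide=r.peptide, allele=r.allele,
                           ic50_nM=float(r.ic50_nM))
            for r in df.itertuples(index=False)]


def write_affinities(records: Sequence[AffinityRecord], handle) -> None:
    pd.DataFrame([{"peptide": r.peptide, "allele": r.allele,
                   "ic50_nM": r.ic50_nM} for r in records]
                 ).to_csv(handle, sep="\t", index=False)


def read_expression(path_or_handle) -> dict[str, float]:
    df = pd.read_csv(path_or_handle, sep="\t")
    return dict(zip(df["transcript_id"], df["fpkm"].astype(float)))


def attach_expression(models: Sequence[TranscriptModel],
                      fpkm: dict[str, float]) -> list[TranscriptModel]:
    return [replace(m, fpkm=fpkm.get(m.transcript_id)) for m in models]


def read_bed(lines: Iterable[str]) -> list[tuple[str, int, int, str, str]]:
    """BED6 -> (contig, start, end, name, strand) tuples; BED is 0-based native."""
    rows = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else "."
        strand = f[5] if len(f) > 5 else "+"
        rows.append((f[0], int(f[1]), int(f[2]), name, strand))
    return rows


def read_bed12_blocks(lines: Iterable[str]) -> list[tuple[str, str, list[tuple[int, int]]]]:
    """BED12 -> (contig, strand, blocks) with blocks as genomic intervals."""
    out = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise FormatError("BED12 record with fewer than 12 fields")
        chrom, start = f[0], int(f[1])
        strand = f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        out.append((chrom, strand, blocks))
    return out
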