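"""Construction of the two personalized search databases.

The *control* database is the canonical proteome: every annotated
protein-coding transcript of the (ns-SNP personalized) genome translated in
its annotated reading frame.

The *all-frames* database is built directly from raw sequencing reads: each
read is translated in all six reading frames through a 33-bp sliding window
(step 1 nt, each window translated in its own frame on both strands), the
products truncated at stop codons, and every surviving 8-11-mer counted.
The count is the peptide's S-value ("seen" value); only peptides with
S >= 10 are retained by default.  A high S-value indicates the peptide is
unlikely to be the product of a sequencing error.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Data import CodonTable

from .formats_io import (Genome, PeptideDbEntry, TranscriptModel, Variant,
                         extract_transcript_sequence, reverse_complement)

log = logging.getLogger("cryptomap")

# Standard genetic code, stops as '*'; 'X' for codons containing N.
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})
STOP_CODONS = frozenset(_TABLE.stop_codons)


def translate(seq: str) -> str:
    """Translate a nucleotide string codon by codon ('*' = stop, 'X' = ambiguous)."""
    return "".join(CODON_TO_AA.get(seq[i:i + 3], "X")
                   for i in range(0, len(seq) - len(seq) % 3, 3))


@dataclass(frozen=True)
class BuildConfig:
    """Sliding-window translation parameters.

    window_bp is three times the maximal peptide length: 33 bp covers the
    11-mer upper end of the class I peptide length range.
    """

    window_bp: int = 33
    min_peptide_len: int = 8
    max_peptide_len: int = 11
    s_min: int = 10
    unique_per_read: bool = False   # count each peptide once per read

    def __post_init__(self) -> None:
        if self.window_bp != 3 * self.max_peptide_len:
            raise ValueError("window_bp must equal 3 x max_peptide_len")
        if self.min_peptide_len > self.max_peptide_len:
            raise ValueError("min_peptide_len must be <= max_peptide_len")
        if self.s_min < 1:
            raise ValueError("s_min must be >= 1")


@dataclass(frozen=True)
class WindowProduct:
    peptide: str
    read_id: str
    window_offset: int
    strand: str               # {forward, revcomp}
    truncated: bool           # stop codon hit inside the window


@dataclass(frozen=True)
class ProteinDbEntry:
    identifier: str
    sequence: str
    is_decoy: bool = False


# ---------------------------------------------------------------------------
# Personalized genome
# ---------------------------------------------------------------------------

def apply_variants(genome: Genome, variants: Iterable[Variant]) -> Genome:
    """Substitute SNV alt alleles into the genome (contig lengths unchanged)."""
    seqs = {name: list(seq) for name, seq in genome.items()}
    seen: set[tuple[str, int]] = set()
    for v in variants:
        if v.contig not in seqs:
            raise KeyError(f"variant {v.identifier}: unknown contig {v.contig!r}")
        key = (v.contig, v.position)
        if key in seen:
            raise ValueError(f"two variants at {v.contig}:{v.position + 1}")
        seen.add(key)
        current = seqs[v.contig][v.position]
        if current != v.ref_allele:
            raise ValueError(
                f"variant {v.identifier}: ref allele {v.ref_allele} does not "
                f"match genome base {current} at {v.contig}:{v.position + 1}")
        seqs[v.contig][v.position] = v.alt_allele
    out = Genome()
    for name, chars in seqs.items():
        out[name] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# Control (canonical proteome) database
# ---------------------------------------------------------------------------

def cds_sequence(genome: Genome, model: TranscriptModel) -> str:
    """Spliced CDS nucleotides of a coding transcript, 5'->3'."""
    if model.cds_span is None:
        raise ValueError(f"{model.transcript_id}: no CDS")
    cs, ce = model.cds_span
    contig = genome[model.contig]
    parts = [contig[max(s, cs):min(e, ce)] for s, e in model.exons
             if max(s, cs) < min(e, ce)]
    seq = "".join(parts)
    return seq if model.strand == "+" else reverse_complement(seq)


def build_control_db(genome: Genome,
                     annotations: Iterable[TranscriptModel]) -> list[ProteinDbEntry]:
    """Translate every coding transcript in its annotated frame.

    Trailing stops are removed; an internal stop truncates the protein with
    a warning (annotation defects are tolerated, not fatal).
    """
    entries: list[ProteinDbEntry] = []
    for model in annotations:
        if model.cds_span is None:
            continue
        protein = translate(cds_sequence(genome, model))
        if protein.endswith("*"):
            protein = protein[:-1]
        if "*" in protein:
            log.warning("transcript %s: internal stop, protein truncated",
                        model.transcript_id)
            protein = protein.split("*", 1)[0]
        if protein:
            entries.append(ProteinDbEntry(identifier=model.transcript_id,
                                          sequence=protein))
    return entries


# ---------------------------------------------------------------------------
# All-frames database
# ---------------------------------------------------------------------------

def sixframe_window_products(read: str, cfg: BuildConfig = BuildConfig(),
                             read_id: str = "") -> list[WindowProduct]:
    """All six-frame sliding-window translation products of one read.

    Every ``window_bp`` window (step 1 nt) is translated in its own frame on
    the forward sequence and on the reverse complement of the window; the
    1-nt slide covers all six reading frames in aggregate.  Translation
    stops at the first stop codon; products shorter than the minimal length
    are discarded; windows containing N are skipped.
    """
    read = read.upper()
    w = cfg.window_bp
    n = len(read)
    if n < w:
        log.debug("read %s shorter than window (%d < %d), skipped",
                  read_id, n, w)
        return []
    rc = reverse_complement(read)
    # Translate each of the three frames once per strand; window products are
    # substrings of these frame translations (identical to per-window
    # translation, but linear time).
    fwd_frames = [translate(read[f:]) for f in range(3)]
    rev_frames = [translate(rc[f:]) for f in range(3)]
    n_aa = cfg.max_peptide_len

    # N positions: a window [o, o+w) is skipped if it contains any N.
    n_positions = [i for i, b in enumerate(read) if b == "N"]

    def has_n(o: int) -> bool:
        # n_positions is short in practice; linear scan is fine
        return any(o <= p < o + w for p in n_positions)

    products: list[WindowProduct] = []
    for o in range(n - w + 1):
        if n_positions and has_n(o):
            continue
        f = o % 3
        aa = fwd_frames[f][(o - f) // 3:(o - f) // 3 + n_aa]
        stop = aa.find("*")
        truncated = stop >= 0
        pep = aa[:stop] if truncated else aa
        if len(pep) >= cfg.min_peptide_len:
            products.append(WindowProduct(pep, read_id, o, "forward", truncated))
        # the same window on the reverse strand: its start in rc coordinates
        ro = n - w - o
        rf = ro % 3
        aa = rev_frames[rf][(ro - rf) // 3:(ro - rf) // 3 + n_aa]
        stop = aa.find("*")
        truncated = stop >= 0
        pep = aa[:stop] if truncated else aa
        if len(pep) >= cfg.min_peptide_len:
            products.append(WindowProduct(pep, read_id, o, "revcomp", truncated))
    return products


def iter_fastq(handle) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ text stream."""
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().rstrip("\n")
        handle.readline()            # '+'
        handle.readline()            # qualities
        yield header[1:].split()[0], seq


def count_window_products(reads: Iterable[tuple[str, str]],
                          cfg: BuildConfig = BuildConfig()) -> Counter:
    """S-value counter over all window products of all reads."""
    counts: Counter = Counter()
    n_reads = 0
    for read_id, seq in reads:
        n_reads += 1
        peptides = (p.peptide for p in sixframe_window_products(seq, cfg, read_id))
        if cfg.unique_per_read:
            counts.update(set(peptides))
        else:
            counts.update(peptides)
    if n_reads == 0:
        log.warning("no reads supplied; all-frames database is empty")
    return counts


def build_allframes_db(reads: Iterable[tuple[str, str]],
                       cfg: BuildConfig = BuildConfig()) -> list[PeptideDbEntry]:
    """All-frames peptide database: S-value counting plus the S >= s_min gate.

    Output is sorted by sequence, hence invariant to read order, and (by the
    window/strand symmetry of the translation) to reverse-complementing the
    reads.
    """
    counts = count_window_products(reads, cfg)
    entries = [PeptideDbEntry(sequence=pep, s_value=s)
               for pep, s in counts.items() if s >= cfg.s_min]
    entries.sort(key=lambda e: e.sequence)
    return entries
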