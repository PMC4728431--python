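"""Translation start/stop prediction for cryptic peptide-coding regions.

The start codon of a cryptic PCR is predicted by three sequential rules
applied within the in-frame window bounded by the nearest upstream stop
codon: (i) the 5'-most upstream AUG in any Kozak context, (ii) the 5'-most
upstream near-cognate codon (one substitution away from AUG) in an optimal
or strong Kozak context, (iii) the first codon after the upstream stop.
The stop codon is the first in-frame stop downstream of the PCR.  The
initiator is decoded as methionine whatever its identity (initiator-tRNA
decoding); the codon itself is reported alongside.

Kozak classes: optimal = GCC(A/G)CC.start.G, strong = (A/G)NN.start.G,
weak = anything else.

Upstream ORFs of a transcript are all ORFs initiating at an AUG in optimal
or strong context within the 5'UTR, running to their first in-frame stop;
they are "contained" when they stop before the CDS start and "junction"
when they overlap it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .database_build import STOP_CODONS, translate
from .formats_io import TranscriptModel, derive_transcript_regions

NEAR_COGNATE = frozenset({"CTG", "GTG", "TTG", "ATA", "ATT", "ATC",
                          "ACG", "AAG", "AGG"})
PURINES = frozenset("AG")
FLANK_BP = 750     # genomic flank per side for PCRs without a source transcript


class FramingError(ValueError):
    """PCR offset inconsistent with the frame of the supplied sequence."""


@dataclass(frozen=True)
class StartPrediction:
    position: int              # coordinate of the start codon in the sequence
    codon: str
    codon_class: str           # {AUG, near_cognate, other}
    kozak: str                 # {optimal, strong, weak}
    rule_applied: str          # {i, ii, iii}
    insufficient_context: bool = False


@dataclass(frozen=True)
class OrfPrediction:
    start: StartPrediction
    stop_position: Optional[int]    # codon start of the stop; None = sequence end
    protein: str
    truncated_at_end: bool

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class Uorf:
    start_position: int
    stop_position: Optional[int]
    location: str              # {contained_5UTR, junction_5UTR_exon}


def kozak_context(sequence: str, start_pos: int) -> tuple[str, bool]:
    """(class, insufficient_context) for a candidate start codon.

    Requires 6 nt upstream and the +4 base downstream; otherwise the codon
    is weak with the insufficient-context flag raised.
    """
    if start_pos < 6 or start_pos + 4 > len(sequence):
        return "weak", True
    up = sequence[start_pos - 6:start_pos]
    plus4 = sequence[start_pos + 3]
    if plus4 == "G":
        if (up[0:3] == "GCC" and up[3] in PURINES and up[4:6] == "CC"):
            return "optimal", False
        if up[3] in PURINES:
            return "strong", False
    return "weak", False


def _codon_class(codon: str) -> str:
    if codon == "ATG":
        return "AUG"
    if codon in NEAR_COGNATE:
        return "near_cognate"
    return "other"


def predict_start(sequence: str, pcr_start: int) -> StartPrediction:
    """Three-rule start-codon prediction for a PCR within ``sequence``.

    ``sequence`` is the source transcript (sense peptides) or the genomic
    flank around the PCR (antisense/intronic/intergenic peptides), 5'->3'
    and in frame with the PCR.  The search region runs from just after the
    nearest upstream in-frame stop (or the first in-frame codon of the
    sequence) up to and including the PCR start codon.
    """
    if pcr_start < 0 or pcr_start + 3 > len(sequence):
        raise FramingError(f"PCR start {pcr_start} outside sequence")
    frame = pcr_start % 3
    # nearest upstream in-frame stop
    region_start = frame
    for pos in range(pcr_start - 3, frame - 1, -3):
        if sequence[pos:pos + 3] in STOP_CODONS:
            region_start = pos + 3
            break
    candidates = list(range(region_start, pcr_start + 1, 3))

    def _make(pos: int, rule: str) -> StartPrediction:
        codon = sequence[pos:pos + 3]
        kozak, insufficient = kozak_context(sequence, pos)
        return StartPrediction(position=pos, codon=codon,
                               codon_class=_codon_class(codon), kozak=kozak,
                               rule_applied=rule,
                               insufficient_context=insufficient)

    for pos in candidates:                                   # rule i
        if sequence[pos:pos + 3] == "ATG":
            return _make(pos, "i")
    for pos in candidates:                                   # rule ii
        if sequence[pos:pos + 3] in NEAR_COGNATE:
            kozak, _ = kozak_context(sequence, pos)
            if kozak in ("optimal", "strong"):
                return _make(pos, "ii")
    return _make(candidates[0] if candidates else pcr_start, "iii")


def predict_orf(sequence: str, pcr_start: int, pcr_len_nt: int,
                start: Optional[StartPrediction] = None) -> OrfPrediction:
    """Source-protein prediction: predicted start to first stop after the PCR.

    The protein begins with M regardless of the initiator codon; it always
    contains the peptide encoded by the PCR (after the initiator when the
    peptide starts at the second residue).
    """
    if start is None:
        start = predict_start(sequence, pcr_start)
    pcr_end = pcr_start + pcr_len_nt
    stop_position: Optional[int] = None
    for pos in range(max(start.position + 3, pcr_end), len(sequence) - 2, 3):
        if sequence[pos:pos + 3] in STOP_CODONS:
            stop_position = pos
            break
    end = stop_position if stop_position is not None \
        else len(sequence) - (len(sequence) - start.position) % 3
    body = translate(sequence[start.position + 3:end])
    return OrfPrediction(start=start, stop_position=stop_position,
                         protein="M" + body,
                         truncated_at_end=stop_position is None)


def find_uorfs(transcript_sequence: str, transcript: TranscriptModel
               ) -> list[Uorf]:
    """Upstream ORFs: optimal/strong-context AUGs starting in the 5'UTR.

    Each qualifying AUG defines an ORF to its first in-frame stop (or the
    transcript end).  A stop entirely before the CDS start makes the uORF
    "contained"; otherwise it overlaps the 5'UTR-exon junction.
    """
    regions = derive_transcript_regions(transcript)
    if "5UTR" not in regions:
        return []
    utr_start, cds_start = regions["5UTR"][0], regions["CDS"][0]
    uorfs: list[Uorf] = []
    for pos in range(utr_start, cds_start):
        if transcript_sequence[pos:pos + 3] != "ATG":
            continue
        kozak, _ = kozak_context(transcript_sequence, pos)
        if kozak not in ("optimal", "strong"):
            continue
        stop_position: Optional[int] = None
        for p in range(pos + 3, len(transcript_sequence) - 2, 3):
            if transcript_sequence[p:p + 3] in STOP_CODONS:
                stop_position = p
                break
        contained = stop_position is not None and stop_position + 3 <= cds_start
        uorfs.append(Uorf(start_position=pos, stop_position=stop_position,
                          location="contained_5UTR" if contained
                          else "junction_5UTR_exon"))
    return uorfs


def has_uorf(transcript_sequence: str, transcript: TranscriptModel) -> bool:
    return bool(find_uorfs(transcript_sequence, transcript))
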