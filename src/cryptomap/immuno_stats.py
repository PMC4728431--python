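"""Peptide-level statistics on the cryptic vs conventional immunopeptidome.

C-terminal signature: amino-acid class usage (hydrophobic/polar x
large/small) at the four C-terminal peptide positions (P4-P1) and the four
residues downstream of the C terminus in the source protein (P1'-P4'),
compared between cryptic and conventional peptides with two-sided Fisher
exact tests.  Also: per-length enrichment, presenting-allotype assignment
(minimum predicted IC50), HLA-restriction dependence of cross-subject
detection, and promiscuous-binder calls at the 5,000 nM cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .formats_io import AffinityRecord
from .psm_filtering import min_affinities
from .transcript_features import ContingencyResult, _fisher

# Default residue grouping by bulkiness and hydrophobicity
# (HL hydrophobic/large, HS hydrophobic/small-medium,
#  PL polar/large, PS polar/small-medium); editable configuration.
DEFAULT_AA_CLASSES: dict[str, str] = {
    **{aa: "HL" for aa in "FILMVWY"},
    **{aa: "HS" for aa in "ACGP"},
    **{aa: "PL" for aa in "EHKQR"},
    **{aa: "PS" for aa in "DNST"},
}

SIGNATURE_POSITIONS = ("P4", "P3", "P2", "P1", "P1'", "P2'", "P3'", "P4'")
PROMISCUOUS_IC50_NM = 5000.0


def _validate_classes(classes: Mapping[str, str]) -> None:
    if sorted(classes) != sorted("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError("class table must cover the 20 standard residues")


def _signature_residue(peptide: str, flank: str, position: str) -> Optional[str]:
    """Residue at a signature position, or None past the protein end."""
    if position.endswith("'"):
        i = int(position[1]) - 1
        return flank[i] if i < len(flank) else None
    i = int(position[1])
    return peptide[-i] if len(peptide) >= i else None


def cterm_signature(cryptic: Sequence[tuple[str, str]],
                    conventional: Sequence[tuple[str, str]],
                    classes: Mapping[str, str] = DEFAULT_AA_CLASSES
                    ) -> dict[tuple[str, str], ContingencyResult]:
    """Per (position, class) 2x2 exact tests between the two peptide groups.

    Each group is a list of (peptide, downstream_flank) pairs, the flank
    being the residues following the peptide's C terminus in its source
    protein (possibly empty when the protein stops at the C terminus; such
    peptides contribute to P4-P1 only).  Result values carry the observed
    table, the (Haldane-corrected) odds ratio and the two-sided p-value.
    """
    _validate_classes(classes)
    if not cryptic or not conventional:
        raise ValueError("both peptide groups must be non-empty")
    results: dict[tuple[str, str], ContingencyResult] = {}
    for position in SIGNATURE_POSITIONS:
        group_residues = []
        for group in (cryptic, conventional):
            residues = [_signature_residue(p, f, position) for p, f in group]
            group_residues.append([r for r in residues if r is not None])
        for cls in sorted(set(classes.values())):
            (cr, co) = group_residues
            a = sum(classes[r] == cls for r in cr)
            c = sum(classes[r] == cls for r in co)
            results[(position, cls)] = _fisher(
                ((a, len(cr) - a), (c, len(co) - c)))
    return results


def log2_odds_ratio(result: ContingencyResult) -> float:
    return math.log2(result.odds_ratio)


def length_distribution_compare(cryptic: Iterable[str],
                                conventional: Iterable[str]
                                ) -> dict[int, ContingencyResult]:
    """Per-length (8-11) 2x2 enrichment tests between the groups."""
    cl = [len(p) for p in cryptic]
    vl = [len(p) for p in conventional]
    out = {}
    for length in (8, 9, 10, 11):
        a = sum(l == length for l in cl)
        c = sum(l == length for l in vl)
        out[length] = _fisher(((a, len(cl) - a), (c, len(vl) - c)))
    return out


def assign_allotype(peptide: str, affinities: Iterable[AffinityRecord],
                    subject_alleles: set[str]) -> str:
    """Presenting allotype = allele with minimal predicted IC50 (ties: name)."""
    best: Optional[tuple[float, str]] = None
    seen = set()
    for rec in affinities:
        if rec.peptide != peptide or rec.allele not in subject_alleles:
            continue
        seen.add(rec.allele)
        key = (rec.ic50_nM, rec.allele)
        if best is None or key < best:
            best = key
    missing = subject_alleles - seen
    if missing:
        raise KeyError(f"peptide {peptide}: missing affinities for {sorted(missing)}")
    return best[1]


@dataclass(frozen=True)
class DetectionMatrix:
    """Cross-subject detection data for the HLA-restriction analysis."""

    detected: Mapping[str, frozenset[str]]        # subject -> detected peptides
    alleles: Mapping[str, frozenset[str]]         # subject -> HLA-A/B alleles
    presenting_allele: Mapping[str, str]          # peptide -> allele in index subject


def hla_restriction_test(matrix: DetectionMatrix, index_subject: str
                         ) -> ContingencyResult:
    """Dependence of detection on carrying the presenting allotype.

    Over all (peptide, non-index subject) pairs: detected yes/no crossed
    with presence of the index subject's presenting allele in the subject's
    genotype, two-sided Fisher exact test.
    """
    others = [s for s in matrix.detected if s != index_subject]
    if len(others) < 2:
        raise ValueError("need at least two non-index subjects")
    a = b = c = d = 0
    for peptide, allele in matrix.presenting_allele.items():
        for subject in others:
            det = peptide in matrix.detected[subject]
            has = allele in matrix.alleles[subject]
            if det and has:
                a += 1
            elif det:
                b += 1
            elif has:
                c += 1
            else:
                d += 1
    return _fisher(((a, b), (c, d)))


def promiscuous_binders(peptides: Iterable[str],
                        affinities: Iterable[AffinityRecord],
                        other_subject_alleles: set[str],
                        ic50_max_nM: float = PROMISCUOUS_IC50_NM
                        ) -> tuple[set[str], set[str]]:
    """Split peptides by minimum IC50 over another subject's alleles.

    IC50 <= the threshold (inclusive) calls a promiscuous binder.
    """
    aff = min_affinities(affinities, other_subject_alleles)
    promiscuous, non_promiscuous = set(), set()
    for p in peptides:
        if p not in aff:
            raise KeyError(f"peptide {p}: no affinity for the other subject")
        (promiscuous if aff[p] <= ic50_max_nM else non_promiscuous).add(p)
    return promiscuous, non_promiscuous
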