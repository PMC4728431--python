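"""Transcript-level features separating cryptic from conventional sources.

Covers 3'UTR length/intron metrics, exact-match scans for stabilizing and
destabilizing 3'UTR elements, expression comparisons, rare-codon usage
statistics and in-silico synonymous/non-synonymous SNP classification.

Codons are "rare" when their observed usage frequency within their
synonymous family is below the uniform expectation (1/family size) and
"common" when above; exact ties go to common.  With the bundled human
usage table this partitions the 64 codons into 30 rare and 34 common.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .database_build import CODON_TO_AA, translate
from .formats_io import TranscriptModel, Variant, derive_transcript_regions
from .genomic_annotation import PcrLocus

log = logging.getLogger("cryptomap")


@dataclass(frozen=True)
class Utr3Profile:
    transcript_id: str
    length_nt: int
    intron_count: int
    destabilizing_count: int = 0
    stabilizing_count: int = 0
    has_utr3: bool = True


@dataclass(frozen=True)
class ElementLists:
    destabilizing: frozenset[str]
    stabilizing: frozenset[str]

    @staticmethod
    def _normalize(motifs: Iterable[str]) -> frozenset[str]:
        out = set()
        for m in motifs:
            m = m.upper().replace("U", "T")
            if not m:
                raise ValueError("empty motif")
            out.add(m)
        return frozenset(out)

    @classmethod
    def from_motifs(cls, destabilizing: Iterable[str],
                    stabilizing: Iterable[str]) -> "ElementLists":
        return cls(destabilizing=cls._normalize(destabilizing),
                   stabilizing=cls._normalize(stabilizing))

    @classmethod
    def from_tsv(cls, path_or_handle) -> "ElementLists":
        df = pd.read_csv(path_or_handle, sep="\t")
        return cls.from_motifs(
            df.loc[df["class"] == "destabilizing", "motif"],
            df.loc[df["class"] == "stabilizing", "motif"])


@dataclass(frozen=True)
class SnpClassification:
    identifier: str
    call: str                   # {synonymous, non_synonymous}


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    sidedness: str = "two_sided"


def _fisher(table, sidedness: str = "two_sided") -> ContingencyResult:
    """Fisher exact test with Haldane-corrected OR for zero cells."""
    (a, b), (c, d) = table
    alt = {"two_sided": "two-sided", "one_sided_greater": "greater",
           "one_sided_less": "less"}[sidedness]
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alt)
    if 0 in (a, b, c, d):
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    return ContingencyResult(table=((a, b), (c, d)),
                             odds_ratio=(a2 * d2) / (b2 * c2),
                             p_value=float(p), sidedness=sidedness)


# ---------------------------------------------------------------------------
# 3'UTR metrics and element scans
# ---------------------------------------------------------------------------

def utr3_metrics(transcript: TranscriptModel) -> tuple[int, int, bool]:
    """(exonic 3'UTR length, number of 3'UTR introns, has_utr3 flag)."""
    regions = derive_transcript_regions(transcript)
    if "3UTR" not in regions:
        return 0, 0, False
    length = regions["3UTR"][1] - regions["3UTR"][0]
    cs, ce = transcript.cds_span
    if transcript.strand == "+":
        span = (ce, transcript.span[1])
    else:
        span = (transcript.span[0], cs)
    introns = sum(1 for a, b in transcript.introns()
                  if span[0] <= a and b <= span[1])
    return length, introns, True


def scan_elements(utr_sequence: str, lists: ElementLists) -> tuple[int, int]:
    """(destabilizing, stabilizing) exact-match counts, overlaps included."""
    seq = utr_sequence.upper().replace("U", "T")

    def count(motifs: frozenset[str]) -> int:
        if not motifs:
            log.warning("empty motif list; count is 0")
            return 0
        total = 0
        for motif in motifs:
            start = seq.find(motif)
            while start >= 0:
                total += 1
                start = seq.find(motif, start + 1)
        return total

    return count(lists.destabilizing), count(lists.stabilizing)


def utr3_profile(transcript: TranscriptModel, transcript_sequence: str,
                 lists: ElementLists) -> Utr3Profile:
    length, introns, has_utr3 = utr3_metrics(transcript)
    if not has_utr3:
        return Utr3Profile(transcript.transcript_id, 0, 0, has_utr3=False)
    regions = derive_transcript_regions(transcript)
    utr_seq = transcript_sequence[regions["3UTR"][0]:regions["3UTR"][1]]
    de, st = scan_elements(utr_seq, lists)
    return Utr3Profile(transcript.transcript_id, length, introns,
                       destabilizing_count=de, stabilizing_count=st)


def compare_stability(cryptic: Sequence[Utr3Profile],
                      conventional: Sequence[Utr3Profile]) -> dict:
    """3'UTR feature comparison between cryptic and conventional sources.

    Lengths: two-sided rank-sum.  Destabilizing / stabilizing counts:
    one-sided rank-sum (cryptic > conventional).  Intron presence (0 vs
    >= 1): two-sided Fisher exact test.
    """
    if len(cryptic) < 2 or len(conventional) < 2:
        return {"insufficient_data": True}
    cl = [p.length_nt for p in cryptic]
    vl = [p.length_nt for p in conventional]
    report: dict = {"insufficient_data": False,
                    "median_length_cryptic": float(np.median(cl)),
                    "median_length_conventional": float(np.median(vl))}
    report["length_p"] = float(stats.mannwhitneyu(
        cl, vl, alternative="two-sided").pvalue)
    for feature in ("destabilizing_count", "stabilizing_count"):
        a = [getattr(p, feature) for p in cryptic]
        b = [getattr(p, feature) for p in conventional]
        report[f"{feature}_p"] = float(stats.mannwhitneyu(
            a, b, alternative="greater").pvalue)
    table = ((sum(p.intron_count == 0 for p in cryptic),
              sum(p.intron_count >= 1 for p in cryptic)),
             (sum(p.intron_count == 0 for p in conventional),
              sum(p.intron_count >= 1 for p in conventional)))
    report["intron_presence"] = _fisher(table)
    return report


def expression_compare(cryptic_fpkm: Sequence[float],
                       conventional_fpkm: Sequence[float],
                       all_expressed_fpkm: Sequence[float] = ()) -> dict:
    """log10 FPKM distributions of cryptic vs conventional source genes."""
    crypt = np.log10([f for f in cryptic_fpkm if f > 0])
    conv = np.log10([f for f in conventional_fpkm if f > 0])
    report = {"median_log10_cryptic": float(np.median(crypt)),
              "median_log10_conventional": float(np.median(conv)),
              "p_value": float(stats.mannwhitneyu(
                  crypt, conv, alternative="two-sided").pvalue)}
    if len(all_expressed_fpkm):
        expressed = np.log10([f for f in all_expressed_fpkm if f > 0])
        report["median_log10_all_expressed"] = float(np.median(expressed))
    return report


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

class CodonUsageTable:
    """Per-codon usage with rare/common classification.

    ``usage`` maps each of the 64 codons to its fraction of synonymous
    usage; the constructor normalizes raw counts or per-thousand values
    within each synonymous family (stop codons form a 3-member family).
    """

    def __init__(self, weights: dict[str, float]):
        missing = set(CODON_TO_AA) - set(weights)
        if missing:
            raise ValueError(f"missing codons: {sorted(missing)}")
        families: dict[str, list[str]] = {}
        for codon, aa in CODON_TO_AA.items():
            families.setdefault(aa, []).append(codon)
        self.usage: dict[str, float] = {}
        self.expected: dict[str, float] = {}
        for aa, codons in families.items():
            total = sum(weights[c] for c in codons)
            if total <= 0:
                raise ValueError(f"zero total usage for family {aa}")
            for c in codons:
                self.usage[c] = weights[c] / total
                self.expected[c] = 1.0 / len(codons)

    @classmethod
    def from_tsv(cls, path_or_handle) -> "CodonUsageTable":
        df = pd.read_csv(path_or_handle, sep="\t")
        return cls(dict(zip(df["codon"], df["frequency_per_thousand"].astype(float))))

    @classmethod
    def human(cls) -> "CodonUsageTable":
        ref = resources.files("cryptomap.data") / "codon_usage_human.tsv"
        with ref.open("r") as handle:
            return cls.from_tsv(handle)


def classify_codons(table: CodonUsageTable,
                    tie_tol: float = 1e-9) -> tuple[set[str], set[str]]:
    """(rare, common) partition of all 64 codons; ties go to common."""
    rare, common = set(), set()
    for codon, observed in table.usage.items():
        if observed < table.expected[codon] - tie_tol:
            rare.add(codon)
        else:
            common.add(codon)
    return rare, common


def _codon_counts(sequences: Iterable[str], rare: set[str]) -> tuple[int, int]:
    n_rare = n_common = 0
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise ValueError("coding sequence length not a multiple of 3")
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if codon in rare:
                n_rare += 1
            elif codon in CODON_TO_AA:
                n_common += 1
    return n_rare, n_common


def rare_codon_enrichment(group_a: Iterable[str], group_b: Iterable[str],
                          table: CodonUsageTable) -> ContingencyResult:
    """2x2 exact test of rare/common codon counts between sequence groups."""
    rare, _ = classify_codons(table)
    a = _codon_counts(group_a, rare)
    b = _codon_counts(group_b, rare)
    return _fisher((a, b))


# ---------------------------------------------------------------------------
# SNP classification and frequency
# ---------------------------------------------------------------------------

def classify_snp(pcr: PcrLocus, peptide: str, variant: Variant) -> SnpClassification:
    """Mutate the PCR in silico, translate, compare with the peptide.

    The alt allele is substituted strand-aware (complemented for minus-
    strand loci) at its position within the PCR reading sequence.
    """
    positions = pcr.genomic_positions()
    if variant.contig != pcr.contig or variant.position not in positions:
        raise ValueError(f"variant {variant.identifier} outside the PCR")
    idx = positions.index(variant.position)
    comp = str.maketrans("ACGTN", "TGCAN")
    alt = variant.alt_allele if pcr.strand == "+" \
        else variant.alt_allele.translate(comp)
    seq = pcr.nt_sequence[:idx] + alt + pcr.nt_sequence[idx + 1:]
    call = "synonymous" if translate(seq) == peptide else "non_synonymous"
    return SnpClassification(identifier=variant.identifier, call=call)


def nssnp_frequency(loci_by_group: dict[str, Sequence[tuple[PcrLocus, str]]],
                    variants: Sequence[Variant]) -> dict:
    """ns-SNP density per PCR bp for each group, plus a 2x2 exact test.

    ``loci_by_group`` maps group name (e.g. "cryptic"/"conventional") to
    (locus, peptide) pairs.  PCR base pairs are deduplicated per group;
    each intersecting SNV is classified by mutate-and-translate and only
    non-synonymous calls are counted.
    """
    per_group: dict[str, dict] = {}
    for group, pairs in loci_by_group.items():
        bases: set[tuple[str, int]] = set()
        n_ns = 0
        for locus, peptide in pairs:
            positions = set(locus.genomic_positions())
            bases |= {(locus.contig, p) for p in positions}
            for v in variants:
                if v.contig == locus.contig and v.position in positions:
                    if classify_snp(locus, peptide, v).call == "non_synonymous":
                        n_ns += 1
        total_bp = len(bases)
        if total_bp == 0:
            raise ValueError(f"group {group!r}: zero total PCR bp")
        per_group[group] = {"ns_snps": n_ns, "total_bp": total_bp,
                            "frequency_per_bp": n_ns / total_bp}
    report: dict = {"groups": per_group}
    if len(per_group) == 2:
        # 2x2 rows follow the caller's group order (first group on top)
        (ga, gb) = list(per_group)
        a, b = per_group[ga], per_group[gb]
        report["test"] = _fisher(((a["ns_snps"], a["total_bp"] - a["ns_snps"]),
                                  (b["ns_snps"], b["total_bp"] - b["ns_snps"])))
    return report
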