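"""Target-decoy FDR filtering and the conventional/cryptic split.

FDR is the paper-style ratio estimate: 100 x (decoy identifications /
target identifications) among records passing a joint (search-engine score,
MHC-binding affinity) threshold pair.  Threshold optimization scans the
grid of observed scores x observed per-peptide minimum IC50 values and
keeps the pair admitting the most target peptides at the requested FDR.

Counting is peptide-level: PSMs are collapsed to the best-scoring record
per (peptide, database, is_decoy) before anything else, and a peptide's
affinity is the minimum predicted IC50 over the subject's class I alleles
(a peptide need only bind one allotype to be presented).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats_io import AffinityRecord, PsmRecord


class NoAdmissibleThreshold(ValueError):
    """No (score, affinity) pair satisfies the FDR bound."""


@dataclass(frozen=True)
class ThresholdPair:
    score_min: float
    ic50_max_nM: float

    def __post_init__(self) -> None:
        if self.score_min < 0:
            raise ValueError("score_min must be >= 0")
        if self.ic50_max_nM <= 0:
            raise ValueError("ic50_max_nM must be > 0")


@dataclass(frozen=True)
class FdrResult:
    n_targets: int
    n_decoys: int

    @property
    def fdr_percent(self) -> float:
        """100 x decoys / targets; NaN (fails any <= bound) when no targets."""
        if self.n_targets == 0:
            return math.nan
        return 100.0 * self.n_decoys / self.n_targets


def collapse_psms(psms: Iterable[PsmRecord]) -> list[PsmRecord]:
    """Best-scoring record per (peptide, database, is_decoy)."""
    best: dict[tuple[str, str, bool], PsmRecord] = {}
    for p in psms:
        key = (p.peptide, p.database, p.is_decoy)
        if key not in best or p.score > best[key].score:
            best[key] = p
    return [best[k] for k in sorted(best)]


def min_affinities(affinities: Iterable[AffinityRecord],
                   alleles: set[str]) -> dict[str, float]:
    """Per-peptide minimum IC50 over the subject's alleles."""
    out: dict[str, float] = {}
    for rec in affinities:
        if rec.allele in alleles:
            prev = out.get(rec.peptide)
            if prev is None or rec.ic50_nM < prev:
                out[rec.peptide] = rec.ic50_nM
    return out


def _require_affinities(psms: Sequence[PsmRecord],
                        aff: dict[str, float]) -> None:
    missing = sorted({p.peptide for p in psms if p.peptide not in aff})
    if missing:
        raise KeyError("peptides with no affinity record for the subject's "
                       f"alleles: {missing}")


def compute_fdr(psms: Iterable[PsmRecord],
                affinities: Iterable[AffinityRecord],
                thr: ThresholdPair,
                alleles: set[str]) -> FdrResult:
    """Decoy-based FDR at a joint threshold pair.

    A (collapsed) record passes iff score >= score_min and its minimum IC50
    over the subject's alleles is <= ic50_max_nM.
    """
    collapsed = collapse_psms(psms)
    aff = min_affinities(affinities, alleles)
    _require_affinities(collapsed, aff)
    n_targets = n_decoys = 0
    for p in collapsed:
        if p.score >= thr.score_min and aff[p.peptide] <= thr.ic50_max_nM:
            if p.is_decoy:
                n_decoys += 1
            else:
                n_targets += 1
    return FdrResult(n_targets=n_targets, n_decoys=n_decoys)


def accepted_peptides(psms: Iterable[PsmRecord],
                      affinities: Iterable[AffinityRecord],
                      thr: ThresholdPair, alleles: set[str],
                      database: str | None = None) -> set[str]:
    """Target peptides passing the thresholds (optionally one database)."""
    collapsed = collapse_psms(psms)
    aff = min_affinities(affinities, alleles)
    _require_affinities(collapsed, aff)
    out = set()
    for p in collapsed:
        if p.is_decoy:
            continue
        if database is not None and p.database not in (database, "both"):
            continue
        if p.score >= thr.score_min and aff[p.peptide] <= thr.ic50_max_nM:
            out.add(p.peptide)
    return out


def optimize_thresholds(psms: Iterable[PsmRecord],
                        affinities: Iterable[AffinityRecord],
                        alleles: set[str],
                        fdr_target_percent: float = 5.0
                        ) -> tuple[ThresholdPair, FdrResult]:
    """Joint threshold pair maximizing accepted targets at the FDR bound.

    The grid is unique observed scores x unique observed per-peptide
    minimum affinities.  Ties on the target count are broken toward lower
    FDR, then lower score_min, then higher ic50_max (the most permissive
    admissible pair).
    """
    collapsed = collapse_psms(psms)
    if not any(not p.is_decoy for p in collapsed):
        raise NoAdmissibleThreshold("no target PSMs supplied")
    aff = min_affinities(affinities, alleles)
    _require_affinities(collapsed, aff)

    scores = np.array([p.score for p in collapsed])
    affs = np.array([aff[p.peptide] for p in collapsed])
    decoy = np.array([p.is_decoy for p in collapsed])

    s_grid = np.unique(scores)           # ascending
    a_grid = np.unique(affs)             # ascending
    s_idx = np.searchsorted(s_grid, scores)
    a_idx = np.searchsorted(a_grid, affs)

    # 2D histograms, then: targets(i,j) = #{score >= s_grid[i], aff <= a_grid[j]}
    shape = (len(s_grid), len(a_grid))
    t_hist = np.zeros(shape)
    d_hist = np.zeros(shape)
    np.add.at(t_hist, (s_idx[~decoy], a_idx[~decoy]), 1)
    np.add.at(d_hist, (s_idx[decoy], a_idx[decoy]), 1)
    t_cnt = np.cumsum(np.cumsum(t_hist[::-1], axis=0)[::-1], axis=1)
    d_cnt = np.cumsum(np.cumsum(d_hist[::-1], axis=0)[::-1], axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = 100.0 * d_cnt / t_cnt
    admissible = (t_cnt > 0) & (fdr <= fdr_target_percent)
    if not admissible.any():
        raise NoAdmissibleThreshold(
            f"no threshold pair reaches FDR <= {fdr_target_percent}%")

    best = None   # (-n_targets, fdr, score_min, -ic50_max, i, j)
    ii, jj = np.nonzero(admissible)
    for i, j in zip(ii, jj):
        key = (-t_cnt[i, j], fdr[i, j], s_grid[i], -a_grid[j])
        if best is None or key < best[0]:
            best = (key, i, j)
    _, i, j = best
    thr = ThresholdPair(score_min=float(s_grid[i]), ic50_max_nM=float(a_grid[j]))
    return thr, FdrResult(n_targets=int(t_cnt[i, j]), n_decoys=int(d_cnt[i, j]))


def split_conventional_cryptic(accepted_allframes: set[str],
                               accepted_control: set[str]
                               ) -> tuple[set[str], set[str], set[str]]:
    """(conventional, putative cryptic, control-only) peptide sets.

    Conventional = identified by both databases; putative cryptic =
    all-frames only.  Control-only peptides are returned for reporting (they
    indicate canonical peptides the all-frames search missed).
    """
    conventional = accepted_allframes & accepted_control
    putative_cryptic = accepted_allframes - accepted_control
    control_only = accepted_control - accepted_allframes
    return conventional, putative_cryptic, control_only
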