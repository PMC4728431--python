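"""End-to-end orchestration of the cryptic-peptide discovery workflow.

Stage order: personalize the genome with ns-SNVs -> build the control
(canonical proteome) and all-frames (six-frame read translation) databases
-> joint score/affinity FDR filtering of the PSMs -> split identifications
into conventional (both databases) and putative cryptic (all-frames only)
-> locate, filter and classify every putative cryptic peptide.  The run
manifest reconciles the bookkeeping: every putative cryptic peptide ends
as exactly one validated record or one discard.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .database_build import (BuildConfig, ProteinDbEntry, apply_variants,
                             build_allframes_db, build_control_db, iter_fastq)
from .formats_io import (Genome, PeptideDbEntry, TranscriptModel,
                         read_affinities, read_expression, read_genome,
                         read_psms, read_variants, parse_annotations,
                         write_peptide_db)
from .genomic_annotation import (DiscardRecord, MapRecord, classify_peptides)
from .psm_filtering import (FdrResult, ThresholdPair, accepted_peptides,
                            compute_fdr, optimize_thresholds,
                            split_conventional_cryptic)

log = logging.getLogger("cryptomap")


@dataclass
class RunResult:
    thresholds: ThresholdPair
    fdr: FdrResult
    fdr_control: FdrResult
    fdr_allframes: FdrResult
    control_db: list[ProteinDbEntry]
    allframes_db: list[PeptideDbEntry]
    conventional: set[str]
    putative_cryptic: set[str]
    control_only: set[str]
    cryptic_maps: list[MapRecord]
    cryptic_discards: list[DiscardRecord]
    conventional_maps: list[MapRecord]
    conventional_discards: list[DiscardRecord]

    def manifest(self) -> dict:
        discards_by_reason: dict[str, int] = {}
        for d in self.cryptic_discards:
            discards_by_reason[d.reason] = discards_by_reason.get(d.reason, 0) + 1
        m = {
            "thresholds": {"score_min": self.thresholds.score_min,
                           "ic50_max_nM": self.thresholds.ic50_max_nM},
            "fdr_percent": self.fdr.fdr_percent,
            "fdr_control_percent": self.fdr_control.fdr_percent,
            "fdr_allframes_percent": self.fdr_allframes.fdr_percent,
            "n_control_db_proteins": len(self.control_db),
            "n_allframes_db_peptides": len(self.allframes_db),
            "n_allframes_identified": len(self.putative_cryptic)
                                      + len(self.conventional),
            "n_conventional": len(self.conventional),
            "n_putative_cryptic": len(self.putative_cryptic),
            "n_validated_cryptic": len(self.cryptic_maps),
            "n_discarded_by_reason": discards_by_reason,
            "n_control_only": len(self.control_only),
        }
        assert m["n_putative_cryptic"] == (m["n_validated_cryptic"]
                                           + sum(discards_by_reason.values()))
        return m


def run_core(reference: Genome, variants, models: Sequence[TranscriptModel],
             expression: dict[str, float], reads: Iterable[tuple[str, str]],
             psms, affinities, alleles: set[str],
             build_cfg: BuildConfig = BuildConfig(),
             fdr_target_percent: float = 5.0,
             validated: Optional[dict[str, bool]] = None,
             alignments: Optional[dict] = None) -> RunResult:
    """Run every stage on in-memory inputs."""
    personalized = apply_variants(reference, variants)
    control_db = build_control_db(personalized, models)
    allframes_db = build_allframes_db(reads, build_cfg)

    thr, fdr = optimize_thresholds(psms, affinities, alleles,
                                   fdr_target_percent)
    by_db = {
        db: [p for p in psms if p.database in (db, "both")]
        for db in ("control", "allframes")
    }
    fdr_control = compute_fdr(by_db["control"], affinities, thr, alleles) \
        if by_db["control"] else FdrResult(0, 0)
    fdr_allframes = compute_fdr(by_db["allframes"], affinities, thr, alleles) \
        if by_db["allframes"] else FdrResult(0, 0)

    acc_allframes = accepted_peptides(psms, affinities, thr, alleles,
                                      database="allframes")
    acc_control = accepted_peptides(psms, affinities, thr, alleles,
                                    database="control")
    conventional, putative_cryptic, control_only = \
        split_conventional_cryptic(acc_allframes, acc_control)
    if control_only:
        log.warning("%d peptides identified only by the control database",
                    len(control_only))

    cryptic_maps, cryptic_discards = classify_peptides(
        putative_cryptic, personalized, models, expression, kind="cryptic",
        alignments=alignments, validated=validated)
    conv_maps, conv_discards = classify_peptides(
        conventional, personalized, models, expression, kind="conventional")

    return RunResult(
        thresholds=thr, fdr=fdr, fdr_control=fdr_control,
        fdr_allframes=fdr_allframes, control_db=control_db,
        allframes_db=allframes_db, conventional=conventional,
        putative_cryptic=putative_cryptic, control_only=control_only,
        cryptic_maps=cryptic_maps, cryptic_discards=cryptic_discards,
        conventional_maps=conv_maps, conventional_discards=conv_discards)


def maps_to_frame(maps: Sequence[MapRecord]) -> pd.DataFrame:
    rows = []
    for m in maps:
        rows.append({
            "peptide": m.peptide, "kind": m.kind,
            "cryptic_status": m.cryptic_status or "",
            "gene": m.source_gene_id or "", "transcript":
            m.source_transcript_id or "", "contig": m.locus.contig,
            "blocks": ";".join(f"{s}-{e}" for s, e in m.locus.blocks),
            "strand": m.locus.strand, "reading_frame": m.reading_frame})
    return pd.DataFrame(rows, columns=["peptide", "kind", "cryptic_status",
                                       "gene", "transcript", "contig",
                                       "blocks", "strand", "reading_frame"])


def run_all(genome_path, gtf_path, variants_path, reads_path, psms_path,
            affinities_path, expression_path, alleles: set[str],
            out_dir, build_cfg: BuildConfig = BuildConfig(),
            fdr_target_percent: float = 5.0) -> dict:
    """File-based end-to-end run; writes outputs + manifest to ``out_dir``."""
    paths = [genome_path, gtf_path, variants_path, reads_path, psms_path,
             affinities_path, expression_path]
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    genome = read_genome(str(genome_path))
    with open(gtf_path) as fh:
        models = parse_annotations(fh)
    with open(variants_path) as fh:
        variants = read_variants(fh, genome=genome)
    expression = read_expression(expression_path)
    psms = read_psms(psms_path)
    affinities = read_affinities(affinities_path)
    with open(reads_path) as fh:
        reads = list(iter_fastq(fh))

    result = run_core(genome, variants, models, expression, reads, psms,
                      affinities, alleles, build_cfg, fdr_target_percent)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "control.fa", "w") as fh:
        for e in result.control_db:
            fh.write(f">{e.identifier}\n{e.sequence}\n")
    with open(out / "allframes.fa", "w") as fh:
        write_peptide_db(result.allframes_db, fh, include_decoys=True)
    maps_to_frame(result.cryptic_maps + result.conventional_maps).to_csv(
        out / "maps.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(d) for d in result.cryptic_discards
                  + result.conventional_discards]).to_csv(
        out / "discards.tsv", sep="\t", index=False)
    manifest = result.manifest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
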