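"""Toy genomes, annotations, reads and PSM tables with planted ground truth.

The simulator emulates the inputs of the real workflow at desk scale: a
B-cell-line-like subject with a personalized genome (reference + ns-SNVs),
Ensembl-style gene annotations with expression values, RNA-seq reads
tiling the expressed pre-mRNAs, and search-engine-like PSM and predicted
binding-affinity tables.  Peptides of every cryptic category are planted
at known loci, so the full pipeline can be scored against an exact truth
table.

Planted 11-mer encodings are placed so that each category's defining
geometry holds (e.g. the out-of-frame exonic peptide sits at a +1 codon
offset inside a CDS; the intron-exon peptide straddles a splice donor).
Two decoy peptides are always planted alongside: one present at two
genomic loci (must be discarded as multi-mapping) and one canonical
in-frame CDS peptide reported only by the all-frames search (must be
discarded as frame-conventional).

Reads are substitution-error-only and tile each expressed gene's pre-mRNA
(sense strand; plus the reverse complement for genes carrying an antisense
plant) at a depth proportional to FPKM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .database_build import (CODON_TO_AA, STOP_CODONS, BuildConfig,
                             ProteinDbEntry, translate)
from .formats_io import (AffinityRecord, Genome, PeptideDbEntry, PsmRecord,
                         TranscriptModel, Variant, reverse_complement)
from .genomic_annotation import GenomeScanner

log = logging.getLogger("cryptomap")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in sorted(CODON_TO_AA):
    CODONS_BY_AA.setdefault(CODON_TO_AA[_codon], []).append(_codon)
NONSTOP_CODONS = sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*")

SUBJECT_ALLELES = ("HLA-A*03:01", "HLA-A*29:02", "HLA-B*08:01", "HLA-B*44:03")

GENE_CATEGORIES = ("5UTR", "5UTR/EXON", "EXON", "INTRON/EXON", "INTRON",
                   "RETAINED_INTRON", "3UTR", "ANTISENSE", "conventional")
ALL_CATEGORIES = GENE_CATEGORIES + ("INTERGENIC",)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 14
    planted: dict = field(default_factory=lambda: {c: 1 for c in ALL_CATEGORIES})
    peptide_len: int = 11
    read_length: int = 100
    depth: int = 20                    # baseline depth at FPKM 10
    error_rate: float = 0.0
    n_multilocus_decoys: int = 1
    n_inframe_decoys: int = 1
    # PSM simulation
    n_psms: Optional[int] = None       # None: targets = planted peptides only
    fraction_incorrect_psms: float = 0.0
    score_mu_correct: float = 55.0
    score_mu_incorrect: float = 25.0
    score_sigma: float = 10.0
    decoy_score_shift: float = 0.0
    alleles: tuple = SUBJECT_ALLELES

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if not 0.0 <= self.fraction_incorrect_psms <= 1.0:
            raise ValueError("fraction_incorrect_psms must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    peptide: str
    category: str                     # cryptic status, "conventional", or decoy kind
    contig: str
    start: int                        # genomic, 0-based half-open
    end: int
    strand: str
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    extra_loci: tuple = ()            # additional (start, end) for multi-locus decoys
    orf_start_tx: Optional[int] = None
    orf_stop_tx: Optional[int] = None
    orf_length_aa: Optional[int] = None


@dataclass
class SimulatedReference:
    reference: Genome
    personalized: Genome
    models: list[TranscriptModel]
    expression: dict[str, float]
    variants: list[Variant]
    truth: list[TruthRecord]
    config: SimConfig

    def truth_by_category(self) -> dict[str, list[TruthRecord]]:
        out: dict[str, list[TruthRecord]] = {}
        for rec in self.truth:
            out.setdefault(rec.category, []).append(rec)
        return out

    def planted_cryptic(self) -> list[TruthRecord]:
        skip = {"conventional", "multi_locus_decoy", "inframe_decoy"}
        return [r for r in self.truth if r.category not in skip]


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_codons(rng: np.random.Generator, n: int,
                   exclude_atg: bool = False) -> str:
    pool = [c for c in NONSTOP_CODONS if not (exclude_atg and c == "ATG")]
    return "".join(rng.choice(pool, size=n))


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    return "".join(rng.choice(CODONS_BY_AA[aa]) for aa in peptide)


# ---------------------------------------------------------------------------
# gene assembly
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    gene_id: str
    strand: str
    category: Optional[str]           # planted category or None (plain gene)
    peptide: Optional[str] = None
    decoy: bool = False               # in-frame decoy (canonical but allframes-only)
    local_seq: str = ""               # sense pre-mRNA (5'->3')
    exons_local: list = field(default_factory=list)
    cds_local: tuple = (0, 0)
    plant_local: Optional[tuple[int, int]] = None   # sense-local plant window
    plant_antisense: bool = False
    orf: Optional[tuple[int, int, int]] = None      # (start_tx, stop_tx, aa)


def _map_base(m: int, introns: Sequence[tuple[int, int]]) -> int:
    """Mature coordinate -> sense-local (pre-mRNA) coordinate."""
    return m + sum(l for mp, l in introns if mp <= m)


def _build_gene(rng: np.random.Generator, plan: _GenePlan, cfg: SimConfig,
                max_tries: int = 60) -> None:
    """Fill in a gene plan: sequence, exon/CDS structure and the plant."""
    cat = plan.category
    pep_nt = 3 * cfg.peptide_len
    for _ in range(max_tries):
        u5 = int(rng.integers(220, 320))
        n_codons = int(rng.integers(70, 110))
        u3 = int(rng.integers(260, 420))
        mature = _random_nt(rng, u5) + "ATG" + \
            _random_codons(rng, n_codons - 2) + "TAA" + _random_nt(rng, u3)
        cds_m = (u5, u5 + 3 * n_codons)
        m_len = len(mature)

        introns: list[tuple[int, int]] = []       # (mature insert pos, length)
        if cat in ("INTRON", "INTRON/EXON", "RETAINED_INTRON"):
            pos = cds_m[0] + 3 * int(rng.integers(15, n_codons - 30))
            introns.append((pos, int(rng.integers(180, 260))))
        elif cat is None and rng.random() < 0.5:
            pos = cds_m[1] + int(rng.integers(40, u3 - 60))
            introns.append((pos, int(rng.integers(120, 200))))

        intron_seqs = {mp: "GT" + _random_nt(rng, l - 4) + "AG"
                       for mp, l in introns}
        # assemble sense-local sequence and exon intervals
        parts, exons_local = [], []
        cursor_m = cursor_l = 0
        for mp, l in sorted(introns):
            parts.append(mature[cursor_m:mp])
            exons_local.append((cursor_l, cursor_l + (mp - cursor_m)))
            cursor_l += (mp - cursor_m)
            parts.append(intron_seqs[mp])
            cursor_l += l
            cursor_m = mp
        parts.append(mature[cursor_m:])
        exons_local.append((cursor_l, cursor_l + (m_len - cursor_m)))
        local = "".join(parts)
        cds_local = (_map_base(cds_m[0], introns),
                     _map_base(cds_m[1] - 1, introns) + 1)

        # --- plant ---------------------------------------------------------
        peptide = plan.peptide
        plant: Optional[tuple[int, int]] = None
        orf = None
        if cat is not None:
            enc = _encode_peptide(rng, peptide)
            if cat == "5UTR":
                p = 150                                    # mature == local here
                local = (local[:p - 33] + "TAA" + "GCCACC" + "ATG" + "GCT" +
                         _pad_codons(rng, 6) + enc +
                         _pad_codons(rng, 2) + "TGA" +
                         local[p + pep_nt + 9:])
                plant = (p, p + pep_nt)
                orf = (p - 24, p + pep_nt + 6, (pep_nt + 30) // 3)
            elif cat == "5UTR/EXON":
                p = cds_local[0] - 13                      # 13 nt UTR + rest CDS
                local = local[:p] + enc + local[p + pep_nt:]
                plant = (p, p + pep_nt)
            elif cat in ("EXON", "conventional"):
                off = 0 if cat == "conventional" else 1
                p = cds_local[0] + 3 * int(rng.integers(10, 40)) + off
                local = local[:p] + enc + local[p + pep_nt:]
                plant = (p, p + pep_nt)
            elif cat == "INTRON/EXON":
                istart = introns[0][0]          # local == mature left of the intron
                p = istart - 13                 # 13 nt exon + 20 nt intron
                local = local[:p] + enc + local[p + pep_nt:]
                plant = (p, p + pep_nt)
            elif cat in ("INTRON", "RETAINED_INTRON"):
                p = introns[0][0] + 40          # intron interior
                local = local[:p] + enc + local[p + pep_nt:]
                plant = (p, p + pep_nt)
            elif cat == "3UTR":
                p = cds_local[1] + 60
                local = local[:p] + enc + local[p + pep_nt:]
                plant = (p, p + pep_nt)
            elif cat == "ANTISENSE":
                p = cds_local[1] + 80                      # inside the 3'UTR
                local = local[:p] + reverse_complement(enc) + local[p + pep_nt:]
                plant = (p, p + pep_nt)

        # reject if the canonical CDS translation gained an internal stop
        cds_seq = "".join(local[a:b] for a, b in _clip(exons_local, cds_local))
        protein = translate(cds_seq)
        if "*" in protein[:-1] or not protein.endswith("*"):
            continue
        plan.local_seq = local
        plan.exons_local = exons_local
        plan.cds_local = cds_local
        plan.plant_local = plant
        plan.plant_antisense = (cat == "ANTISENSE")
        plan.orf = orf
        return
    raise RuntimeError(f"could not assemble gene for category {cat!r}")


def _pad_codons(rng: np.random.Generator, n: int) -> str:
    """Non-stop, non-ATG codons (keeps planted ORF starts unambiguous)."""
    pool = [c for c in NONSTOP_CODONS if c != "ATG"]
    return "".join(rng.choice(pool, size=n))


def _clip(exons: Sequence[tuple[int, int]],
          span: tuple[int, int]) -> list[tuple[int, int]]:
    out = []
    for s, e in exons:
        a, b = max(s, span[0]), min(e, span[1])
        if a < b:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(cfg: SimConfig) -> SimulatedReference:
    """Build the reference/personalized genome pair with planted truth."""
    for attempt in range(5):
        try:
            return _simulate_reference_once(cfg, attempt)
        except RuntimeError as exc:       # pragma: no cover - rare retry path
            log.warning("simulation attempt %d failed (%s), retrying", attempt, exc)
    raise RuntimeError("reference simulation failed after bounded retries")


def _simulate_reference_once(cfg: SimConfig, attempt: int) -> SimulatedReference:
    rng = np.random.default_rng((cfg.seed, attempt))
    contig = "chrS"

    # distinct planted peptides
    n_planted = sum(cfg.planted.get(c, 0) for c in ALL_CATEGORIES)
    n_decoys = cfg.n_multilocus_decoys + cfg.n_inframe_decoys
    peptides: list[str] = []
    while len(peptides) < n_planted + n_decoys:
        p = _random_peptide(rng, cfg.peptide_len)
        if p not in peptides:
            peptides.append(p)
    pep_iter = iter(peptides)

    plans: list[_GenePlan] = []
    gene_n = 0

    def new_plan(category: Optional[str], peptide: Optional[str]) -> _GenePlan:
        nonlocal gene_n
        gene_n += 1
        strand = "+" if rng.random() < 0.7 else "-"
        return _GenePlan(gene_id=f"GENE{gene_n:03d}", strand=strand,
                         category=category, peptide=peptide)

    for cat in GENE_CATEGORIES:
        for _ in range(cfg.planted.get(cat, 0)):
            plans.append(new_plan(cat, next(pep_iter)))
    for _ in range(cfg.n_inframe_decoys):
        plan = new_plan("conventional", next(pep_iter))
        plan.decoy = True
        plans.append(plan)
    while len(plans) < cfg.n_genes:
        plans.append(new_plan(None, None))

    for plan in plans:
        _build_gene(rng, plan, cfg)

    # --- contig assembly ---------------------------------------------------
    pieces: list[str] = []
    cursor = 0
    gene_offsets: dict[str, int] = {}

    def gap(n: int) -> str:
        return _random_nt(rng, n)

    intergenic_plants: list[tuple[str, int]] = []      # (peptide, genomic start)
    multilocus_plants: list[tuple[str, list[int]]] = []

    pieces.append(gap(300))
    cursor += 300
    for plan in plans:
        genomic = plan.local_seq if plan.strand == "+" \
            else reverse_complement(plan.local_seq)
        gene_offsets[plan.gene_id] = cursor
        pieces.append(genomic)
        cursor += len(genomic)
        g = gap(int(rng.integers(350, 500)))
        pieces.append(g)
        cursor += len(g)

    # intergenic peptides in their own windows
    for _ in range(cfg.planted.get("INTERGENIC", 0)):
        pep = next(pep_iter)
        enc = _encode_peptide(rng, pep)
        window = gap(150) + enc + gap(150)
        intergenic_plants.append((pep, cursor + 150))
        pieces.append(window)
        cursor += len(window)
    # multi-locus decoys: identical encoding planted twice, intergenic
    for _ in range(cfg.n_multilocus_decoys):
        pep = next(pep_iter)
        enc = _encode_peptide(rng, pep)
        starts = []
        for _ in range(2):
            window = gap(150) + enc + gap(150)
            starts.append(cursor + 150)
            pieces.append(window)
            cursor += len(window)
        multilocus_plants.append((pep, starts))
    pieces.append(gap(300))

    personalized = Genome()
    personalized[contig] = "".join(pieces)

    # --- transcript models ---------------------------------------------------
    models: list[TranscriptModel] = []
    expression: dict[str, float] = {}
    truth: list[TruthRecord] = []
    pep_nt = 3 * cfg.peptide_len

    for plan in plans:
        g0 = gene_offsets[plan.gene_id]
        L = len(plan.local_seq)

        def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
            a, b = iv
            if plan.strand == "+":
                return (g0 + a, g0 + b)
            return (g0 + L - b, g0 + L - a)

        exons = sorted(to_genomic(iv) for iv in plan.exons_local)
        cds = to_genomic(plan.cds_local)
        cds = (min(cds), max(cds))
        tid = plan.gene_id.replace("GENE", "TX") + ".1"
        fpkm = float(rng.uniform(8, 30)) if plan.category is not None \
            else float(rng.choice([0.0, rng.uniform(1, 20)], p=[0.25, 0.75]))
        model = TranscriptModel(
            transcript_id=tid, gene_id=plan.gene_id,
            gene_name=plan.gene_id.replace("GENE", "g"),
            biotype="protein_coding", strand=plan.strand, contig=contig,
            exons=exons, cds_span=cds)
        models.append(model)
        expression[tid] = fpkm

        source_tid = tid
        if plan.category == "RETAINED_INTRON":
            tid2 = plan.gene_id.replace("GENE", "TX") + ".2"
            span = (min(s for s, _ in exons), max(e for _, e in exons))
            models.append(TranscriptModel(
                transcript_id=tid2, gene_id=plan.gene_id,
                gene_name=plan.gene_id.replace("GENE", "g"),
                biotype="retained_intron", strand=plan.strand, contig=contig,
                exons=[span], cds_span=None))
            expression[tid2] = fpkm + 15.0     # retained isoform dominates
            source_tid = tid2

        if plan.category is not None and plan.plant_local is not None:
            start, end = to_genomic(plan.plant_local)
            start, end = min(start, end), max(start, end)
            locus_strand = plan.strand
            if plan.plant_antisense:
                locus_strand = "-" if plan.strand == "+" else "+"
            category = "inframe_decoy" if plan.decoy else plan.category
            orf = plan.orf
            truth.append(TruthRecord(
                peptide=plan.peptide, category=category, contig=contig,
                start=start, end=end, strand=locus_strand,
                gene_id=plan.gene_id, transcript_id=source_tid,
                orf_start_tx=orf[0] if orf else None,
                orf_stop_tx=orf[1] if orf else None,
                orf_length_aa=orf[2] if orf else None))

    for pep, start in intergenic_plants:
        truth.append(TruthRecord(peptide=pep, category="INTERGENIC",
                                 contig=contig, start=start,
                                 end=start + pep_nt, strand="+"))
    for pep, starts in multilocus_plants:
        truth.append(TruthRecord(peptide=pep, category="multi_locus_decoy",
                                 contig=contig, start=starts[0],
                                 end=starts[0] + pep_nt, strand="+",
                                 extra_loci=tuple((s, s + pep_nt)
                                                  for s in starts[1:])))

    # verify planted locus uniqueness (six-frame scan of the genome)
    scanner = GenomeScanner(personalized)
    for rec in truth:
        expected = 1 + len(rec.extra_loci)
        found = scanner.locate(rec.peptide)
        if len(found) != expected:
            raise RuntimeError(
                f"peptide {rec.peptide} has {len(found)} loci, expected {expected}")

    # --- reference genome: back out ns-SNVs from the personalized one ------
    variants: list[Variant] = []
    ref_chars = list(personalized[contig])
    conv = next((r for r in truth if r.category == "conventional"), None)
    snv_positions = []
    if conv is not None:
        snv_positions.append(conv.start + 4)     # inside the conventional PCR
    plain = [p for p in plans if p.category is None]
    if plain:
        g0 = gene_offsets[plain[0].gene_id]
        cs = plain[0].cds_local[0]
        local_pos = cs + 10
        L = len(plain[0].local_seq)
        gp = g0 + local_pos if plain[0].strand == "+" else g0 + L - 1 - local_pos
        snv_positions.append(gp)
    for i, pos in enumerate(snv_positions, start=1):
        alt = ref_chars[pos]                      # personalized base
        ref = str(rng.choice([b for b in "ACGT" if b != alt]))
        ref_chars[pos] = ref
        variants.append(Variant(contig=contig, position=pos, ref_allele=ref,
                                alt_allele=alt, identifier=f"snv{i}",
                                quality=60.0))
    reference = Genome()
    reference[contig] = "".join(ref_chars)

    return SimulatedReference(reference=reference, personalized=personalized,
                              models=models, expression=expression,
                              variants=variants, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(sim: SimulatedReference,
                   rng: Optional[np.random.Generator] = None
                   ) -> list[tuple[str, str]]:
    """Tile expressed pre-mRNAs (and antisense/intergenic windows) with reads.

    Per-gene depth scales with FPKM (depth = cfg.depth x FPKM / 10); read
    ids encode the template of origin.  Substitution errors are applied at
    cfg.error_rate.
    """
    cfg = sim.config
    if rng is None:
        rng = np.random.default_rng((cfg.seed, 7919))
    genome = sim.personalized
    templates: list[tuple[str, str, float]] = []     # (name, sequence, fpkm)

    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in sim.models:
        by_gene.setdefault(m.gene_id, []).append(m)
    antisense_genes = {r.gene_id for r in sim.truth if r.category == "ANTISENSE"}

    for gid, transcripts in by_gene.items():
        fpkm = max(sim.expression.get(t.transcript_id, 0.0) for t in transcripts)
        if fpkm <= 0:
            continue
        span = (min(t.span[0] for t in transcripts),
                max(t.span[1] for t in transcripts))
        contig = transcripts[0].contig
        seq = genome[contig][span[0]:span[1]]
        if transcripts[0].strand == "-":
            seq = reverse_complement(seq)
        templates.append((f"{gid}|sense", seq, fpkm))
        if gid in antisense_genes:
            templates.append((f"{gid}|antisense", reverse_complement(seq), fpkm))

    for rec in sim.truth:
        if rec.category in ("INTERGENIC", "multi_locus_decoy"):
            for start, end in ((rec.start, rec.end), *rec.extra_loci):
                a, b = max(0, start - 140), min(len(genome[rec.contig]), end + 140)
                templates.append((f"intergenic|{start}",
                                  genome[rec.contig][a:b], 10.0))

    reads: list[tuple[str, str]] = []
    rl = cfg.read_length
    for name, seq, fpkm in templates:
        if len(seq) < rl:
            continue
        depth = max(1, round(cfg.depth * fpkm / 10.0))
        step = max(1, round(rl / depth))
        for i, start in enumerate(range(0, len(seq) - rl + 1, step)):
            read = seq[start:start + rl]
            if cfg.error_rate > 0:
                read = _mutate(rng, read, cfg.error_rate)
            reads.append((f"{name}|{i}", read))
    return reads


def _mutate(rng: np.random.Generator, read: str, rate: float) -> str:
    chars = list(read)
    for i in np.nonzero(rng.random(len(chars)) < rate)[0]:
        chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def write_fastq(reads: Sequence[tuple[str, str]], handle) -> None:
    for read_id, seq in reads:
        handle.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------

def simulate_psms(sim: SimulatedReference,
                  control_db: Sequence[ProteinDbEntry],
                  allframes_db: Sequence[PeptideDbEntry],
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[list[PsmRecord], list[AffinityRecord], dict[str, bool]]:
    """Search-engine-like PSM and affinity tables.

    Correct targets are the planted peptides (padded with additional
    all-frames entries when cfg.n_psms is set); incorrect targets and
    decoys are drawn symmetrically from one lower score distribution, so
    the decoy-based FDR estimate tracks the realized false-match rate.
    Returns (psms, affinities, is_correct-by-peptide).
    """
    cfg = sim.config
    if rng is None:
        rng = np.random.default_rng((cfg.seed, 104729))
    control_seqs = [e.sequence for e in control_db]
    af_sequences = [e.sequence for e in allframes_db]
    af_set = set(af_sequences)

    planted = [r.peptide for r in sim.truth]
    missing = [p for p in planted if p not in af_set]
    if missing:
        raise RuntimeError(f"planted peptides absent from all-frames db: {missing}")
    forced_allframes = {r.peptide for r in sim.truth
                        if r.category == "inframe_decoy"}

    correct = list(planted)
    n_incorrect = 0
    if cfg.n_psms is not None:
        n_correct = round(cfg.n_psms * (1.0 - cfg.fraction_incorrect_psms))
        n_incorrect = cfg.n_psms - n_correct
        pool = sorted(af_set - set(planted))
        extra = rng.choice(pool, size=max(0, n_correct - len(correct)),
                           replace=False)
        correct.extend(str(p) for p in extra)
        pool = sorted(af_set - set(correct))
        incorrect = [str(p) for p in rng.choice(pool, size=n_incorrect,
                                                replace=False)]
    elif cfg.fraction_incorrect_psms > 0:
        n_incorrect = round(len(correct) * cfg.fraction_incorrect_psms
                            / (1 - cfg.fraction_incorrect_psms))
        pool = sorted(af_set - set(correct))
        incorrect = [str(p) for p in rng.choice(pool, size=n_incorrect,
                                                replace=False)]
    else:
        incorrect = []

    used = set(correct) | set(incorrect)
    decoy_pool = sorted({s[::-1] for s in af_sequences} - used)
    decoys = [str(p) for p in rng.choice(decoy_pool, size=len(incorrect),
                                         replace=False)]

    def in_control(pep: str) -> bool:
        return any(pep in seq for seq in control_seqs)

    psms: list[PsmRecord] = []
    is_correct: dict[str, bool] = {}

    def db_label(pep: str) -> str:
        if pep in forced_allframes:
            return "allframes"
        return "both" if in_control(pep) else "allframes"

    for pep in correct:
        score = max(0.0, float(rng.normal(cfg.score_mu_correct, cfg.score_sigma)))
        psms.append(PsmRecord(peptide=pep, score=score, database=db_label(pep),
                              is_decoy=False))
        is_correct[pep] = True
    for pep in incorrect:
        score = max(0.0, float(rng.normal(cfg.score_mu_incorrect, cfg.score_sigma)))
        psms.append(PsmRecord(peptide=pep, score=score, database=db_label(pep),
                              is_decoy=False))
        is_correct[pep] = False
    for pep in decoys:
        score = max(0.0, float(rng.normal(
            cfg.score_mu_incorrect + cfg.decoy_score_shift, cfg.score_sigma)))
        psms.append(PsmRecord(peptide=pep, score=score, database="allframes",
                              is_decoy=True))

    affinities: list[AffinityRecord] = []
    planted_set = set(planted)
    for pep in sorted({p.peptide for p in psms}):
        genuine = pep in planted_set or (pep in is_correct and is_correct[pep])
        if genuine:
            best = min(float(rng.lognormal(np.log(120.0), 0.6)), 1200.0)
            values = {a: float(rng.uniform(2000, 30000)) for a in cfg.alleles}
            values[str(rng.choice(cfg.alleles))] = best
        else:
            # incorrect targets and decoys share one affinity distribution
            if rng.random() < 0.5:
                best = float(rng.lognormal(np.log(400.0), 1.0))
                values = {a: float(rng.uniform(1500, 40000)) for a in cfg.alleles}
                values[str(rng.choice(cfg.alleles))] = best
            else:
                values = {a: float(rng.uniform(1500, 40000)) for a in cfg.alleles}
        for allele, ic50 in values.items():
            affinities.append(AffinityRecord(peptide=pep, allele=allele,
                                             ic50_nM=max(1.0, ic50)))
    return psms, affinities, is_correct
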