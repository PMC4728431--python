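"""PCR location, filtering cascade, region classification and metrics."""

import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import bio_translate
from cryptomap.formats_io import Genome, TranscriptModel
from cryptomap.genomic_annotation import (DiscardRecord, GeneIndex,
                                          GenomeScanner, MapRecord, PcrLocus,
                                          UnlocatablePeptide,
                                          assign_source_gene, classify_region,
                                          filter_unique_locus, locate_pcr,
                                          pcr_coverage, positional_bias,
                                          select_source_isoform,
                                          validate_reading_frame)


def make_genome(seq: str, name: str = "c") -> Genome:
    g = Genome()
    g[name] = seq
    return g


def naive_locate(genome: Genome, peptide: str):
    """Per-position six-frame oracle (Biopython translation of every window)."""
    hits = set()
    n = 3 * len(peptide)
    for contig, seq in genome.items():
        for o in range(len(seq) - n + 1):
            window = seq[o:o + n]
            if str(Seq(window).translate()) == peptide:
                hits.add((contig, "+", (o, o + n)))
            if str(Seq(window).reverse_complement().translate()) == peptide:
                hits.add((contig, "-", (o, o + n)))
    return hits


class TestLocatePcr:
    def test_single_planted_occurrence(self):
        rng = np.random.default_rng(0)
        flank = "".join(rng.choice(list("ACGT"), size=800))
        enc = "ATGGCTGCTAAAGGTCTGGAAGATCTGAAAGTT"
        genome = make_genome(flank + enc + flank[::-1])
        loci = locate_pcr("MAAKGLEDLKV", genome)
        assert len(loci) == 1
        assert bio_translate(loci[0].nt_sequence) == "MAAKGLEDLKV"

    def test_two_contigs_two_loci(self):
        enc = "ATGGCTGCTAAAGGTCTGGAAGATCTGAAAGTT"
        g = Genome()
        g["c1"] = "AAAA" + enc + "TTTT"
        g["c2"] = "GGGG" + enc + "CCCC"
        assert len(locate_pcr("MAAKGLEDLKV", g)) == 2

    def test_unlocatable_raises(self):
        with pytest.raises(UnlocatablePeptide):
            locate_pcr("WWWWWWWW", make_genome("ACGT" * 50))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_sixframe_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = make_genome(seq)
        scanner = GenomeScanner(genome)
        # peptides sampled from actual frame translations (guaranteed hits)
        for _ in range(6):
            o = int(rng.integers(0, 1900))
            pep = bio_translate(seq[o:o + 24])
            if "*" in pep or len(pep) < 8:
                continue
            got = {(l.contig, l.strand, l.blocks[0])
                   for l in locate_pcr(pep, scanner)}
            assert got == naive_locate(genome, pep)

    def test_spliced_locus_from_alignments(self):
        """BED12-style blocks give a spliced PCR whose translation matches."""
        left, right = "ATGGCTGCTAAAGGT", "CTGGAAGATCTGAAAGTT"
        intron = "GT" + "A" * 40 + "AG"
        genome = make_genome("CCCC" + left + intron + right + "CCCC")
        blocks = [(4, 4 + len(left)),
                  (4 + len(left) + len(intron),
                   4 + len(left) + len(intron) + len(right))]
        (locus,) = locate_pcr("MAAKGLEDLKV", genome,
                              alignments=[("c", "+", blocks)])
        assert locus.blocks == tuple(blocks)
        assert bio_translate(locus.nt_sequence) == "MAAKGLEDLKV"


class TestUniqueLocus:
    def test_single_locus_passes(self):
        locus = PcrLocus("c", ((0, 24),), "+", "A" * 24)
        assert filter_unique_locus("PEPTIDES", [locus]) is locus

    def test_multi_locus_discarded(self):
        a = PcrLocus("c", ((0, 24),), "+", "A" * 24)
        b = PcrLocus("c", ((90, 114),), "+", "A" * 24)
        result = filter_unique_locus("PEPTIDES", [a, b])
        assert result == DiscardRecord("PEPTIDES", "multi_locus")

    def test_simulator_multilocus_decoy_discarded(self, sim, pipeline_result):
        decoy = next(t.peptide for t in sim.truth
                     if t.category == "multi_locus_decoy")
        assert DiscardRecord(decoy, "multi_locus") in \
            pipeline_result.cryptic_discards


def toy_models():
    fwd = TranscriptModel("T1", "G1", strand="+", contig="c",
                          exons=[(1000, 2000)], cds_span=(1200, 1800))
    rev = TranscriptModel("T2", "G2", strand="-", contig="c",
                          exons=[(3000, 4000)], cds_span=(3200, 3800))
    return [fwd, rev]


class TestSourceGene:
    def test_same_strand_assignment(self):
        locus = PcrLocus("c", ((1500, 1527),), "+", "A" * 27)
        assert assign_source_gene(locus, toy_models()) == ("gene", "G1")

    def test_antisense_when_only_opposite(self):
        locus = PcrLocus("c", ((1500, 1527),), "-", "A" * 27)
        assert assign_source_gene(locus, toy_models()) == ("antisense", "G1")

    def test_intergenic(self):
        locus = PcrLocus("c", ((2500, 2527),), "+", "A" * 27)
        assert assign_source_gene(locus, toy_models()) == ("intergenic", None)

    def test_nested_same_strand_genes_ambiguous(self):
        models = toy_models() + [TranscriptModel(
            "T3", "G3", strand="+", contig="c", exons=[(1400, 1600)])]
        locus = PcrLocus("c", ((1500, 1527),), "+", "A" * 27)
        assert assign_source_gene(locus, models)[0] == "multi_gene"

    @pytest.mark.parametrize("seed", range(2))
    def test_matches_overlap_oracle(self, sim, seed):
        """Random loci against a naive span-overlap scan of all genes."""
        rng = np.random.default_rng(seed)
        index = GeneIndex(sim.models)
        spans = {}
        for m in sim.models:
            s, e = m.span
            if m.gene_id in spans:
                c, st, s0, e0 = spans[m.gene_id]
                spans[m.gene_id] = (c, st, min(s0, s), max(e0, e))
            else:
                spans[m.gene_id] = (m.contig, m.strand, s, e)
        for _ in range(60):
            start = int(rng.integers(0, len(sim.personalized["chrS"]) - 27))
            strand = "+" if rng.random() < 0.5 else "-"
            locus = PcrLocus("chrS", ((start, start + 27),), strand, "A" * 27)
            same = sorted(g for g, (c, st, s, e) in spans.items()
                          if c == "chrS" and st == strand
                          and max(s, start) < min(e, start + 27))
            opp = sorted(g for g, (c, st, s, e) in spans.items()
                         if c == "chrS" and st != strand
                         and max(s, start) < min(e, start + 27))
            got = assign_source_gene(locus, index)
            if len(same) == 1:
                assert got == ("gene", same[0])
            elif len(same) > 1:
                assert got[0] == "multi_gene"
            elif opp:
                assert got[0] == "antisense"
            else:
                assert got == ("intergenic", None)


class TestIsoformSelection:
    def models(self):
        mk = lambda tid, n: TranscriptModel(tid, "G", strand="+", contig="c",
                                            exons=[(0, n)])
        return [mk("T1", 500), mk("T2", 900)]

    def test_highest_fpkm(self):
        assert select_source_isoform("G", self.models(),
                                     {"T1": 5.0, "T2": 1.2}).transcript_id == "T1"

    def test_tie_smallest_id(self):
        assert select_source_isoform("G", self.models(),
                                     {"T1": 2.0, "T2": 2.0}).transcript_id == "T1"

    def test_zero_fpkm_not_expressed(self):
        assert select_source_isoform("G", self.models(),
                                     {"T1": 0.0, "T2": 1.0}).transcript_id == "T2"

    def test_fallback_longest(self):
        assert select_source_isoform("G", self.models(),
                                     {}).transcript_id == "T2"

    def test_random_tables_match_argmax_oracle(self):
        rng = np.random.default_rng(1)
        models = [TranscriptModel(f"T{i}", "G", strand="+", contig="c",
                                  exons=[(0, 100 + i)]) for i in range(8)]
        for _ in range(25):
            fpkm = {m.transcript_id: float(rng.choice([0.0, rng.uniform(0, 9)]))
                    for m in models}
            chosen = select_source_isoform("G", models, fpkm)
            expressed = {t: v for t, v in fpkm.items() if v > 0}
            if expressed:
                best = max(expressed.values())
                assert fpkm[chosen.transcript_id] == best
                assert chosen.transcript_id == min(
                    t for t, v in expressed.items() if v == best)


def region_model():
    # 5'UTR [100,150), CDS [150,450), 3'UTR [450,600); intron [250,350)
    return TranscriptModel("T", "G", strand="+", contig="c",
                           exons=[(100, 250), (350, 600)], cds_span=(150, 450))


def naive_status(locus, transcript, siblings=()):
    """Independent per-base labelling oracle for the classification rules."""
    labels = set()
    span = transcript.span
    for s, e in locus.blocks:
        for p in range(s, e):
            if not (span[0] <= p < span[1]):
                continue
            exonic = any(a <= p < b for a, b in transcript.exons)
            if not exonic:
                labels.add("intron")
            elif transcript.cds_span is None:
                labels.add("ncexon")
            else:
                cs, ce = transcript.cds_span
                if cs <= p < ce:
                    labels.add("CDS")
                elif (p < cs) == (transcript.strand == "+"):
                    labels.add("5UTR")
                else:
                    labels.add("3UTR")
    if "intron" in labels:
        return "INTRON/EXON" if labels - {"intron"} else "INTRON"
    if "ncexon" in labels:
        if transcript.biotype == "retained_intron":
            retained = [(max(s, a), min(e, b))
                        for s, e in transcript.exons
                        for sib in siblings if sib is not transcript
                        for a, b in zip([x[1] for x in sib.exons],
                                        [x[0] for x in sib.exons[1:]])
                        if max(s, a) < min(e, b)]
            pos = [p for s, e in locus.blocks for p in range(s, e)]
            if all(any(a <= p < b for a, b in retained) for p in pos):
                return "RETAINED_INTRON"
        return "EXON"
    if "5UTR" in labels:
        return "5UTR/EXON" if "CDS" in labels else "5UTR"
    return "3UTR" if "3UTR" in labels else "EXON"


class TestClassifyRegion:
    def mk(self, start, end, strand="+"):
        return PcrLocus("c", ((start, end),), strand, "A" * (end - start))

    @pytest.mark.parametrize("start,end,expected", [
        (120, 147, "5UTR"),
        (140, 167, "5UTR/EXON"),          # crosses the CDS start at 150
        (160, 187, "EXON"),
        (240, 267, "INTRON/EXON"),        # crosses the splice donor at 250
        (260, 287, "INTRON"),
        (500, 527, "3UTR"),
        (440, 467, "3UTR"),               # reads through the canonical stop
    ])
    def test_boundary_rules(self, start, end, expected):
        assert classify_region(self.mk(start, end), region_model()) == expected

    def test_randomized_pcrs_match_per_base_oracle(self, sim):
        rng = np.random.default_rng(8)
        index = GeneIndex(sim.models)
        for model in sim.models:
            siblings = index.transcripts_by_gene[model.gene_id]
            lo, hi = model.span
            for _ in range(30):
                start = int(rng.integers(max(0, lo - 5), hi - 27))
                locus = self.mk(start, start + 27, model.strand)
                try:
                    expected = naive_status(locus, model, siblings)
                    got = classify_region(locus, model, siblings)
                except Exception:
                    continue
                assert got == expected

    def test_simulator_statuses_recovered(self, sim, pipeline_result):
        """Every planted category label is reproduced by the classifier."""
        truth = {t.peptide: t.category for t in sim.planted_cryptic()}
        got = {m.peptide: m.cryptic_status
               for m in pipeline_result.cryptic_maps}
        assert got == truth


class TestReadingFrame:
    def setup_method(self):
        rng = np.random.default_rng(12)
        codons = ["GCT", "AAA", "GGT", "CTG", "GAA", "GAT", "TGC", "CAT"]
        self.cds = "ATG" + "".join(rng.choice(codons, size=60)) + "TAA"
        seq = "T" * 50 + self.cds + "G" * 50
        self.genome = make_genome(seq)
        self.model = TranscriptModel("T", "G", strand="+", contig="c",
                                     exons=[(0, len(seq))],
                                     cds_span=(50, 50 + len(self.cds)))

    def test_in_frame_offset_multiple_of_three(self):
        start = 50 + 12
        nt = self.genome["c"][start:start + 27]
        locus = PcrLocus("c", ((start, start + 27),), "+", nt)
        assert validate_reading_frame(locus, self.model, self.genome,
                                      "EXON") == "in"

    def test_out_of_frame_offset(self):
        start = 50 + 13
        nt = self.genome["c"][start:start + 27]
        locus = PcrLocus("c", ((start, start + 27),), "+", nt)
        assert validate_reading_frame(locus, self.model, self.genome,
                                      "EXON") == "out"

    def test_non_exonic_status_returns_none(self):
        locus = PcrLocus("c", ((0, 27),), "+", "A" * 27)
        assert validate_reading_frame(locus, self.model, self.genome,
                                      "5UTR") == "none"

    def test_inframe_decoy_is_control_substring(self, sim, control_db,
                                                pipeline_result):
        """A frame-conventional discard is canonical: substring of its protein."""
        decoy = next(t.peptide for t in sim.truth
                     if t.category == "inframe_decoy")
        assert DiscardRecord(decoy, "frame_conventional") in \
            pipeline_result.cryptic_discards
        assert any(decoy in e.sequence for e in control_db)


class TestCoverage:
    LOCUS = PcrLocus("c", ((100, 127),), "+", "A" * 27)

    def test_counts_overlapping_reads(self):
        reads = [("c", 90, 110, "r1", "+"), ("c", 120, 160, "r2", "+"),
                 ("c", 105, 120, "r3", "+")]
        assert pcr_coverage(self.LOCUS, reads) == 3

    def test_half_open_adjacency_not_overlap(self):
        reads = [("c", 60, 100, "r1", "+"), ("c", 127, 180, "r2", "+")]
        assert pcr_coverage(self.LOCUS, reads) == 0

    def test_random_layouts_match_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            reads = [("c", int(s), int(s) + 40, f"r{i}", "+")
                     for i, s in enumerate(rng.integers(0, 300, size=50))]
            expected = sum(1 for _, s, e, _, _ in reads
                           if s < 127 and 100 < e)
            assert pcr_coverage(self.LOCUS, reads) == expected


class TestPositionalBias:
    def model(self, n=1000):
        return TranscriptModel("T", "G", strand="+", contig="c",
                               exons=[(0, n)], cds_span=(200, 800))

    def mk_record(self, start, status):
        locus = PcrLocus("c", ((start, start + 27),), "+", "A" * 27)
        return MapRecord("PEP", "cryptic", locus, cryptic_status=status)

    def test_normalized_start(self):
        assert positional_bias(self.mk_record(100, "5UTR"),
                               self.model()) == pytest.approx(0.1)

    def test_start_zero(self):
        assert positional_bias(self.mk_record(0, "5UTR"), self.model()) == 0.0

    def test_excluded_categories_skipped(self):
        for status in ("INTRON", "INTERGENIC", "ANTISENSE"):
            assert positional_bias(self.mk_record(100, status),
                                   self.model()) is None

    def test_utr5_planted_left_shifted_vs_cds(self):
        """5'UTR-planted starts rank below CDS-planted starts (n=50/50)."""
        from scipy.stats import mannwhitneyu
        rng = np.random.default_rng(21)
        model = self.model()
        utr = [positional_bias(self.mk_record(int(rng.integers(0, 170)),
                                              "5UTR"), model)
               for _ in range(50)]
        cds = [positional_bias(self.mk_record(int(rng.integers(200, 770)),
                                              "EXON"), model)
               for _ in range(50)]
        p = mannwhitneyu(utr, cds, alternative="less").pvalue
        assert p < 0.05


class TestTotality:
    def test_every_peptide_accounted(self, pipeline_result):
        """n_putative = n_maps + n_discards, with no duplicates."""
        n_in = len(pipeline_result.putative_cryptic)
        outs = [m.peptide for m in pipeline_result.cryptic_maps] + \
               [d.peptide for d in pipeline_result.cryptic_discards]
        assert sorted(outs) == sorted(set(outs))
        assert n_in == len(outs)
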