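import numpy as np
import pytest

from tascreen.assembly import (
    CDS,
    UTR3,
    UTR5,
    SignalElement,
    TranscriptModel,
    antisense_window,
    assemble_candidates,
    build_antitoxin_isoforms,
    build_toxin_mrna,
    classify_overlap,
    evaluate_confidence,
    group_promoters,
    group_terminators,
)
from tascreen.screen import OrfRecord
from tascreen.seqio import GenomeRecord, GenomicInterval, reverse_complement
from tascreen.signals import PromoterHit
from tascreen.simulate import SimConfig, simulate_genome


def prom_elem(tss, strand, confidence="low"):
    return SignalElement("promoter", tss, strand, confidence)


def term_elem(end3, strand, confidence="low"):
    return SignalElement("terminator", end3, strand, confidence)


def mrna_cds_only(low, high, strand):
    cds = GenomicInterval(low, high, strand)
    return TranscriptModel(strand=strand, tss=cds.five_prime, end3=cds.three_prime, cds=cds)


class TestAntisenseWindow:
    def test_padding_and_strand(self):
        w = antisense_window(GenomicInterval(1000, 1191, 1), genome_length=10_000)
        assert (w.low, w.high, w.strand) == (700, 1491, -1)

    def test_clipped_at_genome_start(self):
        w = antisense_window(GenomicInterval(50, 200, 1), genome_length=10_000)
        assert (w.low, w.high) == (1, 500)

    def test_fixture_4253_antitoxin_inside_window(self):
        # this antitoxin's 5' end extends 172 nt beyond the toxin CDS,
        # still inside the 300 nt search window
        toxin = GenomicInterval.from_start_end(4_016_545, 4_016_411)
        anti = GenomicInterval.from_start_end(4_016_466, 4_016_717)
        w = antisense_window(toxin, genome_length=5_200_000)
        assert w.low <= anti.low and anti.high <= w.high
        assert w.strand == 1


class TestBuildIsoforms:
    def test_two_tss_share_terminator(self):
        # plus-strand antitoxin against a minus-strand toxin: two isoforms
        # of 56 and 85 nt sharing their 3' end, shortest numbered first
        mrna = mrna_cds_only(3_792_476, 3_792_667, -1)
        isoforms = build_antitoxin_isoforms(
            [prom_elem(3_792_450, 1), prom_elem(3_792_421, 1)],
            [term_elem(3_792_505, 1)],
            mrna, strand=1,
        )
        assert [i.transcript.length for i in isoforms] == [56, 85]
        assert [i.isoform_index for i in isoforms] == [1, 2]
        assert {i.transcript.end3 for i in isoforms} == {3_792_505}

    def test_three_tss_one_terminator_minus_strand(self):
        mrna = mrna_cds_only(299_411, 299_551, 1)
        isoforms = build_antitoxin_isoforms(
            [prom_elem(t, -1) for t in (299_493, 299_517, 299_574)],
            [term_elem(299_423, -1)],
            mrna, strand=-1,
        )
        assert [i.transcript.length for i in isoforms] == [71, 95, 152]
        assert all(i.transcript.strand == -1 for i in isoforms)

    def test_terminator_upstream_gives_nothing(self):
        mrna = mrna_cds_only(1000, 1191, -1)
        assert build_antitoxin_isoforms(
            [prom_elem(1100, 1)], [term_elem(1050, 1)], mrna, strand=1
        ) == []

    def test_min_length_filter(self):
        mrna = mrna_cds_only(1000, 1191, -1)
        isoforms = build_antitoxin_isoforms(
            [prom_elem(1100, 1)], [term_elem(1130, 1)], mrna, strand=1,
            min_length=40,
        )
        assert isoforms == []  # 31 nt transcript discarded


class TestBuildToxinMrna:
    ORF = OrfRecord(GenomicInterval(1000, 1191, 1), "M" * 63, "ATG", "g", 1)

    def test_fallback_is_bare_cds(self):
        m = build_toxin_mrna(self.ORF, [], [])
        assert (m.tss, m.end3) == (1000, 1191)
        assert m.utr5 is None and m.utr3 is None

    def test_utr5_length_40(self):
        m = build_toxin_mrna(self.ORF, [prom_elem(960, 1)], [])
        assert m.tss == 960
        assert m.utr5 == GenomicInterval(960, 999, 1)
        assert m.utr5.length == 40

    def test_utr3_length_55(self):
        m = build_toxin_mrna(self.ORF, [], [term_elem(1246, 1)])
        assert m.end3 == 1246
        assert m.utr3 == GenomicInterval(1192, 1246, 1)
        assert m.utr3.length == 55

    def test_minus_strand_utrs(self):
        orf = OrfRecord(GenomicInterval(1000, 1191, -1), "M" * 63, "ATG", "g", 1)
        m = build_toxin_mrna(orf, [prom_elem(1231, -1)], [term_elem(950, -1)])
        assert (m.tss, m.end3) == (1231, 950)
        assert m.utr5 == GenomicInterval(1192, 1231, -1)
        assert m.utr3 == GenomicInterval(950, 999, -1)

    def test_downstream_promoter_ignored(self):
        m = build_toxin_mrna(self.ORF, [prom_elem(1100, 1)], [])
        assert m.tss == 1000 and m.utr5 is None


class TestClassifyOverlap:
    @pytest.mark.parametrize("anti,toxin,expected", [
        # worked-example rows recomputed from coordinates alone
        ((3_792_450, 3_792_505, 1), (3_792_476, 3_792_667, -1), {CDS, UTR3}),
        ((1_096_424, 1_096_466, 1), (1_096_486, 1_096_632, -1), {UTR3}),
        ((1_152_693, 1_152_843, 1), (1_152_629, 1_152_754, -1), {CDS, UTR5}),
        ((1000, 1191, 1), (1000, 1191, -1), {CDS}),  # exact cover
    ])
    def test_examples(self, anti, toxin, expected):
        mrna = mrna_cds_only(toxin[0], toxin[1], toxin[2])
        assert classify_overlap(GenomicInterval(*anti), mrna) == expected

    def test_same_strand_rejected(self):
        mrna = mrna_cds_only(1000, 1191, 1)
        with pytest.raises(ValueError, match="opposite"):
            classify_overlap(GenomicInterval(1000, 1100, 1), mrna)

    def test_bounded_utr_used_when_modelled(self):
        cds = GenomicInterval(1000, 1191, 1)
        mrna = TranscriptModel(strand=1, tss=960, end3=1246, cds=cds,
                               utr5=GenomicInterval(960, 999, 1),
                               utr3=GenomicInterval(1192, 1246, 1))
        assert classify_overlap(GenomicInterval(950, 955, -1), mrna) == set()
        assert classify_overlap(GenomicInterval(960, 970, -1), mrna) == {UTR5}

    def test_extension_never_removes_categories(self, rng):
        mrna = mrna_cds_only(1000, 1191, 1)
        for _ in range(50):
            low = int(rng.integers(700, 1500))
            high = int(rng.integers(low, 1600))
            iv = GenomicInterval(low, high, -1)
            base = classify_overlap(iv, mrna)
            wider = GenomicInterval(max(1, low - 30), high + 30, -1)
            assert base <= classify_overlap(wider, mrna)


class TestConfidence:
    def _hit(self, tss, method, score=0.0):
        return PromoterHit(
            box35=GenomicInterval(max(1, tss - 35), max(2, tss - 30), 1),
            box10=GenomicInterval(max(3, tss - 12), max(4, tss - 7), 1),
            tss=tss, strand=1, score=score, method=method,
        )

    def test_both_methods_high(self):
        assert evaluate_confidence([self._hit(100, "pwm"), self._hit(102, "consensus")]) == "high"

    def test_one_method_low(self):
        assert evaluate_confidence([self._hit(100, "pwm")]) == "low"

    def test_nearby_cross_method_hits_group_high(self):
        elems = group_promoters([self._hit(100, "pwm", 14.0), self._hit(102, "consensus")])
        assert len(elems) == 1 and elems[0].confidence == "high"
        assert elems[0].position == 100  # pwm hit preferred for the position

    def test_distant_same_method_hits_stay_separate(self):
        elems = group_promoters([self._hit(100, "pwm"), self._hit(140, "pwm")])
        assert [e.confidence for e in elems] == ["low", "low"]
        assert [e.position for e in elems] == [100, 140]


class TestAssembleCandidates:
    def test_recovers_planted_loci(self):
        cfg = SimConfig(genome_length=10_000, n_loci=2, seed=42)
        genome, truths = simulate_genome(cfg)
        candidates, log = assemble_candidates(genome)
        found = {(c.toxin.interval.low, c.toxin.interval.high, c.toxin.interval.strand)
                 for c in candidates}
        for t in truths:
            assert (t.toxin_iv.low, t.toxin_iv.high, t.toxin_iv.strand) in found
        by_iv = {(c.toxin.interval.low, c.toxin.interval.high): c for c in candidates}
        for t in truths:
            cand = by_iv[(t.toxin_iv.low, t.toxin_iv.high)]
            assert any(i.overlap_classes == t.expected_classes for i in cand.isoforms)
            assert all(i.transcript.strand == -t.toxin_iv.strand for i in cand.isoforms)

    def test_count_conservation_across_stages(self):
        genome, _ = simulate_genome(SimConfig(genome_length=10_000, n_loci=2, seed=42))
        _, log = assemble_candidates(genome)
        for stage in ("tm_filter", "homology_filter", "operon_filter", "signal_gate"):
            c = log[stage]
            assert c["kept"] + c["dropped"] == c["in"]

    def test_toxin_without_antisense_signals_yields_nothing(self, rng):
        # a hydrophobic ORF alone, no planted promoter/terminator nearby
        flank = "".join(rng.choice(list("CA"), size=600))
        orf = "TAA" + "ATG" + "CTG" * 30 + "AAA" * 20 + "TAA"
        genome = GenomeRecord("g", flank + orf + flank)
        candidates, log = assemble_candidates(genome)
        assert log["tm_filter"]["kept"] >= 1
        assert candidates == []

    def test_mirror_symmetry_of_full_scan(self):
        genome, _ = simulate_genome(SimConfig(genome_length=10_000, n_loci=2, seed=7))
        L = len(genome)
        mirrored = GenomeRecord(genome.identifier, reverse_complement(genome.sequence))
        fwd, _ = assemble_candidates(genome)
        rev, _ = assemble_candidates(mirrored)

        def key(cands):
            out = set()
            for c in cands:
                iso = frozenset(
                    (i.transcript.interval.low, i.transcript.interval.high,
                     frozenset(i.overlap_classes))
                    for i in c.isoforms
                )
                out.add((c.toxin.interval.low, c.toxin.interval.high,
                         c.toxin.interval.strand, iso))
            return out

        def mirror(cands):
            out = set()
            for c in cands:
                iso = frozenset(
                    (L - i.transcript.interval.high + 1, L - i.transcript.interval.low + 1,
                     frozenset(_mirror_classes(i.overlap_classes)))
                    for i in c.isoforms
                )
                out.add((L - c.toxin.interval.high + 1, L - c.toxin.interval.low + 1,
                         -c.toxin.interval.strand, iso))
            return out

        def _mirror_classes(classes):
            return classes  # categories are strand-relative, unchanged by mirroring

        assert key(fwd) == mirror(rev)
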