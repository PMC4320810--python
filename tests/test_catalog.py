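"""TSS association, chromatin/ambiguity filters, positional classes, naming."""

import numpy as np
import pytest

from lncprobe.annotations import AnnotationSet, GeneModel, TranscriptRecord
from lncprobe.catalog import (
    LncRnaRecord, associate_tss, build_catalog, classify_position,
    coding_tss_regions, exclude_ambiguous_tss, filter_by_chromatin, name_lncrnas,
)
from lncprobe.tss import TssRegion


def _lnc(start, end, strand="+", chrom="chr1", tid="lnc1"):
    return TranscriptRecord(tid, "synthetic", chrom, start, end, strand,
                            ((start, end),), "noncoding", tid)


def _region(start, end, strand="+", count=30, chrom="chr1"):
    return TssRegion(chrom, strand, start, end, count, 1)


def _gene(symbol, start, end, strand="+", exons=None, chrom="chr1"):
    return GeneModel(symbol, chrom, start, end, strand,
                     tuple(exons or [(start, end)]), (f"tx_{symbol}",))


class TestAssociateTss:
    def test_flank_window_and_strand(self):
        lnc = _lnc(100_000, 102_000)
        near = _region(90_000, 90_020)          # 10 kb upstream
        far = _region(65_000, 65_020)           # 35 kb upstream
        anti = _region(100_000, 100_020, "-")   # opposite strand at the 5' end
        got = associate_tss(lnc, [near, far, anti], flank=30_000)
        assert got == [near]

    def test_flank_monotonicity(self):
        rng = np.random.default_rng(5)
        lnc = _lnc(500_000, 501_000)
        regions = [
            _region(int(s), int(s) + 20)
            for s in rng.integers(400_000, 600_000, size=200)
        ]
        counts = [
            len(associate_tss(lnc, regions, flank)) for flank in (0, 10_000, 30_000, 60_000)
        ]
        assert counts == sorted(counts)


class TestChromatinFilter:
    PEAKS = {
        ("H3K4me3", "unstim"): {"chr1": [(1_000, 2_000)]},
        ("H3K27Ac", "LPS"): {"chr1": [(5_000, 6_000)]},
    }

    def test_filter_mark_peak_retains(self):
        region = _region(1_500, 1_520)
        assert filter_by_chromatin([region], self.PEAKS) == [region]

    def test_no_peak_drops(self):
        assert filter_by_chromatin([_region(9_000, 9_020)], self.PEAKS) == []

    def test_h3k27ac_alone_does_not_rescue(self):
        # H3K27Ac is not part of the TSS filter set
        assert filter_by_chromatin([_region(5_500, 5_520)], self.PEAKS) == []


class TestAmbiguity:
    def test_overlap_with_coding_tss_removed(self):
        coding = {"chr1": [(10_000, 11_001)]}
        ambiguous = _region(10_500, 10_520)
        clean = _region(30_000, 30_020)
        assert exclude_ambiguous_tss([ambiguous, clean], coding) == [clean]

    def test_coding_tss_regions_are_strand_aware_anchors(self):
        plus = TranscriptRecord("c1", "synthetic", "chr1", 5_000, 8_000, "+",
                                ((5_000, 8_000),), "coding", "G1")
        minus = TranscriptRecord("c2", "synthetic", "chr1", 20_000, 24_000, "-",
                                 ((20_000, 24_000),), "coding", "G2")
        regions = coding_tss_regions(AnnotationSet([plus, minus]), ambiguity_window=500)
        assert regions["chr1"][0] == (4_500, 5_501)          # + strand: 5' = start
        assert regions["chr1"][1] == (23_499, 24_500)        # - strand: 5' = end - 1


class TestClassification:
    GENE = _gene("GeneA", 20_000, 30_000,
                 exons=[(20_000, 21_000), (24_000, 25_000), (29_000, 30_000)])

    @pytest.mark.parametrize(
        "start,end,strand,expected",
        [
            (24_200, 24_900, "+", "exonic_sense"),
            (22_000, 23_000, "+", "intronic_sense"),   # wholly within intron 1
            (24_500, 26_500, "-", "antisense"),
            (18_500, 19_200, "-", "bidirectional"),    # 800 bp gap, opposite strand
            (10_000, 15_000, "-", "intergenic"),       # 5 kb gap
            (10_000, 15_000, "+", "intergenic"),       # same strand, never bidirectional
        ],
    )
    def test_rule_table(self, start, end, strand, expected):
        cls, gene, dist = classify_position(_lnc(start, end, strand), [self.GENE])
        assert cls == expected
        assert (dist == 0) == (expected in ("exonic_sense", "intronic_sense", "antisense"))

    def test_tss_distance_metric_variant(self):
        # gap to gene = 1.2 kb (not bidirectional by the gene metric) but the
        # TSS-to-TSS distance is 1201 -> still intergenic; at 900 bp gap both agree
        lnc = _lnc(17_900, 18_800, "-")
        by_gene, _, _ = classify_position(lnc, [self.GENE], bidirectional_metric="gene")
        by_tss, _, _ = classify_position(lnc, [self.GENE], bidirectional_metric="tss")
        assert by_gene == "intergenic"
        assert by_tss == "intergenic"
        near = _lnc(18_200, 19_100, "-")
        assert classify_position(near, [self.GENE], bidirectional_metric="tss")[0] == "bidirectional"

    def test_no_coding_gene_on_chromosome(self):
        cls, gene, dist = classify_position(_lnc(0, 500, chrom="chrX"), [self.GENE])
        assert cls == "intergenic" and gene is None and dist is None

    def test_longest_overlap_wins_over_nearest(self):
        a = _gene("A", 0, 1_000)
        b = _gene("B", 900, 3_000)
        lnc = _lnc(500, 2_000, "+")  # overlaps A by 500, B by 1100
        _, gene, _ = classify_position(lnc, [a, b])
        assert gene.gene_symbol == "B"


def test_naming_and_collisions():
    def rec(tid, start, neighbor):
        return LncRnaRecord(
            lnc_id=tid, span=_lnc(start, start + 500, tid=tid),
            tss_regions=[_region(start, start + 20)], primary_tss=start,
            position_class="intergenic", neighbor_gene=neighbor,
            neighbor_distance=100, display_name=tid,
        )

    records = [rec("l1", 1_000, "Nfkb2"), rec("l2", 5_000, "Rel"),
               rec("l3", 9_000, "Rel"), rec("l4", 12_000, None)]
    name_lncrnas(records)
    names = {r.lnc_id: r.display_name for r in records}
    assert names == {"l1": "lncRNA-Nfkb2", "l2": "lncRNA-Rel",
                     "l3": "lncRNA-Rel-2", "l4": "l4"}


def test_lncrna_with_one_ambiguous_tss_survives_with_the_other():
    lnc = _lnc(50_000, 52_000)
    own = _region(50_000, 50_020, count=40)
    ambiguous = _region(70_000, 70_020, count=90)
    coding_tx = TranscriptRecord("c", "synthetic", "chr1", 70_000, 80_000, "+",
                                 ((70_000, 80_000),), "coding", "G")
    annots = AnnotationSet([lnc, coding_tx])
    peaks = {("PolII", "unstim"): {"chr1": [(49_000, 51_000), (69_000, 71_000)]}}
    catalog, funnel = build_catalog([lnc], [own, ambiguous], annots, peaks)
    assert len(catalog) == 1
    assert catalog[0].tss_regions == [own]
    # primary TSS anchored on the surviving region even though the ambiguous
    # one had more tags
    assert abs(catalog[0].primary_tss - 50_010) <= 10


def test_all_tss_ambiguous_drops_lncrna():
    lnc = _lnc(69_500, 71_500)
    region = _region(70_000, 70_020)
    coding_tx = TranscriptRecord("c", "synthetic", "chr1", 70_000, 80_000, "+",
                                 ((70_000, 80_000),), "coding", "G")
    annots = AnnotationSet([lnc, coding_tx])
    peaks = {("PolII", "unstim"): {"chr1": [(69_000, 71_000)]}}
    catalog, funnel = build_catalog([lnc], [region], annots, peaks)
    assert catalog == [] and funnel["after_ambiguity"] == 0


def test_position_classes_partition_catalog(small_result):
    counts = {
        k: v for k, v in small_result.funnel.counts.items() if k.startswith("class_")
    }
    assert sum(counts.values()) == len(small_result.catalog)
    assert small_result.funnel.counts["catalog"] == len(small_result.catalog)
    # every catalog entry kept at least one validated TSS region
    assert all(r.tss_regions for r in small_result.catalog)
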