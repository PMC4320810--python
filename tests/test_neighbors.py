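"""Neighbor-gene relations and TF-binding association."""

import numpy as np
import pandas as pd
import pytest

from lncprobe.annotations import GeneModel, TranscriptRecord
from lncprobe.catalog import LncRnaRecord
from lncprobe.neighbors import (
    associate_tf_peaks, distance_by_chromatin_class, nearest_neighbor,
    neighbor_coexpression, tf_target_expression_shift,
)


def _gene(symbol, start, end, strand="+", chrom="chr1"):
    return GeneModel(symbol, chrom, start, end, strand, ((start, end),), (symbol,))


def _lnc(tid, start, end, strand="+", chrom="chr1"):
    return TranscriptRecord(tid, "synthetic", chrom, start, end, strand,
                            ((start, end),), "noncoding", tid)


def _record(tid, start, end, tss, chrom="chr1", pclass="intergenic", cclass="elncRNA"):
    rec = LncRnaRecord(
        lnc_id=tid, span=_lnc(tid, start, end, chrom=chrom), tss_regions=[],
        primary_tss=tss, position_class=pclass, neighbor_gene=None,
        neighbor_distance=None, display_name=tid,
    )
    rec.chromatin_class = cclass
    return rec


class TestNearestNeighbor:
    def test_containment_gives_distance_zero(self):
        pair = nearest_neighbor(_lnc("l", 1_000, 2_000), [_gene("A", 0, 10_000)])
        assert pair.gene_symbol == "A" and pair.distance == 0

    def test_smaller_gap_wins(self):
        genes = [_gene("A", 2_300, 3_000), _gene("B", 3_200, 4_000)]
        pair = nearest_neighbor(_lnc("l", 0, 2_000), genes)
        assert pair.gene_symbol == "A" and pair.distance == 300

    def test_longest_overlap_wins(self):
        genes = [_gene("A", 0, 1_500), _gene("B", 1_200, 3_000)]
        # lnc overlaps A by 500 and B by 800
        pair = nearest_neighbor(_lnc("l", 1_000, 2_000), genes)
        assert pair.gene_symbol == "B" and pair.distance == 0

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(12)
        genes = []
        for i in range(300):
            s = int(rng.integers(0, 500_000))
            genes.append(_gene(f"g{i}", s, s + int(rng.integers(200, 5_000))))
        for _ in range(100):
            s = int(rng.integers(0, 500_000))
            lnc = _lnc("l", s, s + int(rng.integers(200, 3_000)))
            pair = nearest_neighbor(lnc, genes)
            # oracle: exhaustive scan with the same tie rules
            overl = [
                (min(lnc.end, g.end) - max(lnc.start, g.start), g)
                for g in genes
                if lnc.start < g.end and g.start < lnc.end
            ]
            if overl:
                best = max(overl, key=lambda t: (t[0], -t[1].start))[1]
                expect = (best.gene_symbol, 0)
            else:
                gaps = [
                    (g.start - lnc.end if g.start >= lnc.end else lnc.start - g.end, g)
                    for g in genes
                ]
                d, g = min(gaps, key=lambda t: (t[0], t[1].start))
                expect = (g.gene_symbol, d)
            assert (pair.gene_symbol, pair.distance) == expect


class TestTfAssociation:
    def test_window_boundary(self):
        recs = [_record("l1", 100_000, 101_000, 100_000)]
        peaks = {
            ("p65", "LPS"): {"chr1": [(104_900, 105_100)]},   # 5 kb: bound
            ("IRF3", "LPS"): {"chr1": [(112_000, 112_300)]},  # 12 kb: not bound
        }
        binding, summary = associate_tf_peaks(recs, peaks, window=10_000)
        by_tf = binding.set_index("tf")["bound"]
        assert bool(by_tf["p65"]) and not bool(by_tf["IRF3"])
        assert summary["bound_by_any_core"] == 1

    def test_venn_cells_sum_to_any_core(self):
        rng = np.random.default_rng(7)
        recs = [
            _record(f"l{i}", i * 100_000, i * 100_000 + 1_000, i * 100_000)
            for i in range(30)
        ]
        peaks = {}
        for tf in ("p65", "IRF3", "JunB", "cJun"):
            chrom_peaks = []
            for rec in recs:
                if rng.random() < 0.4:
                    chrom_peaks.append((rec.primary_tss + 2_000, rec.primary_tss + 2_200))
            peaks[(tf, "LPS")] = {"chr1": sorted(chrom_peaks)}
        binding, summary = associate_tf_peaks(recs, peaks)
        assert sum(summary["venn"].values()) == summary["bound_by_any_core"]

    def test_window_monotonicity(self):
        rng = np.random.default_rng(8)
        recs = [
            _record(f"l{i}", i * 50_000, i * 50_000 + 500, i * 50_000)
            for i in range(20)
        ]
        peaks = {
            ("p65", "LPS"): {
                "chr1": sorted(
                    (int(p), int(p) + 200)
                    for p in rng.integers(0, 1_000_000, size=100)
                )
            }
        }
        small = associate_tf_peaks(recs, peaks, window=5_000)[1]["bound_by_any_core"]
        large = associate_tf_peaks(recs, peaks, window=20_000)[1]["bound_by_any_core"]
        assert small <= large

    def test_planted_all_four_recovered(self, small_universe, small_result):
        truth = small_universe.truth
        planted = set(
            truth.loc[truth["tf_bound"].fillna("") == "p65,IRF3,JunB,cJun", "lnc_id"]
        )
        venn_all = small_result.tf_summary["bound_by_all_core"]
        assert venn_all == len(planted) == small_universe.config.n_bound_all_four
        # and the mean pairwise summit distance stays within 2 kb as planted
        assert small_result.tf_summary["mean_pairwise_summit_distance"] < 2_000


class TestCoexpression:
    def test_planted_coregulation_detected(self):
        rng = np.random.default_rng(3)
        n = 50
        lnc_fc = rng.normal(1.5, 0.4, size=n)
        pairs = pd.DataFrame(
            {
                "lnc_id": [f"l{i}" for i in range(n)],
                "gene_symbol": [f"g{i}" for i in range(n)],
                "distance": 1_000,
                "lnc_log2fc": lnc_fc,
                "gene_log2fc": lnc_fc + rng.normal(0, 0.3, size=n),
                "position_class": "intergenic",
                "chromatin_class": "elncRNA",
            }
        )
        gene_fc_all = pd.Series(rng.normal(0, 0.5, size=500),
                                index=[f"bg{i}" for i in range(500)])
        out = neighbor_coexpression(pairs, gene_fc_all, set(pairs["lnc_id"]))
        assert (out["p"] < 0.05).all()
        # sign concordance with planted rho near 1: nearly all pairs concordant
        conc = (pairs["lnc_log2fc"] * pairs["gene_log2fc"] > 0).mean()
        assert conc >= 0.75

    def test_permuted_neighbors_show_no_shift(self):
        rng = np.random.default_rng(6)
        gene_fc_all = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
        pvals = []
        for rep in range(50):
            n = 40
            pairs = pd.DataFrame(
                {
                    "lnc_id": [f"l{i}" for i in range(n)],
                    "gene_symbol": rng.choice(gene_fc_all.index, size=n, replace=False),
                    "distance": 1_000,
                    "lnc_log2fc": np.abs(rng.normal(size=n)) + 0.1,
                    "gene_log2fc": rng.normal(size=n),
                    "position_class": "intergenic",
                    "chromatin_class": "plncRNA",
                }
            )
            out = neighbor_coexpression(pairs, gene_fc_all, set(pairs["lnc_id"]))
            pvals.extend(out["p"])
        # null p-values should not pile up near 0
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_identical_distance_distributions(self):
        pairs = pd.DataFrame(
            {
                "lnc_id": [f"l{i}" for i in range(20)],
                "gene_symbol": "g",
                "distance": list(range(10)) * 2,
                "lnc_log2fc": 0.0,
                "gene_log2fc": 0.0,
                "position_class": "intergenic",
                "chromatin_class": ["elncRNA"] * 10 + ["plncRNA"] * 10,
            }
        )
        t, p = distance_by_chromatin_class(pairs)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_tf_target_shift_on_planted_targets():
    rng = np.random.default_rng(5)
    ids = [f"l{i}" for i in range(200)]
    fc = pd.Series(rng.normal(size=200), index=ids)
    fc.iloc[:30] += 2.0
    binding = pd.DataFrame(
        {
            "lnc_id": ids,
            "tf": "p65",
            "condition": "LPS",
            "bound": [i < 30 for i in range(200)],
            "n_peaks": 1,
            "nearest_summit": 0,
        }
    )
    out = tf_target_expression_shift(binding, fc)
    assert out.iloc[0]["p"] < 0.05 and out.iloc[0]["n_targets"] == 30
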