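"""KNN imputation, probe collapsing, fold changes, robust rank aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from lncprobe.expression import (
    ExpressionMatrix, FoldChangeTable, call_regulated, collapse_to_transcripts,
    knn_impute, log2_fold_change, mean_fold_change, normalized_ranks,
    rho_score, rra_aggregate,
)


def _matrix(values, columns=None, platform="P1"):
    df = pd.DataFrame(values, columns=columns or ["unstim_1", "unstim_2", "LPS_1", "LPS_2"])
    df.index = [f"p{i}" for i in range(len(df))]
    conds = {c: ("LPS" if c.startswith("LPS") else "unstim") for c in df.columns}
    return ExpressionMatrix(platform, df, conds)


class TestKnnImpute:
    def test_no_missing_is_identity(self):
        mat = _matrix(np.arange(12.0).reshape(3, 4))
        out = knn_impute(mat, k=2)
        assert out.values.equals(mat.values)

    def test_k1_copies_nearest_row(self):
        vals = np.array([
            [1.0, 1.0, 1.0, np.nan],
            [1.0, 1.0, 1.0, 5.0],
            [9.0, 9.0, 9.0, 9.0],
        ])
        out = knn_impute(_matrix(vals), k=1)
        assert out.values.iloc[0, 3] == 5.0
        # observed cells untouched
        assert out.values.iloc[1, 3] == 5.0 and out.values.iloc[2, 0] == 9.0

    def test_equidistant_neighbors_average(self):
        vals = np.array([
            [1.0, 1.0, 1.0, np.nan],
            [1.0, 1.0, 1.0, 2.0],
            [1.0, 1.0, 1.0, 4.0],
        ])
        out = knn_impute(_matrix(vals), k=2)
        assert out.values.iloc[0, 3] == pytest.approx(3.0)

    def test_all_missing_column_is_error(self):
        vals = np.array([[1.0, np.nan, 2.0, 2.0], [1.0, np.nan, 2.0, 2.0]])
        with pytest.raises(ValueError, match="all values missing"):
            knn_impute(_matrix(vals))

    def test_oversized_k_truncated(self, caplog):
        import logging

        vals = np.array([[1.0, 1.0, 1.0, np.nan], [1.0, 1.0, 1.0, 3.0]])
        with caplog.at_level(logging.WARNING):
            out = knn_impute(_matrix(vals), k=50)
        assert out.values.iloc[0, 3] == 3.0


class TestCollapse:
    ASSIGN = pd.DataFrame(
        {
            "probe_id": ["p0", "p1", "p2"],
            "platform": ["P1", "P1", "P1"],
            "target_id": ["T1", "T1", "T2"],
            "target_kind": ["lncRNA", "lncRNA", "lncRNA"],
        }
    )

    def test_mean_of_probes(self):
        mat = _matrix(np.array([[2.0] * 4, [4.0] * 4, [7.0] * 4]))
        out = collapse_to_transcripts(mat, self.ASSIGN)
        assert out.loc["T1"].tolist() == [3.0] * 4
        assert out.loc["T2"].tolist() == [7.0] * 4

    def test_unassigned_probe_dropped(self):
        mat = _matrix(np.array([[2.0] * 4, [4.0] * 4, [7.0] * 4, [99.0] * 4]))
        out = collapse_to_transcripts(mat, self.ASSIGN)
        assert set(out.index) == {"T1", "T2"}


def test_log2_fold_change_examples():
    mat = _matrix(np.array([[4.0, 4.0, 6.0, 6.0], [5.0, 5.0, 5.0, 5.0]]))
    tm = mat.values
    fc = log2_fold_change(tm, mat.conditions, "D1")
    assert fc.entries["p0"] == pytest.approx(2.0)
    assert fc.entries["p1"] == pytest.approx(0.0)
    # unbalanced replicates: mean(5,7) - 4 = 2
    tm2 = pd.DataFrame([[4.0, 5.0, 7.0]], index=["t"], columns=["u1", "l1", "l2"])
    fc2 = log2_fold_change(tm2, {"u1": "unstim", "l1": "LPS", "l2": "LPS"}, "D2")
    assert fc2.entries["t"] == pytest.approx(2.0)


class TestRra:
    def test_rho_single_list(self):
        assert rho_score([0.2]) == pytest.approx(0.2)

    def test_rho_two_median_ranks(self):
        # beta = (P(Bin(2,.5)>=1), P(Bin(2,.5)>=2)) = (0.75, 0.25)
        assert rho_score([0.5, 0.5]) == pytest.approx(0.25)

    def test_aggregate_two_datasets_midrank(self):
        tables = [
            FoldChangeTable("A", pd.Series({"T1": 2.0, "T2": 0.0})),
            FoldChangeTable("B", pd.Series({"T1": 1.5, "T2": -0.5})),
        ]
        results = {a.transcript_id: a for a in rra_aggregate(tables, "up")}
        assert results["T1"].rho == pytest.approx(0.25)
        assert results["T1"].p == pytest.approx(0.5)
        assert results["T1"].normalized_ranks == (0.5, 0.5)
        assert results["T1"].p_adj == pytest.approx(1.0)  # Bonferroni m=2

    def test_consistent_top_rank_is_most_significant(self):
        rng = np.random.default_rng(0)
        tables = []
        for d in range(6):
            fc = pd.Series(rng.normal(size=50), index=[f"t{i}" for i in range(50)])
            fc["star"] = 10.0
            tables.append(FoldChangeTable(f"D{d}", fc))
        results = rra_aggregate(tables, "up")
        assert results[0].transcript_id == "star"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        tables = [
            FoldChangeTable(f"D{d}", pd.Series(rng.normal(size=30),
                                               index=[f"t{i}" for i in range(30)]))
            for d in range(5)
        ]
        fwd = {a.transcript_id: a.rho for a in rra_aggregate(tables, "up")}
        rev = {a.transcript_id: a.rho for a in rra_aggregate(tables[::-1], "up")}
        assert fwd == rev

    def test_improving_one_rank_never_hurts(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 12))
            r = rng.uniform(0.01, 1.0, size=n)
            rho = rho_score(r)
            j = int(rng.integers(n))
            better = r.copy()
            better[j] *= rng.uniform(0.1, 1.0)
            assert rho_score(better) <= rho + 1e-12

    def test_ties_get_average_ranks(self):
        table = FoldChangeTable("D", pd.Series({"a": 1.0, "b": 1.0, "c": 0.0}))
        r = normalized_ranks(table, "up")
        assert r["a"] == pytest.approx(1.5 / 3) and r["b"] == pytest.approx(1.5 / 3)

    def test_missing_lists_shrink_n(self):
        tables = [
            FoldChangeTable("A", pd.Series({"x": 1.0, "y": 0.0})),
            FoldChangeTable("B", pd.Series({"y": 1.0})),
        ]
        res = {a.transcript_id: a for a in rra_aggregate(tables, "up")}
        assert res["x"].n_datasets == 1 and res["y"].n_datasets == 2


def _result(tid, direction, p_adj):
    from lncprobe.expression import AggregationResult

    return AggregationResult(tid, direction, p_adj / 2, p_adj / 2, p_adj, 3, (0.1,))


def test_call_regulated_boundary_and_conflicts():
    up = [_result("a", "up", 0.04), _result("b", "up", 0.05), _result("c", "up", 0.01)]
    down = [_result("c", "down", 0.02), _result("d", "down", 0.001)]
    with pytest.warns(UserWarning, match="both directions"):
        got_up, got_down = call_regulated(up, down, alpha=0.05)
    assert {a.transcript_id for a in got_up} == {"a", "c"}   # 0.05 excluded; c kept on smaller p
    assert {a.transcript_id for a in got_down} == {"d"}


def test_null_unadjusted_p_is_conservative():
    rng = np.random.default_rng(11)
    n, m = 8, 2_000
    ranks = np.sort(rng.random((m, n)), axis=1)
    from scipy.stats import binom

    beta = binom.sf(np.arange(n), n, ranks)
    p = np.minimum(1.0, beta.min(axis=1) * n)
    assert (p < 0.05).mean() <= 0.0625


def test_mean_fold_change_ignores_missing():
    tables = [
        FoldChangeTable("A", pd.Series({"x": 2.0, "y": 0.0})),
        FoldChangeTable("B", pd.Series({"x": 4.0})),
    ]
    m = mean_fold_change(tables)
    assert m["x"] == pytest.approx(3.0) and m["y"] == pytest.approx(0.0)
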