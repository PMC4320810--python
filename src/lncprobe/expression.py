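"""Cross-dataset integration of LPS-stimulation expression changes.

Per-dataset probe matrices (log2 intensities, unstimulated vs LPS columns)
are KNN-imputed, collapsed to transcript level through the probe
reannotation, and reduced to one log2 fold change per transcript. Fold
changes are then integrated across datasets with robust rank aggregation
(RRA): within each dataset the transcripts are ranked by fold change
(descending for the up direction, ascending for down) and the rank is
normalized by that dataset's list length. For a transcript observed in n
datasets with sorted normalized ranks r(1) <= ... <= r(n), each order
statistic is scored against the uniform null,

    beta_k = P(Binomial(n, r(k)) >= k),

and the rank score is rho = min_k beta_k. The per-transcript p-value is
min(1, rho * n) (a Bonferroni bound over the n order statistics), and the
reported significance is Bonferroni-adjusted again over the m transcripts
tested in that direction. rho (the "aggregation rank score") is what the
heatmap orderings plot as +/- log10.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Probe-level log2 intensity matrix for one dataset.

    `values` is probes x samples with NaN marking missing cells; `conditions`
    maps each sample column to 'unstim' or 'LPS'.
    """

    platform: str
    values: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self):
        unknown = set(self.conditions.values()) - {"unstim", "LPS"}
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        missing = [c for c in self.values.columns if c not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        for cond in ("unstim", "LPS"):
            if not any(v == cond for v in self.conditions.values()):
                raise ValueError(f"no sample labelled {cond}")


@dataclass
class FoldChangeTable:
    """Per-dataset transcript-level log2 fold changes (LPS minus unstimulated)."""

    dataset_id: str
    entries: pd.Series  # index: transcript_id, values: log2fc

    @property
    def n_listed(self) -> int:
        return int(self.entries.size)


@dataclass
class AggregationResult:
    transcript_id: str
    direction: str  # 'up' or 'down'
    rho: float
    p: float
    p_adj: float
    n_datasets: int
    normalized_ranks: tuple[float, ...]


def knn_impute(mat: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing cells with the mean of the k nearest probes' values.

    Nearest probes are found by Euclidean distance over shared observed
    columns (nan-Euclidean). Observed cells are returned unchanged. A column
    with no observed value is an error; k larger than the number of usable
    probe rows is truncated with a warning.
    """
    values = mat.values
    if values.isna().all(axis=None):
        raise ValueError("matrix is entirely missing")
    all_missing_cols = values.columns[values.isna().all(axis=0)]
    if len(all_missing_cols):
        raise ValueError(f"columns with all values missing: {list(all_missing_cols)}")
    if not values.isna().any(axis=None):
        return mat
    usable = int((~values.isna()).any(axis=1).sum()) - 1
    if k > max(usable, 1):
        logger.warning("k=%d exceeds usable rows; truncated to %d", k, max(usable, 1))
        k = max(usable, 1)
    from sklearn.impute import KNNImputer

    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputed = imputer.fit_transform(values.to_numpy(dtype=float))
    out = pd.DataFrame(imputed, index=values.index, columns=values.columns)
    return ExpressionMatrix(mat.platform, out, dict(mat.conditions))


def collapse_to_transcripts(mat: ExpressionMatrix,
                            assignments: pd.DataFrame) -> pd.DataFrame:
    """Average probe rows mapping to the same transcript; drop unassigned probes.

    `assignments` needs columns probe_id/platform/target_id (the probe
    reannotation table); only this matrix's platform is used.
    """
    plat = assignments.loc[
        assignments["platform"] == mat.platform, ["probe_id", "target_id"]
    ]
    # a probe may carry one lncRNA and one coding assignment; it then
    # contributes to both targets
    merged = plat.merge(
        mat.values, left_on="probe_id", right_index=True, how="inner"
    ).drop(columns="probe_id")
    if merged.empty:
        return pd.DataFrame(columns=mat.values.columns)
    return merged.groupby("target_id").mean()


def log2_fold_change(transcript_matrix: pd.DataFrame,
                     conditions: dict[str, str],
                     dataset_id: str) -> FoldChangeTable:
    """mean(LPS) - mean(unstim) per transcript, on log2 intensities."""
    lps_cols = [c for c in transcript_matrix.columns if conditions[c] == "LPS"]
    un_cols = [c for c in transcript_matrix.columns if conditions[c] == "unstim"]
    if not lps_cols or not un_cols:
        raise ValueError("both condition groups must be non-empty")
    fc = transcript_matrix[lps_cols].mean(axis=1) - transcript_matrix[un_cols].mean(axis=1)
    fc = fc.dropna()
    return FoldChangeTable(dataset_id=dataset_id, entries=fc)


def rho_score(ranks: np.ndarray) -> float:
    """RRA rank score: min over k of P(Binomial(n, r(k)) >= k), ranks sorted ascending."""
    r = np.sort(np.asarray(ranks, dtype=float))
    n = r.size
    if n == 0:
        raise ValueError("empty rank vector")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    k = np.arange(1, n + 1)
    beta = stats.binom.sf(k - 1, n, r)
    return float(np.min(beta))


def normalized_ranks(table: FoldChangeTable, direction: str) -> pd.Series:
    """Per-dataset normalized ranks in (0, 1]; average ranks on ties."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    values = table.entries
    # descending fold change ranks first for 'up'; ascending for 'down'
    scores = -values if direction == "up" else values
    ranks = stats.rankdata(scores.to_numpy(), method="average")
    return pd.Series(ranks / table.n_listed, index=values.index)


def rra_aggregate(tables: list[FoldChangeTable], direction: str) -> list[AggregationResult]:
    """Robust rank aggregation of per-dataset fold-change rankings.

    Transcripts absent from a dataset simply contribute no rank there; n is
    the number of datasets where the transcript is measured. Results are
    sorted by adjusted p-value (the aggregated ranking).
    """
    if not tables:
        raise ValueError("at least one fold-change table required")
    per_transcript: dict[str, list[float]] = {}
    for table in tables:
        for tid, r in normalized_ranks(table, direction).items():
            per_transcript.setdefault(tid, []).append(float(r))
    m = len(per_transcript)
    results = []
    for tid, ranks in per_transcript.items():
        r = np.sort(np.array(ranks))
        rho = rho_score(r)
        p = min(1.0, rho * r.size)
        results.append(
            AggregationResult(
                transcript_id=tid, direction=direction, rho=rho, p=p,
                p_adj=min(1.0, p * m), n_datasets=r.size,
                normalized_ranks=tuple(r),
            )
        )
    results.sort(key=lambda a: (a.p_adj, a.rho, a.transcript_id))
    return results


def call_regulated(up_results: list[AggregationResult],
                   down_results: list[AggregationResult],
                   alpha: float = 0.05) -> tuple[list[AggregationResult], list[AggregationResult]]:
    """Transcripts with Bonferroni-adjusted p < alpha in each direction.

    A transcript significant in both directions (pathological) is assigned to
    the direction with the smaller adjusted p, with a warning.
    """
    up = {a.transcript_id: a for a in up_results if a.p_adj < alpha}
    down = {a.transcript_id: a for a in down_results if a.p_adj < alpha}
    both = set(up) & set(down)
    for tid in both:
        warnings.warn(f"transcript {tid} significant in both directions")
        if up[tid].p_adj <= down[tid].p_adj:
            del down[tid]
        else:
            del up[tid]
    return sorted(up.values(), key=lambda a: a.p_adj), sorted(
        down.values(), key=lambda a: a.p_adj
    )


def results_to_frame(results: list[AggregationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id, "direction": a.direction,
                "rho": a.rho, "p": a.p, "p_adj": a.p_adj,
                "n_datasets": a.n_datasets,
                "ar_score_log10": (-1 if a.direction == "up" else 1) * np.log10(max(a.rho, 1e-300)),
            }
            for a in results
        ]
    )


def fold_change_correlation(tables: list[FoldChangeTable],
                            min_shared: int = 10) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-dataset fold changes on shared transcripts.

    Pairs sharing fewer than `min_shared` transcripts get NaN.
    """
    ids = [t.dataset_id for t in tables]
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i, a in enumerate(tables):
        for j, b in enumerate(tables):
            if j < i:
                continue
            shared = a.entries.index.intersection(b.entries.index)
            if len(shared) >= min_shared:
                r = stats.pearsonr(
                    a.entries.loc[shared].to_numpy(), b.entries.loc[shared].to_numpy()
                ).statistic
                mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat


def mean_fold_change(tables: list[FoldChangeTable]) -> pd.Series:
    """Mean log2 fold change per transcript over the datasets where it is measured."""
    df = pd.DataFrame({t.dataset_id: t.entries for t in tables})
    return df.mean(axis=1)
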