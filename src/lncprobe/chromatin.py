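"""Chromatin signal around lncRNA TSSs: enhancer-like vs promoter-like classification.

Signal for each histone mark / PolII is averaged over a window centered on
the lncRNA's primary TSS (default -2 kb .. +2 kb) and normalized to a
10-million-read library. The H3K4me1 : H3K4me3 density ratio at the TSS
separates enhancer-like lncRNAs (elncRNA, me1-high) from promoter-associated
lncRNAs (plncRNA, me3-high). Classification uses the unstimulated condition
by default; LPS stimulation barely moves the ratio.

A pseudo-density epsilon stabilizes the ratio at low coverage. With epsilon
proportional to the cohort's typical density, the label is invariant to a
common rescaling of both marks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._bedio import BedGraphTrack
from .catalog import LncRnaRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2_000
DEFAULT_RATIO_THRESHOLD = 1.0
DEFAULT_CHANGE_THRESHOLD = math.log2(1.5)
QUANT_MARKS = ("H3K4me3", "H3K4me1", "H3K27Ac", "PolII")


@dataclass(frozen=True)
class ChromatinCall:
    lnc_id: str
    ratio: float
    label: str  # 'elncRNA', 'plncRNA' or 'unclassified'


def quantify_window(coverage: BedGraphTrack, chrom: str, tss: int,
                    W: int = DEFAULT_WINDOW, library_size: float = 1e7) -> float:
    """Mean normalized per-base signal over [tss - W, tss + W).

    The window sum is scaled to a 10-million-read library and divided by the
    window width; windows truncated at the chromosome start use the truncated
    width. Unknown chromosomes give density 0 with a warning.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if chrom not in coverage.chroms:
        logger.warning("chromosome %s absent from coverage track", chrom)
        return 0.0
    start = max(0, tss - W)
    end = tss + W
    width = end - start
    total = coverage.window_sum(chrom, start, end)
    return total * (1e7 / library_size) / width


def quantify_catalog(records: list[LncRnaRecord],
                     tracks: dict[tuple[str, str], BedGraphTrack],
                     library_sizes: dict[tuple[str, str], float],
                     W: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Density per lncRNA for every (mark, condition) track, at the primary TSS."""
    rows = {}
    for (mark, condition), track in tracks.items():
        lib = library_sizes.get((mark, condition), 1e7)
        rows[f"{mark}_{condition}"] = [
            quantify_window(track, r.span.chrom, r.primary_tss, W, lib) for r in records
        ]
    df = pd.DataFrame(rows, index=[r.lnc_id for r in records])
    df.index.name = "lnc_id"
    return df


def classify_chromatin(me1_density: float, me3_density: float,
                       ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                       epsilon: float = 0.0) -> ChromatinCall:
    """elncRNA iff (me1 + eps) / (me3 + eps) > ratio_threshold, else plncRNA.

    Both densities zero -> 'unclassified'. A ratio exactly at the threshold is
    promoter-like (ties go to plncRNA).
    """
    if me1_density == 0 and me3_density == 0:
        return ChromatinCall("", float("nan"), "unclassified")
    ratio = (me1_density + epsilon) / (me3_density + epsilon)
    return ChromatinCall("", ratio, "elncRNA" if ratio > ratio_threshold else "plncRNA")


def cohort_epsilon(densities: pd.DataFrame, condition: str = "unstim",
                   fraction: float = 0.1) -> float:
    """Pseudo-density: `fraction` x median nonzero me1/me3 density in the cohort."""
    cols = [f"H3K4me1_{condition}", f"H3K4me3_{condition}"]
    vals = densities[cols].to_numpy().ravel()
    nonzero = vals[vals > 0]
    if nonzero.size == 0:
        return 0.0
    return fraction * float(np.median(nonzero))


def classify_catalog(records: list[LncRnaRecord], densities: pd.DataFrame,
                     ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
                     condition: str = "unstim",
                     epsilon: float | None = None) -> list[ChromatinCall]:
    """Label every catalog lncRNA elncRNA/plncRNA from its TSS densities.

    epsilon=None derives the pseudo-density from the cohort (cohort_epsilon).
    Labels are also written back onto the records' `chromatin_class`.
    """
    if epsilon is None:
        epsilon = cohort_epsilon(densities, condition)
    calls = []
    for rec in records:
        me1 = float(densities.at[rec.lnc_id, f"H3K4me1_{condition}"])
        me3 = float(densities.at[rec.lnc_id, f"H3K4me3_{condition}"])
        call = classify_chromatin(me1, me3, ratio_threshold, epsilon)
        call = ChromatinCall(rec.lnc_id, call.ratio, call.label)
        rec.chromatin_class = call.label
        calls.append(call)
    return calls


def ks_shift_test(sample: np.ndarray, reference: np.ndarray,
                  shift: str) -> tuple[float, float]:
    """One-sided two-sample KS test for a directional shift of `sample` vs `reference`.

    shift='right' tests the alternative that `sample` is stochastically
    greater than `reference`; shift='left' the reverse. Returns (D, p).
    """
    if shift not in ("right", "left"):
        raise ValueError("shift must be 'right' or 'left'")
    alternative = "less" if shift == "right" else "greater"
    res = stats.ks_2samp(sample, reference, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def mark_change_vs_expression(densities: pd.DataFrame,
                              expression_fc: pd.Series,
                              labels: dict[str, str],
                              change_threshold: float = DEFAULT_CHANGE_THRESHOLD,
                              marks: tuple[str, ...] = QUANT_MARKS,
                              epsilon: float | None = None,
                              min_group: int = 5) -> pd.DataFrame:
    """Relate mark density changes under LPS to expression changes, per mark and class.

    lncRNAs whose log2(density_LPS / density_unstim) exceeds +threshold form
    the 'increased' group, below -threshold the 'decreased' group. Each
    group's expression fold-change ECDF is compared to all lncRNAs of that
    chromatin class by a one-sided KS test: increased groups are tested for a
    right shift, decreased for a left shift (all four marks are activity
    marks). Groups smaller than `min_group` are reported with a low-n flag.
    """
    if epsilon is None:
        pooled = densities.to_numpy().ravel()
        nonzero = pooled[pooled > 0]
        epsilon = 0.1 * float(np.median(nonzero)) if nonzero.size else 1e-9
    rows = []
    for cls in ("elncRNA", "plncRNA"):
        ids = [i for i in densities.index if labels.get(i) == cls and i in expression_fc.index]
        if not ids:
            continue
        ref = expression_fc.loc[ids].to_numpy()
        for mark in marks:
            lps = densities.loc[ids, f"{mark}_LPS"].to_numpy()
            un = densities.loc[ids, f"{mark}_unstim"].to_numpy()
            change = np.log2((lps + epsilon) / (un + epsilon))
            for group_name, mask, shift in (
                ("increased", change > change_threshold, "right"),
                ("decreased", change < -change_threshold, "left"),
            ):
                group = expression_fc.loc[np.array(ids)[mask]].to_numpy()
                if group.size == 0:
                    d, p = float("nan"), float("nan")
                else:
                    d, p = ks_shift_test(group, ref, shift)
                if 0 < group.size < min_group:
                    logger.warning(
                        "%s/%s %s group has only %d members", cls, mark, group_name, group.size
                    )
                rows.append(
                    {
                        "chromatin_class": cls, "mark": mark, "group": group_name,
                        "n": int(group.size), "D": d, "p": p,
                        "low_n": bool(0 < group.size < min_group),
                    }
                )
    return pd.DataFrame(rows)


def regulation_class_table(up_ids: set[str], down_ids: set[str],
                           labels: dict[str, str]) -> pd.DataFrame:
    """2x2 table of up/down-regulated lncRNAs by elncRNA/plncRNA label."""
    table = pd.DataFrame(
        0, index=["up", "down"], columns=["elncRNA", "plncRNA"], dtype=int
    )
    for direction, ids in (("up", up_ids), ("down", down_ids)):
        for i in ids:
            lbl = labels.get(i)
            if lbl in ("elncRNA", "plncRNA"):
                table.at[direction, lbl] += 1
    return table


def chi_square_regulation(table: pd.DataFrame, correction: bool = False) -> tuple[float, float]:
    """Chi-square test of independence on the up/down x elnc/plnc table.

    No continuity correction by default (2x2 Yates correction available via
    `correction=True`). Returns (chi2, p).
    """
    res = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return float(res.statistic), float(res.pvalue)
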