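"""lncRNA-to-neighbor-gene relations and transcription-factor binding at lncRNA TSSs.

Neighbors are coding genes chosen by longest overlap (if overlapping) or
smallest gap. Co-expression compares the fold-change distribution of the
neighbors of LPS-changed lncRNAs against all coding genes. TF binding marks
a lncRNA as bound by a factor when at least one peak falls inside the
promoter-proximal window (-10 kb .. +10 kb around the primary TSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import GeneModel, TranscriptRecord
from .catalog import LncRnaRecord, choose_neighbor
from .chromatin import ks_shift_test

logger = logging.getLogger(__name__)

DEFAULT_TF_WINDOW = 10_000
CORE_TFS = ("p65", "IRF3", "JunB", "cJun")


@dataclass(frozen=True)
class NeighborPair:
    lnc_id: str
    gene_symbol: str
    distance: int  # bp; 0 iff overlapping
    lnc_log2fc: float
    gene_log2fc: float

    @property
    def sign_concordant(self) -> bool | None:
        if np.isnan(self.lnc_log2fc) or np.isnan(self.gene_log2fc):
            return None
        return bool(self.lnc_log2fc * self.gene_log2fc > 0)


def nearest_neighbor(lnc: TranscriptRecord, genes: list[GeneModel],
                     lnc_fc: float = float("nan"),
                     gene_fc: dict[str, float] | None = None) -> NeighborPair | None:
    """Neighbor pair for one lncRNA, or None if its chromosome has no coding gene."""
    gene, distance = choose_neighbor(lnc, genes)
    if gene is None:
        return None
    gfc = (gene_fc or {}).get(gene.gene_symbol, float("nan"))
    return NeighborPair(lnc.id, gene.gene_symbol, distance, lnc_fc, gfc)


def build_neighbor_pairs(records: list[LncRnaRecord], genes: list[GeneModel],
                         lnc_fc: pd.Series, gene_fc: pd.Series) -> pd.DataFrame:
    """Neighbor table for the catalog, with fold changes and sign concordance."""
    rows = []
    for rec in records:
        pair = nearest_neighbor(
            rec.span, genes,
            float(lnc_fc.get(rec.lnc_id, float("nan"))),
            gene_fc.to_dict(),
        )
        if pair is None:
            continue
        rows.append(
            {
                "lnc_id": pair.lnc_id,
                "gene_symbol": pair.gene_symbol,
                "distance": pair.distance,
                "lnc_log2fc": pair.lnc_log2fc,
                "gene_log2fc": pair.gene_log2fc,
                "sign_concordant": pair.sign_concordant,
                "position_class": rec.position_class,
                "chromatin_class": rec.chromatin_class,
            }
        )
    return pd.DataFrame(rows)


def gene_level_fold_change(transcript_fc: pd.Series,
                           transcript_to_gene: dict[str, str]) -> pd.Series:
    """Mean integrated fold change per gene over its coding transcripts."""
    df = pd.DataFrame({"fc": transcript_fc})
    df["gene"] = [transcript_to_gene.get(t) for t in df.index]
    df = df.dropna(subset=["gene"])
    return df.groupby("gene")["fc"].mean()


def neighbor_coexpression(pairs: pd.DataFrame, gene_fc_all: pd.Series,
                          changed_ids: set[str],
                          grouping: str = "chromatin_class",
                          min_group: int = 3) -> pd.DataFrame:
    """KS test of neighbor-gene fold changes (changed lncRNAs) vs all coding genes.

    For each group of `grouping` (chromatin or position class), the neighbors
    of LPS-changed lncRNAs in that group are compared to the full coding-gene
    fold-change distribution; upregulated and downregulated lncRNAs are tested
    separately for right and left shifts. Groups below `min_group` are skipped.
    """
    ref = gene_fc_all.dropna().to_numpy()
    rows = []
    changed = pairs[pairs["lnc_id"].isin(changed_ids)].dropna(subset=["gene_log2fc"])
    for group_value, grp in changed.groupby(grouping):
        for direction, mask, shift in (
            ("up", grp["lnc_log2fc"] > 0, "right"),
            ("down", grp["lnc_log2fc"] < 0, "left"),
        ):
            sel = grp[mask]
            if len(sel) < min_group:
                logger.warning(
                    "group %s/%s has %d members; skipped", group_value, direction, len(sel)
                )
                continue
            d, p = ks_shift_test(sel["gene_log2fc"].to_numpy(), ref, shift)
            rows.append(
                {
                    grouping: group_value, "direction": direction,
                    "n": len(sel), "D": d, "p": p,
                }
            )
    return pd.DataFrame(rows)


def distance_by_chromatin_class(pairs: pd.DataFrame) -> tuple[float, float]:
    """Two-sample t-test of elncRNA vs plncRNA neighbor distances.

    Restricted to intergenic and bidirectional lncRNAs, where distance is a
    genuine gap rather than 0 by construction.
    """
    sub = pairs[pairs["position_class"].isin(["intergenic", "bidirectional"])]
    e = sub.loc[sub["chromatin_class"] == "elncRNA", "distance"].to_numpy(float)
    p = sub.loc[sub["chromatin_class"] == "plncRNA", "distance"].to_numpy(float)
    if e.size < 2 or p.size < 2:
        return float("nan"), float("nan")
    res = stats.ttest_ind(e, p, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _peaks_in_window(peaks: dict[str, list[tuple[int, int]]], chrom: str,
                     lo: int, hi: int) -> list[tuple[int, int]]:
    return [(s, e) for s, e in peaks.get(chrom, ()) if s < hi and lo < e]


def associate_tf_peaks(records: list[LncRnaRecord],
                       tf_peak_sets: dict[tuple[str, str], dict[str, list[tuple[int, int]]]],
                       window: int = DEFAULT_TF_WINDOW,
                       core_tfs: tuple[str, ...] = CORE_TFS,
                       venn_condition: str = "LPS") -> tuple[pd.DataFrame, dict]:
    """TF binding flags per lncRNA plus co-binding summaries.

    Returns a long table (lnc_id, tf, condition, bound, n_peaks,
    nearest_summit) and a summary with: Venn cell counts over the core TFs in
    `venn_condition`, the number of lncRNAs bound by >= 1 core TF, the mean
    pairwise distance between different TFs' nearest peak summits on co-bound
    lncRNAs, and the fraction of Bcl6-bound lncRNAs (per condition) whose
    binding colocalizes with >= 1 core TF after LPS.
    """
    rows = []
    bound_map: dict[tuple[str, str, str], tuple[int, ...]] = {}
    for rec in records:
        lo = rec.primary_tss - window
        hi = rec.primary_tss + window
        for (tf, condition), peaks in tf_peak_sets.items():
            hits = _peaks_in_window(peaks, rec.span.chrom, lo, hi)
            summits = tuple(sorted((s + e) // 2 for s, e in hits))
            if hits:
                bound_map[(rec.lnc_id, tf, condition)] = summits
            nearest = (
                min(summits, key=lambda x: abs(x - rec.primary_tss)) if summits else None
            )
            rows.append(
                {
                    "lnc_id": rec.lnc_id, "tf": tf, "condition": condition,
                    "bound": bool(hits), "n_peaks": len(hits),
                    "nearest_summit": nearest,
                }
            )
    binding = pd.DataFrame(rows)

    present_core = [
        tf for tf in core_tfs if any(k[0] == tf for k in tf_peak_sets)
    ]
    for tf in core_tfs:
        if tf not in present_core:
            logger.warning("TF %s has no peak file; omitted from summaries", tf)

    venn: dict[str, int] = {}
    bound_by_any = 0
    summit_distances = []
    for rec in records:
        bound_tfs = tuple(
            tf for tf in present_core if (rec.lnc_id, tf, venn_condition) in bound_map
        )
        if bound_tfs:
            bound_by_any += 1
            key = "+".join(bound_tfs)
            venn[key] = venn.get(key, 0) + 1
        for tf_a, tf_b in combinations(bound_tfs, 2):
            sa = bound_map[(rec.lnc_id, tf_a, venn_condition)]
            sb = bound_map[(rec.lnc_id, tf_b, venn_condition)]
            na = min(sa, key=lambda x: abs(x - rec.primary_tss))
            nb = min(sb, key=lambda x: abs(x - rec.primary_tss))
            summit_distances.append(abs(na - nb))

    per_tf_counts = {
        tf: sum(
            1 for rec in records if (rec.lnc_id, tf, venn_condition) in bound_map
        )
        for tf in present_core
    }

    bcl6_coloc = {}
    if any(k[0] == "Bcl6" for k in tf_peak_sets):
        for condition in sorted({c for (tf, c) in tf_peak_sets if tf == "Bcl6"}):
            bcl6_bound = [
                rec.lnc_id
                for rec in records
                if (rec.lnc_id, "Bcl6", condition) in bound_map
            ]
            if not bcl6_bound:
                bcl6_coloc[condition] = float("nan")
                continue
            coloc = sum(
                any((lnc, tf, "LPS") in bound_map for tf in present_core)
                for lnc in bcl6_bound
            )
            bcl6_coloc[condition] = coloc / len(bcl6_bound)

    summary = {
        "venn": venn,
        "bound_by_any_core": bound_by_any,
        "bound_by_all_core": venn.get("+".join(present_core), 0),
        "per_tf_counts": per_tf_counts,
        "mean_pairwise_summit_distance": (
            float(np.mean(summit_distances)) if summit_distances else float("nan")
        ),
        "bcl6_colocalization": bcl6_coloc,
        "window": window,
        "venn_condition": venn_condition,
    }
    return binding, summary


def tf_target_expression_shift(binding: pd.DataFrame, lnc_fc: pd.Series,
                               condition: str = "LPS") -> pd.DataFrame:
    """Two-sided KS of integrated fold changes: each TF's targets vs all lncRNAs."""
    ref = lnc_fc.dropna().to_numpy()
    rows = []
    for tf, grp in binding[binding["condition"] == condition].groupby("tf"):
        targets = grp.loc[grp["bound"], "lnc_id"]
        vals = lnc_fc.reindex(targets).dropna().to_numpy()
        if vals.size < 3:
            continue
        res = stats.ks_2samp(vals, ref)
        rows.append(
            {"tf": tf, "n_targets": int(vals.size), "D": float(res.statistic),
             "p": float(res.pvalue)}
        )
    return pd.DataFrame(rows)
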