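"""Validated lncRNA catalog: TSS evidence, chromatin filtering, classification, naming.

A probe-derived lncRNA candidate enters the catalog only if at least one
clustered TSS region survives three filters:

1. association — same-strand TSS regions intersecting the lncRNA span extended
   by `flank` (default 30 kb) on both sides;
2. chromatin — the TSS region must be overlapped by at least one peak of
   H3K4me3, H3K4me1 or PolII in either stimulation condition (H3K27Ac is
   deliberately not part of this filter);
3. ambiguity — TSS regions intersecting a coding-gene TSS region (coding 5'
   ends extended by `ambiguity_window` per side) are removed, since they may
   belong to the neighboring coding promoter.

Surviving lncRNAs are classified by position relative to their neighboring
coding gene (exonic sense / intronic sense / antisense / bidirectional /
intergenic) and renamed after that neighbor (lncRNA-<symbol>).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotations import AnnotationSet, GeneModel, TranscriptRecord, coding_gene_models
from .tss import TssRegion

logger = logging.getLogger(__name__)

CHROMATIN_FILTER_MARKS = ("H3K4me3", "H3K4me1", "PolII")
POSITION_CLASSES = (
    "exonic_sense", "intronic_sense", "antisense", "bidirectional", "intergenic",
)

DEFAULT_TSS_FLANK = 30_000
DEFAULT_AMBIGUITY_WINDOW = 500
DEFAULT_BIDIRECTIONAL_MAX = 1_000


@dataclass
class LncRnaRecord:
    """A validated lncRNA with its chosen TSS, positional class and display name."""

    lnc_id: str
    span: TranscriptRecord
    tss_regions: list[TssRegion]
    primary_tss: int
    position_class: str
    neighbor_gene: str | None
    neighbor_distance: int | None  # bp; 0 iff overlapping; None if no coding gene
    display_name: str
    chromatin_class: str = "unclassified"
    excluded_from_expression: bool = False


def _spans_intersect(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def associate_tss(lnc: TranscriptRecord, tss_regions: list[TssRegion],
                  flank: int = DEFAULT_TSS_FLANK,
                  same_strand: bool = True) -> list[TssRegion]:
    """Same-strand TSS regions intersecting [span.start - flank, span.end + flank)."""
    lo = max(0, lnc.start - flank)
    hi = lnc.end + flank
    out = []
    for region in tss_regions:
        if region.chrom != lnc.chrom:
            continue
        if same_strand and region.strand != lnc.strand:
            continue
        if _spans_intersect(lo, hi, region.start, region.end):
            out.append(region)
    return out


def filter_by_chromatin(candidate_tss: list[TssRegion],
                        peak_sets: dict[tuple[str, str], dict[str, list[tuple[int, int]]]],
                        window: int = 0,
                        marks: tuple[str, ...] = CHROMATIN_FILTER_MARKS,
                        missing_track: str = "skip") -> list[TssRegion]:
    """Keep TSS regions overlapped by >= 1 peak of the filter marks in either condition.

    Parameters
    ----------
    peak_sets
        Mapping (mark, condition) -> {chrom: [(start, end), ...]}.
    window
        Extension applied to each TSS region before overlap testing (default 0).
    missing_track
        'skip' ignores absent (mark, condition) tracks; 'abort' raises.
    """
    relevant = []
    for (mark, condition), peaks in peak_sets.items():
        if mark in marks:
            relevant.append(peaks)
    if not relevant:
        expected = {m for m in marks}
        present = {m for (m, _c) in peak_sets}
        if missing_track == "abort" or not peak_sets:
            raise ValueError(
                f"no peak tracks for filter marks {sorted(expected)} (present: {sorted(present)})"
            )
    if missing_track == "abort":
        for mark in marks:
            if not any(m == mark for (m, _c) in peak_sets):
                raise ValueError(f"missing peak track for mark {mark}")

    kept = []
    for region in candidate_tss:
        lo, hi = region.start - window, region.end + window
        hit = False
        for peaks in relevant:
            for p0, p1 in peaks.get(region.chrom, ()):
                if _spans_intersect(lo, hi, p0, p1):
                    hit = True
                    break
            if hit:
                break
        if hit:
            kept.append(region)
    return kept


def coding_tss_regions(annots: AnnotationSet,
                       ambiguity_window: int = DEFAULT_AMBIGUITY_WINDOW
                       ) -> dict[str, list[tuple[int, int]]]:
    """Intervals around coding transcript 5' ends: [tss - w, tss + w + 1) per chrom."""
    out: dict[str, list[tuple[int, int]]] = {}
    for t in annots.coding():
        tss = t.tss
        out.setdefault(t.chrom, []).append(
            (max(0, tss - ambiguity_window), tss + ambiguity_window + 1)
        )
    return {c: sorted(iv) for c, iv in out.items()}


def exclude_ambiguous_tss(lnc_tss: list[TssRegion],
                          coding_tss: dict[str, list[tuple[int, int]]]) -> list[TssRegion]:
    """Remove lncRNA TSS regions intersecting any coding-gene TSS region (any strand)."""
    kept = []
    for region in lnc_tss:
        ambiguous = any(
            _spans_intersect(region.start, region.end, c0, c1)
            for c0, c1 in coding_tss.get(region.chrom, ())
        )
        if not ambiguous:
            kept.append(region)
    return kept


def _overlap_len(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def choose_neighbor(lnc: TranscriptRecord,
                    genes: list[GeneModel]) -> tuple[GeneModel | None, int | None]:
    """Neighbor coding gene: longest overlap if any overlaps, else nearest gap.

    Ties broken by smaller gene start. Returns (gene, distance) with distance 0
    iff overlapping, or (None, None) when the chromosome has no coding gene.
    """
    same_chrom = [g for g in genes if g.chrom == lnc.chrom]
    if not same_chrom:
        return None, None
    overlapping = [
        (g, _overlap_len(lnc.start, lnc.end, g.start, g.end))
        for g in same_chrom
        if _spans_intersect(lnc.start, lnc.end, g.start, g.end)
    ]
    if overlapping:
        best = max(overlapping, key=lambda t: (t[1], -t[0].start))
        return best[0], 0
    gaps = [
        (g, g.start - lnc.end if g.start >= lnc.end else lnc.start - g.end)
        for g in same_chrom
    ]
    best = min(gaps, key=lambda t: (t[1], t[0].start))
    return best[0], best[1]


def classify_position(lnc: TranscriptRecord, genes: list[GeneModel],
                      bidirectional_max: int = DEFAULT_BIDIRECTIONAL_MAX,
                      bidirectional_metric: str = "gene",
                      ) -> tuple[str, GeneModel | None, int | None]:
    """Position class of a lncRNA relative to its neighbor coding gene.

    Rule table, applied to the neighbor chosen by `choose_neighbor`:
    overlapping + same strand + any exon overlap -> exonic_sense;
    overlapping + same strand, introns only     -> intronic_sense;
    overlapping + opposite strand               -> antisense;
    non-overlapping + opposite strand + close   -> bidirectional;
    otherwise                                   -> intergenic.

    "Close" is distance < `bidirectional_max` (default 1 kb), measured as the
    gap between nearest feature ends (`bidirectional_metric='gene'`) or between
    the lncRNA TSS and the gene TSS (`bidirectional_metric='tss'`).
    """
    gene, distance = choose_neighbor(lnc, genes)
    if gene is None:
        return "intergenic", None, None
    if distance == 0:
        if lnc.strand == gene.strand:
            exon_overlap = any(
                _overlap_len(lnc.start, lnc.end, e0, e1) > 0 for e0, e1 in gene.exons
            )
            return ("exonic_sense" if exon_overlap else "intronic_sense"), gene, 0
        return "antisense", gene, 0
    if lnc.strand != gene.strand:
        if bidirectional_metric == "tss":
            metric = abs(lnc.tss - gene.tss)
        else:
            metric = distance
        if metric < bidirectional_max:
            return "bidirectional", gene, distance
    return "intergenic", gene, distance


def name_lncrnas(records: list[LncRnaRecord]) -> None:
    """Assign display names lncRNA-<neighbor symbol>, suffixing collisions in place."""
    counts: dict[str, int] = {}
    for rec in sorted(records, key=lambda r: (r.span.chrom, r.span.start, r.lnc_id)):
        if rec.neighbor_gene is None:
            rec.display_name = rec.lnc_id
            continue
        base = f"lncRNA-{rec.neighbor_gene}"
        n = counts.get(base, 0) + 1
        counts[base] = n
        rec.display_name = base if n == 1 else f"{base}-{n}"


def build_catalog(lnc_candidates: list[TranscriptRecord],
                  tss_regions: list[TssRegion],
                  annots: AnnotationSet,
                  peak_sets: dict[tuple[str, str], dict[str, list[tuple[int, int]]]],
                  flank: int = DEFAULT_TSS_FLANK,
                  ambiguity_window: int = DEFAULT_AMBIGUITY_WINDOW,
                  bidirectional_max: int = DEFAULT_BIDIRECTIONAL_MAX,
                  bidirectional_metric: str = "gene",
                  tss_same_strand: bool = True,
                  chromatin_window: int = 0,
                  exclude_exonic_sense: bool = True,
                  ) -> tuple[list[LncRnaRecord], dict[str, int]]:
    """Run the TSS/chromatin/ambiguity filters and classify surviving lncRNAs.

    Returns the catalog and a funnel dict with counts after each filter stage.
    `exclude_exonic_sense` flags exonic-sense records so downstream expression
    analyses skip them (they often represent UTR fragments of coding mRNAs).
    """
    genes = coding_gene_models(annots)
    coding_tss = coding_tss_regions(annots, ambiguity_window)

    funnel = {
        "candidates": len(lnc_candidates),
        "with_tss": 0,
        "after_chromatin": 0,
        "after_ambiguity": 0,
    }
    records: list[LncRnaRecord] = []
    for lnc in lnc_candidates:
        associated = associate_tss(lnc, tss_regions, flank, same_strand=tss_same_strand)
        if not associated:
            continue
        funnel["with_tss"] += 1
        supported = filter_by_chromatin(associated, peak_sets, window=chromatin_window)
        if not supported:
            continue
        funnel["after_chromatin"] += 1
        unambiguous = exclude_ambiguous_tss(supported, coding_tss)
        if not unambiguous:
            continue
        funnel["after_ambiguity"] += 1
        best = max(unambiguous, key=lambda r: (r.tag_count, -r.start))
        pclass, gene, distance = classify_position(
            lnc, genes, bidirectional_max, bidirectional_metric
        )
        records.append(
            LncRnaRecord(
                lnc_id=lnc.id,
                span=lnc,
                tss_regions=unambiguous,
                primary_tss=best.midpoint,
                position_class=pclass,
                neighbor_gene=gene.gene_symbol if gene else None,
                neighbor_distance=distance,
                display_name=lnc.id,
                excluded_from_expression=(
                    exclude_exonic_sense and pclass == "exonic_sense"
                ),
            )
        )
    name_lncrnas(records)
    for cls in POSITION_CLASSES:
        funnel[f"class_{cls}"] = sum(r.position_class == cls for r in records)
    return records, funnel


def catalog_to_frame(records: list[LncRnaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": r.lnc_id,
                "display_name": r.display_name,
                "chrom": r.span.chrom,
                "start": r.span.start,
                "end": r.span.end,
                "strand": r.span.strand,
                "primary_tss": r.primary_tss,
                "n_tss_regions": len(r.tss_regions),
                "tss_tag_count": max(t.tag_count for t in r.tss_regions),
                "position_class": r.position_class,
                "chromatin_class": r.chromatin_class,
                "neighbor_gene": r.neighbor_gene,
                "neighbor_distance": r.neighbor_distance,
                "excluded_from_expression": r.excluded_from_expression,
            }
            for r in sorted(records, key=lambda r: (r.span.chrom, r.span.start))
        ]
    )
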