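"""Reannotation of microarray probes to lncRNA candidates and coding genes.

Each probe (one best genomic alignment per platform) is intersected with the
exonic intervals of lncRNA candidates and of coding transcripts. A probe that
hits exactly one lncRNA gene yields a lncRNA assignment; exactly one coding
gene, a coding assignment. Probes hitting several distinct genes of the same
kind are dropped to avoid cross-hybridization ambiguity. Ambiguity is judged
at gene level (via gene_symbol), so a probe covering two isoforms of one gene
is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._bedio import Bed6Record, read_bed6
from .annotations import AnnotationSet, TranscriptRecord, lncrna_candidates

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProbeAlignment:
    """Best genomic alignment of one microarray probe."""

    probe_id: str
    platform: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"probe {self.probe_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"probe {self.probe_id}: invalid strand")


@dataclass(frozen=True)
class ProbeAssignment:
    probe_id: str
    platform: str
    target_id: str
    target_kind: str  # 'lncRNA' or 'coding'
    gene_symbol: str


def read_probe_bed6(path, platform: str) -> list[ProbeAlignment]:
    return [
        ProbeAlignment(r.name, platform, r.chrom, r.start, r.end, r.strand)
        for r in read_bed6(path)
    ]


def _exonic_hits(probe: ProbeAlignment, annots: AnnotationSet,
                 strand: str | None, min_overlap_bp: int):
    """Transcripts with >= min_overlap_bp of exon overlap with the probe."""
    hits = []
    for t in annots.query_exons(probe.chrom, probe.start, probe.end, strand):
        ov = sum(
            max(0, min(e1, probe.end) - max(e0, probe.start)) for e0, e1 in t.exons
        )
        if ov >= min_overlap_bp:
            hits.append(t)
    return hits


def assign_probes(probes: list[ProbeAlignment], annots: AnnotationSet,
                  require_same_strand: bool = True,
                  min_overlap_bp: int = 1) -> list[ProbeAssignment]:
    """Intersect probes with exonic intervals and keep unambiguous assignments.

    Returns at most one lncRNA and one coding assignment per probe; a probe
    overlapping multiple distinct genes of the same kind is removed for that
    kind. Probes on chromosomes absent from the annotation are unassigned.
    """
    candidate_ids = {t.id for t in lncrna_candidates(annots)}
    assignments: list[ProbeAssignment] = []
    for probe in probes:
        strand = probe.strand if require_same_strand else None
        hits = _exonic_hits(probe, annots, strand, min_overlap_bp)
        lnc_hits = [t for t in hits if t.id in candidate_ids]
        coding_hits = [t for t in hits if t.biotype == "coding"]
        for kind, kind_hits in (("lncRNA", lnc_hits), ("coding", coding_hits)):
            genes = {t.gene_symbol for t in kind_hits}
            if len(genes) == 1:
                # multiple isoforms of one gene: keep, pick the longest-overlap isoform
                best = max(
                    kind_hits,
                    key=lambda t: (
                        sum(
                            max(0, min(e1, probe.end) - max(e0, probe.start))
                            for e0, e1 in t.exons
                        ),
                        t.id,
                    ),
                )
                assignments.append(
                    ProbeAssignment(
                        probe.probe_id, probe.platform, best.id, kind, best.gene_symbol
                    )
                )
    return assignments


def summarize_reannotation(assignments: list[ProbeAssignment]) -> pd.DataFrame:
    """Per-platform counts of lncRNA probes, coding probes and unique lncRNA targets."""
    rows = []
    platforms = sorted({a.platform for a in assignments})
    for platform in platforms:
        plat = [a for a in assignments if a.platform == platform]
        rows.append(
            {
                "platform": platform,
                "lncRNA_probes": sum(a.target_kind == "lncRNA" for a in plat),
                "coding_probes": sum(a.target_kind == "coding" for a in plat),
                "unique_lncRNAs": len(
                    {a.target_id for a in plat if a.target_kind == "lncRNA"}
                ),
                "unique_coding_genes": len(
                    {a.gene_symbol for a in plat if a.target_kind == "coding"}
                ),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "platform", "lncRNA_probes", "coding_probes",
            "unique_lncRNAs", "unique_coding_genes",
        ],
    )
    total_unique = len({a.target_id for a in assignments if a.target_kind == "lncRNA"})
    df.attrs["unique_lncRNAs_all_platforms"] = total_unique
    return df


def assignments_to_frame(assignments: list[ProbeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": a.probe_id, "platform": a.platform,
                "target_id": a.target_id, "target_kind": a.target_kind,
                "gene_symbol": a.gene_symbol,
            }
            for a in assignments
        ],
        columns=["probe_id", "platform", "target_id", "target_kind", "gene_symbol"],
    )
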