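"""Transcript annotation ingestion, merging and interval queries.

Annotations arrive as BED12 (0-based half-open) or GTF (1-based closed,
converted here), are partitioned into coding genes and lncRNA candidates,
and are served through a strand-aware interval index.

A noncoding transcript is a lncRNA candidate only if its spliced (exonic)
length is at least 200 nt; the length rule applies to the mature transcript,
not the genomic span. Records identical in (chrom, start, end, strand, exon
structure) across sources are merged, keeping every source label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from ._bedio import ParseError, iter_bed12, write_bed12

logger = logging.getLogger(__name__)

MIN_LNCRNA_LENGTH = 200

_KNOWN_SOURCES = {"refseq", "ucsc", "fantom", "ensembl", "synthetic"}
_CODING_TOKENS = {"coding", "protein_coding", "mrna", "cds"}
_NONCODING_TOKENS = {"noncoding", "non_coding", "lncrna", "lincrna", "ncrna", "antisense"}


@dataclass(frozen=True)
class TranscriptRecord:
    """A genomic transcript with exon structure, strand and coding/noncoding label."""

    id: str
    source: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str
    gene_symbol: str
    extra_sources: tuple[str, ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: invalid strand {self.strand!r}")
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"{self.id}: biotype must be coding/noncoding")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        prev_end = None
        for e0, e1 in exons:
            if e0 >= e1 or e0 < self.start or e1 > self.end:
                raise ValueError(f"{self.id}: exon [{e0},{e1}) outside [{self.start},{self.end})")
            if prev_end is not None and e0 < prev_end:
                raise ValueError(f"{self.id}: overlapping exons")
            prev_end = e1
        object.__setattr__(self, "exons", exons)

    @property
    def spliced_length(self) -> int:
        return sum(e1 - e0 for e0, e1 in self.exons)

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def sources(self) -> tuple[str, ...]:
        return (self.source, *self.extra_sources)

    def dedup_key(self):
        return (self.chrom, self.start, self.end, self.strand, self.exons)


class AnnotationSet:
    """Merged transcript collection with strand-aware interval indexes.

    Two indexes are kept: one over transcript spans and one over exons, each
    queryable with or without strand restriction.
    """

    def __init__(self, transcripts: Iterable[TranscriptRecord]):
        self.transcripts: list[TranscriptRecord] = list(transcripts)
        self._by_id = {}
        self._span_trees: dict[tuple[str, str], IntervalTree] = {}
        self._exon_trees: dict[tuple[str, str], IntervalTree] = {}
        for t in self.transcripts:
            if t.id in self._by_id:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            self._by_id[t.id] = t
            self._span_trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
                t.start, t.end, t
            )
            exon_tree = self._exon_trees.setdefault((t.chrom, t.strand), IntervalTree())
            for e0, e1 in t.exons:
                exon_tree.addi(e0, e1, t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def get(self, transcript_id: str) -> TranscriptRecord:
        return self._by_id[transcript_id]

    def _query(self, trees, chrom, start, end, strand):
        strands = (strand,) if strand else ("+", "-")
        hits = []
        for s in strands:
            tree = trees.get((chrom, s))
            if tree is not None:
                hits.extend(iv.data for iv in tree.overlap(start, end))
        return hits

    def query_span(self, chrom: str, start: int, end: int,
                   strand: str | None = None) -> list[TranscriptRecord]:
        """Transcripts whose genomic span intersects [start, end)."""
        seen, out = set(), []
        for t in self._query(self._span_trees, chrom, start, end, strand):
            if t.id not in seen:
                seen.add(t.id)
                out.append(t)
        return out

    def query_exons(self, chrom: str, start: int, end: int,
                    strand: str | None = None) -> list[TranscriptRecord]:
        """Transcripts with at least one exon intersecting [start, end)."""
        seen, out = set(), []
        for t in self._query(self._exon_trees, chrom, start, end, strand):
            if t.id not in seen:
                seen.add(t.id)
                out.append(t)
        return out

    def coding(self) -> list[TranscriptRecord]:
        return [t for t in self.transcripts if t.biotype == "coding"]

    def noncoding(self) -> list[TranscriptRecord]:
        return [t for t in self.transcripts if t.biotype == "noncoding"]

    def chroms(self) -> list[str]:
        return sorted({t.chrom for t in self.transcripts})


def _resolve_biotype(token: str, name: str) -> str | None:
    token_l = token.lower()
    if token_l in _CODING_TOKENS:
        return "coding"
    if token_l in _NONCODING_TOKENS:
        return "noncoding"
    # RefSeq convention: NR_* accessions are noncoding, NM_* coding.
    if name.startswith("NR_"):
        return "noncoding"
    if name.startswith("NM_"):
        return "coding"
    return None


def _records_from_bed12(path, source: str) -> tuple[list[TranscriptRecord], int]:
    records, skipped = [], 0
    for row in iter_bed12(path):
        name = row["name"]
        parts = name.split("|")
        # name convention: id|biotype|gene_symbol (biotype/symbol optional)
        tid = parts[0]
        token = parts[1] if len(parts) > 1 else ""
        symbol = parts[2] if len(parts) > 2 else tid
        biotype = _resolve_biotype(token, tid)
        if biotype is None:
            skipped += 1
            continue
        records.append(
            TranscriptRecord(
                id=tid, source=source, chrom=row["chrom"], start=row["start"],
                end=row["end"], strand=row["strand"], exons=tuple(row["exons"]),
                biotype=biotype, gene_symbol=symbol,
            )
        )
    return records, skipped


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for piece in attr.strip().split(";"):
        piece = piece.strip()
        if not piece:
            continue
        if " " in piece:
            key, value = piece.split(" ", 1)
            out[key] = value.strip().strip('"')
    return out


def _records_from_gtf(path, source: str) -> tuple[list[TranscriptRecord], int]:
    # Collect exon features per transcript_id; GTF is 1-based closed -> half-open here.
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 GTF fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"invalid strand {strand!r}")
            attrs = _parse_gtf_attributes(attr)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(path, lineno, "exon without transcript_id")
            exons.setdefault(tid, []).append((start_i, end_i))
            meta.setdefault(
                tid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "biotype_token": attrs.get("transcript_biotype", attrs.get("gene_biotype", "")),
                    "gene_symbol": attrs.get("gene_name", attrs.get("gene_id", tid)),
                },
            )
    records = []
    for tid, ex in exons.items():
        m = meta[tid]
        biotype = _resolve_biotype(m["biotype_token"], tid)
        if biotype is None:
            skipped += 1
            continue
        ex = sorted(ex)
        records.append(
            TranscriptRecord(
                id=tid, source=source, chrom=m["chrom"], start=ex[0][0], end=ex[-1][1],
                strand=m["strand"], exons=tuple(ex), biotype=biotype,
                gene_symbol=m["gene_symbol"],
            )
        )
    return records, skipped


def load_annotations(paths: Sequence, source_labels: Sequence[str],
                     formats: Sequence[str] | None = None) -> AnnotationSet:
    """Load and merge transcript annotations from multiple sources.

    Parameters
    ----------
    paths
        Annotation files, BED12 or GTF.
    source_labels
        One label per file (refseq/ucsc/fantom/ensembl/synthetic).
    formats
        Optional per-file format override ('bed12' or 'gtf'); inferred from the
        file suffix otherwise.

    Records identical in coordinates, strand and exon structure across files are
    deduplicated into a single record carrying all source labels. Records whose
    biotype cannot be resolved are skipped with a logged warning count.
    """
    if len(paths) != len(source_labels):
        raise ValueError("paths and source_labels differ in length")
    merged: dict[tuple, TranscriptRecord] = {}
    total_skipped = 0
    for i, (path, label) in enumerate(zip(paths, source_labels)):
        if label not in _KNOWN_SOURCES:
            raise ValueError(f"unknown source label {label!r}")
        fmt = formats[i] if formats else None
        if fmt is None:
            fmt = "gtf" if str(path).endswith((".gtf", ".gff", ".gff3")) else "bed12"
        if fmt == "gtf":
            records, skipped = _records_from_gtf(path, label)
        else:
            records, skipped = _records_from_bed12(path, label)
        total_skipped += skipped
        for rec in records:
            key = rec.dedup_key()
            if key in merged:
                prev = merged[key]
                if rec.source not in prev.sources:
                    merged[key] = replace(
                        prev, extra_sources=prev.extra_sources + (rec.source,)
                    )
            else:
                merged[key] = rec
    if total_skipped:
        logger.warning("skipped %d records with unresolvable biotype", total_skipped)
    return AnnotationSet(merged.values())


def lncrna_candidates(annots: AnnotationSet,
                      min_length: int = MIN_LNCRNA_LENGTH) -> list[TranscriptRecord]:
    """Noncoding transcripts whose spliced length is >= `min_length` (default 200 nt)."""
    return [t for t in annots.noncoding() if t.spliced_length >= min_length]


def short_noncoding(annots: AnnotationSet,
                    min_length: int = MIN_LNCRNA_LENGTH) -> list[TranscriptRecord]:
    """Noncoding transcripts excluded from the candidate set by the length rule."""
    return [t for t in annots.noncoding() if t.spliced_length < min_length]


@dataclass(frozen=True)
class GeneModel:
    """Gene-level view: union of a symbol's transcript spans and exons."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcript_ids: tuple[str, ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _merge_intervals(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def coding_gene_models(annots: AnnotationSet) -> list[GeneModel]:
    """Collapse coding transcripts into per-(symbol, chrom, strand) gene models."""
    groups: dict[tuple, list[TranscriptRecord]] = {}
    for t in annots.coding():
        groups.setdefault((t.gene_symbol, t.chrom, t.strand), []).append(t)
    genes = []
    for (symbol, chrom, strand), ts in groups.items():
        genes.append(
            GeneModel(
                gene_symbol=symbol, chrom=chrom,
                start=min(t.start for t in ts), end=max(t.end for t in ts),
                strand=strand,
                exons=_merge_intervals(
                    [(e0, e1) for t in ts for e0, e1 in t.exons]
                ),
                transcript_ids=tuple(sorted(t.id for t in ts)),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_symbol))
    return genes


def write_annotations_bed12(annots: AnnotationSet, path) -> None:
    """Serialize an AnnotationSet as BED12, preserving biotype and symbol in the name."""
    rows = []
    for t in sorted(annots, key=lambda t: (t.chrom, t.start, t.end, t.id)):
        rows.append(
            {
                "chrom": t.chrom, "start": t.start, "end": t.end,
                "name": f"{t.id}|{t.biotype}|{t.gene_symbol}",
                "score": 0, "strand": t.strand, "exons": list(t.exons),
            }
        )
    write_bed12(rows, path)
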