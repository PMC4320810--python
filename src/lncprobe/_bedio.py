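"""Light-weight readers/writers for the plain-text genomic formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention) in memory and on disk,
except GTF input which is converted at the reader boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised for malformed records; carries file and line context."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class Bed6Record:
    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str


def read_bed6(path) -> list[Bed6Record]:
    """Read a BED6 file (strand required)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(path, lineno, f"expected >=6 BED fields, got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if start_i >= end_i:
                raise ParseError(path, lineno, f"start {start_i} >= end {end_i}")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"invalid strand {strand!r}")
            try:
                score_f = float(score)
            except ValueError:
                score_f = 0.0
            records.append(Bed6Record(chrom, start_i, end_i, name, score_f, strand))
    return records


def write_bed6(records: Iterable[Bed6Record], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for r in records:
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def iter_bed12(path) -> Iterator[dict]:
    """Yield dicts for BED12 lines: chrom, start, end, name, score, strand, exons."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(path, lineno, f"expected 12 BED fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = fields[4]
                strand = fields[5]
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError:
                raise ParseError(path, lineno, "malformed numeric field") from None
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"invalid strand {strand!r}")
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ParseError(path, lineno, "block count does not match block lists")
            exons = [(start + bs, start + bs + sz) for bs, sz in zip(block_starts, block_sizes)]
            if any(e0 >= e1 for e0, e1 in exons):
                raise ParseError(path, lineno, "empty exon block")
            if exons[-1][1] > end:
                raise ParseError(path, lineno, "exon extends beyond transcript end")
            yield {
                "chrom": chrom, "start": start, "end": end, "name": name,
                "score": score, "strand": strand, "exons": exons,
                "lineno": lineno,
            }


def write_bed12(rows: Iterable[dict], path, header: str | None = None) -> None:
    """Write BED12; each row needs chrom/start/end/name/strand/exons, optional score/rgb."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for r in rows:
            exons = sorted(r["exons"])
            sizes = ",".join(str(e1 - e0) for e0, e1 in exons)
            starts = ",".join(str(e0 - r["start"]) for e0, e1 in exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r["chrom"], r["start"], r["end"], r["name"], r.get("score", 0),
                        r["strand"], r["start"], r["end"], r.get("rgb", "0,0,0"),
                        len(exons), sizes, starts,
                    )
                )
                + "\n"
            )


class BedGraphTrack:
    """Per-chromosome step-function coverage from a bedGraph file.

    Stores sorted, non-overlapping intervals; `window_sum` integrates signal over
    an arbitrary window, clipping at interval boundaries.
    """

    def __init__(self, per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._per_chrom = per_chrom

    @classmethod
    def read(cls, path) -> "BedGraphTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
        per_chrom = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            per_chrom[str(chrom)] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp["value"].to_numpy(),
            )
        return cls(per_chrom)

    @property
    def chroms(self) -> list[str]:
        return list(self._per_chrom)

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base signal over [start, end); 0.0 for unknown chromosomes."""
        if chrom not in self._per_chrom or end <= start:
            return 0.0
        starts, ends, values = self._per_chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.sum(ov * values[lo:hi]))

    def total_signal(self) -> float:
        return float(
            sum(np.sum((e - s) * v) for s, e, v in self._per_chrom.values())
        )


def write_bedgraph(intervals: Iterable[tuple[str, int, int, float]], path,
                   header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_peaks(path) -> dict[str, list[tuple[int, int]]]:
    """Read peak intervals from BED3+/narrowPeak; returns sorted intervals per chrom."""
    peaks: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            peaks.setdefault(fields[0], []).append((start, end))
    return {c: sorted(iv) for c, iv in peaks.items()}


def write_peaks(peaks: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(peaks):
            for start, end in sorted(peaks[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def write_tsv(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Write a TSV with an optional '#key=value' metadata header block."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)
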