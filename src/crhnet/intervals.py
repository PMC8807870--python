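"""Genomic coordinate primitives shared by every stage of the pipeline.

Coordinates are 0-based, half-open ``[start, end)`` throughout — the BED
convention. Overlap of ``[a, b)`` and ``[c, d)`` is ``min(b, d) - max(a, c)``
and adjacency (``b == c``) is *not* overlap. Strand is carried for promoters
but never consulted by overlap logic: peaks and chromatin contacts are
unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PromoterRecord",
    "ElementRecord",
    "read_intervals",
    "write_intervals",
    "read_gene_table",
    "make_promoters",
    "overlap_hits",
    "merge_intervals",
]


class IntervalParseError(ValueError):
    """A line of an interval file did not parse; carries the line number."""


@dataclass
class GenomicInterval:
    """Half-open interval on a chromosome, optionally named/stranded/scored."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str | None = None
    signal: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class PromoterRecord:
    """Promoter window centred on an annotated TSS (default 500 bp total)."""

    gene_id: str
    tss: int
    interval: GenomicInterval
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(
                f"TSS {self.tss} outside promoter window "
                f"[{self.interval.start}, {self.interval.end}) for {self.gene_id}"
            )


@dataclass
class ElementRecord:
    """A DNAse-accessible element with its activity (geometric-mean signal).

    ``element_class`` is ``"active"`` for elements retained as functional
    distal elements and ``"candidate"`` for accessible regions that never
    reach a functional connection.
    """

    interval: GenomicInterval
    dnase_signal: float = 0.0
    h3k27ac_signal: float = 0.0
    activity: float = 0.0
    element_class: str = "candidate"

    def __post_init__(self) -> None:
        if self.dnase_signal < 0 or self.h3k27ac_signal < 0:
            raise ValueError("signals must be nonnegative")
        if self.element_class not in ("active", "candidate"):
            raise ValueError(f"invalid element_class {self.element_class!r}")


_FORMAT_COLUMNS = {"BED": (3, 6), "narrowPeak": (10, 10), "bedGraph": (4, 4)}


def read_intervals(path: str | Path, format: str = "BED") -> list[GenomicInterval]:
    """Read BED/narrowPeak/bedGraph into sorted :class:`GenomicInterval` lists.

    Signal is taken from narrowPeak column 7 (signalValue) or bedGraph
    column 4. Output is sorted by (chrom, start).
    """
    if format not in _FORMAT_COLUMNS:
        raise ValueError(f"unknown format {format!r}")
    min_cols, _ = _FORMAT_COLUMNS[format]
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise IntervalParseError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IntervalParseError(f"{path}:{lineno}: {exc}") from None
            name = strand = None
            signal = None
            if format == "BED":
                if len(fields) >= 4:
                    name = fields[3] or None
                if len(fields) >= 6:
                    strand = fields[5]
            elif format == "narrowPeak":
                name = fields[3] or None
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
                signal = float(fields[6])
            else:  # bedGraph
                signal = float(fields[3])
            try:
                out.append(
                    GenomicInterval(chrom, start, end, id=name, strand=strand, signal=signal)
                )
            except ValueError as exc:
                raise IntervalParseError(f"{path}:{lineno}: {exc}") from None
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval], path: str | Path, format: str = "BED"
) -> None:
    """Write intervals back out; exact coordinate round-trip with read_intervals."""
    with open(path, "w") as fh:
        for iv in intervals:
            if format == "BED":
                cols = [iv.chrom, str(iv.start), str(iv.end)]
                if iv.id is not None or iv.strand is not None:
                    cols += [iv.id or ".", "0", iv.strand or "."]
                fh.write("\t".join(cols) + "\n")
            elif format == "bedGraph":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.signal or 0.0:g}\n")
            elif format == "narrowPeak":
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            str(iv.start),
                            str(iv.end),
                            iv.id or ".",
                            "0",
                            iv.strand or ".",
                            f"{iv.signal or 0.0:g}",
                            "-1",
                            "-1",
                            "-1",
                        ]
                    )
                    + "\n"
                )
            else:
                raise ValueError(f"unknown format {format!r}")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """TSV with header gene_id/chrom/strand/tss; 0-based TSS positions."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def make_promoters(genes: pd.DataFrame, width: int = 500) -> list[PromoterRecord]:
    """Symmetric promoter window of ``width`` bp around each TSS, clipped at 0."""
    if width <= 0 or width % 2 != 0:
        raise ValueError(f"width must be positive and even, got {width}")
    half = width // 2
    out = []
    for row in genes.itertuples(index=False):
        if pd.isna(row.tss):
            raise ValueError(f"gene {row.gene_id} has no TSS")
        tss = int(row.tss)
        start = max(0, tss - half)
        end = tss + half
        iv = GenomicInterval(str(row.chrom), start, end, id=str(row.gene_id),
                             strand=getattr(row, "strand", None))
        out.append(PromoterRecord(str(row.gene_id), tss, iv, strand=iv.strand))
    return out


def _interval_id(iv: GenomicInterval, index: int) -> str:
    return iv.id if iv.id is not None else str(index)


def overlap_hits(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[str, str, int]]:
    """All (query id, subject id, overlap bp) pairs with >= 1 bp overlap.

    Half-open arithmetic: touching intervals do not overlap. Ids fall back
    to the input index when an interval is unnamed.
    """
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(subject):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (j, iv))
    hits: list[tuple[str, str, int]] = []
    for i, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for node in sorted(tree.overlap(q.start, q.end)):
            j, s = node.data
            bp = min(q.end, s.end) - max(q.start, s.start)
            if bp >= 1:
                hits.append((_interval_id(q, i), _interval_id(s, j), bp))
    return hits


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge into a disjoint sorted set; intervals within ``gap`` bp are joined.

    With the default ``gap=0`` touching half-open intervals merge.
    Idempotent.
    """
    if gap < 0:
        raise ValueError(f"gap must be >= 0, got {gap}")
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + gap:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(merged[-1].chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged
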