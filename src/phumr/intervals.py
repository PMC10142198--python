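"""Genomic intervals and small interval utilities.

All coordinates are 0-based, half-open ``[start, end)``, the BED convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    m = _CHROM_RE.match(chrom)
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        return (1, {"X": 0, "Y": 1, "M": 2, "MT": 2}[body], "")
    return (2, 0, chrom)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (chrom_sort_key(iv.chrom), iv.start, iv.end))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or bookended runs are merged."""
    ivs = sort_intervals(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def read_bed(path) -> list[GenomicInterval]:
    """Read the first three columns of a BED file."""
    out = []
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return sort_intervals(out)


def write_bed(intervals: Sequence[GenomicInterval], path, names=None, scores=None) -> None:
    with open(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                row.append(str(names[i]))
                row.append(str(scores[i]) if scores is not None else "0")
                row.append(".")
            fh.write("\t".join(row) + "\n")
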