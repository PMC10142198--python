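"""Read, filter and assemble per-CpG WGBS methylation calls.

A methylome is represented as a table of CpG sites (one row per merged-strand
CpG) with methylated and total read counts; the methylation level is always
recomputed as ``meth / total`` and never trusted from the input file.
Coordinates are 0-based internally (``pos`` is the position of the C on the
forward strand of the CpG dinucleotide); the Bismark coverage dialect is
1-based inclusive and is shifted on input.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, chrom_sort_key

#: Chromosomes kept by default; everything else is treated as scaffold.
DEFAULT_CHROMS: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

SITE_COLUMNS = ["chrom", "pos", "meth", "total", "level"]


class ParseError(ValueError):
    """A methylation-call file could not be parsed; carries the line number."""


@dataclass(frozen=True)
class CpGSite:
    """One merged-strand CpG with its read counts."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position: {self}")
        if not (0 <= self.meth_reads <= self.total_reads):
            raise ValueError(f"invalid counts: {self}")
        if self.total_reads <= 0:
            raise ValueError(f"non-positive total reads: {self}")

    @property
    def level(self) -> float:
        return self.meth_reads / self.total_reads


@dataclass
class MethylomeSample:
    """One sample's per-CpG calls, sorted by (chrom, pos), unique positions.

    ``sites`` is a DataFrame with columns chrom, pos, meth, total, level.
    """

    sample_id: str
    cohort: str
    sites: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SITE_COLUMNS))

    def __post_init__(self) -> None:
        if self.cohort not in ("normal", "tumor"):
            raise ValueError(f"cohort must be 'normal' or 'tumor', got {self.cohort!r}")
        self.sites = _normalize_site_table(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def iter_sites(self) -> Iterable[CpGSite]:
        for row in self.sites.itertuples(index=False):
            yield CpGSite(row.chrom, int(row.pos), int(row.meth), int(row.total))


def _normalize_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    sites = sites.reset_index(drop=True)
    if len(sites) == 0:
        return pd.DataFrame(columns=SITE_COLUMNS)
    if (sites["meth"] < 0).any() or (sites["total"] <= 0).any():
        raise ValueError("negative or non-positive read counts")
    if (sites["meth"] > sites["total"]).any():
        raise ValueError("methylated count exceeds total count")
    dup = sites.duplicated(subset=["chrom", "pos"])
    if dup.any():
        row = sites[dup].iloc[0]
        raise ValueError(f"duplicate CpG site at {row['chrom']}:{row['pos']}")
    sites = sites.copy()
    sites["level"] = sites["meth"] / sites["total"]
    key = sites["chrom"].map(chrom_sort_key)
    order = sorted(range(len(sites)), key=lambda i: (key.iloc[i], sites["pos"].iloc[i]))
    sites = sites.iloc[order].reset_index(drop=True)
    sites["pos"] = sites["pos"].astype(np.int64)
    sites["meth"] = sites["meth"].astype(np.int64)
    sites["total"] = sites["total"].astype(np.int64)
    return sites[SITE_COLUMNS]


def read_methylation_calls(
    path,
    dialect: str = "bismark_cov",
    sample_id: str | None = None,
    cohort: str = "normal",
) -> MethylomeSample:
    """Read one sample's per-CpG calls.

    Dialects
    --------
    ``bismark_cov``
        chrom, start, end, percent-methylated, meth count, unmeth count;
        1-based inclusive coordinates (shifted to 0-based on input).
    ``bedgraph_counts``
        chrom, start, end, level, meth count, unmeth count; 0-based half-open.

    The level column of either dialect is ignored and recomputed from counts.
    """
    if dialect not in ("bismark_cov", "bedgraph_counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if sample_id is None:
        sample_id = str(path)
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return MethylomeSample(sample_id=sample_id, cohort=cohort)
    if raw.shape[1] < 6:
        raise ParseError(f"{path}: expected 6 columns, found {raw.shape[1]}")
    raw = raw.iloc[:, :6]
    raw.columns = ["chrom", "start", "end", "value", "meth", "unmeth"]
    for col in ("start", "meth", "unmeth"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: malformed row at line {line} (column {col!r})")
        raw[col] = converted.astype(np.int64)
    if (raw["meth"] < 0).any() or (raw["unmeth"] < 0).any():
        raise ValueError(f"{path}: negative read counts")
    pos = raw["start"] - 1 if dialect == "bismark_cov" else raw["start"]
    sites = pd.DataFrame(
        {
            "chrom": raw["chrom"],
            "pos": pos,
            "meth": raw["meth"],
            "total": raw["meth"] + raw["unmeth"],
        }
    )
    sites = sites[sites["total"] > 0].reset_index(drop=True)
    return MethylomeSample(sample_id=sample_id, cohort=cohort, sites=sites)


def write_cov(sample: MethylomeSample, path) -> None:
    """Write a sample in the Bismark coverage dialect (1-based inclusive)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for row in sample.sites.itertuples(index=False):
            pct = 100.0 * row.meth / row.total
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:.6g}\t"
                f"{row.meth}\t{row.total - row.meth}\n"
            )


def merge_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Merge per-strand CpG records into forward-strand CpG sites.

    ``records`` has columns chrom, pos, strand, meth, total. A reverse-strand
    record at position p+1 is paired with the forward-strand record at p and
    their counts are summed; unpaired records pass through at the forward C
    position. Total read count is conserved exactly.
    """
    required = {"chrom", "pos", "strand", "meth", "total"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    for strand in ("+", "-"):
        sub = records[records["strand"] == strand]
        if sub.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError(f"duplicate {strand}-strand record at the same position")
    shifted = records.copy()
    rev = shifted["strand"] == "-"
    shifted.loc[rev, "pos"] = shifted.loc[rev, "pos"] - 1
    merged = (
        shifted.groupby(["chrom", "pos"], as_index=False)[["meth", "total"]]
        .sum()
        .astype({"pos": np.int64})
    )
    return _normalize_site_table(merged.assign(level=merged["meth"] / merged["total"]))


def filter_sites(
    sample: MethylomeSample,
    min_reads: int = 5,
    main_chroms: Sequence[str] = DEFAULT_CHROMS,
) -> MethylomeSample:
    """Keep sites with strictly more than ``min_reads`` reads on whitelisted chromosomes."""
    keep = (sample.sites["total"] > min_reads) & sample.sites["chrom"].isin(set(main_chroms))
    return MethylomeSample(
        sample_id=sample.sample_id,
        cohort=sample.cohort,
        sites=sample.sites[keep].reset_index(drop=True),
    )


@dataclass
class MethylationMatrix:
    """CpG-site x sample methylation levels with a missing-value mask.

    ``sites`` has columns chrom, pos and (when built over regions) region_id;
    ``levels[i, j]`` is NaN where sample j did not detect site i.
    """

    sites: pd.DataFrame
    levels: np.ndarray
    sample_ids: list[str]
    cohorts: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def normal_idx(self) -> np.ndarray:
        return np.flatnonzero(self.cohorts == "normal")

    @property
    def tumor_idx(self) -> np.ndarray:
        return np.flatnonzero(self.cohorts == "tumor")

    def cohort_levels(self, cohort: str) -> np.ndarray:
        return self.levels[:, np.flatnonzero(self.cohorts == cohort)]


def build_matrix(
    samples: Sequence[MethylomeSample],
    regions: Sequence[GenomicInterval] | None = None,
) -> MethylationMatrix:
    """Assemble the site x sample level matrix over the union of sample sites.

    With ``regions``, sites are restricted to those falling inside a region and
    each kept site is labeled with the (0-based) index of its region.
    """
    cohorts = np.array([s.cohort for s in samples])
    for cohort in ("normal", "tumor"):
        if not (cohorts == cohort).any():
            raise ValueError(f"no samples in cohort {cohort!r}")
    frames = []
    for j, s in enumerate(samples):
        frames.append(s.sites[["chrom", "pos", "level"]].assign(_col=j))
    stacked = pd.concat(frames, ignore_index=True)
    wide = stacked.pivot_table(index=["chrom", "pos"], columns="_col", values="level")
    wide = wide.reindex(columns=range(len(samples)))
    sites = wide.index.to_frame(index=False)
    order = sorted(
        range(len(sites)),
        key=lambda i: (chrom_sort_key(sites["chrom"].iloc[i]), sites["pos"].iloc[i]),
    )
    sites = sites.iloc[order].reset_index(drop=True)
    levels = wide.to_numpy(dtype=float)[order]

    if regions is not None:
        region_id = np.full(len(sites), -1, dtype=np.int64)
        for k, iv in enumerate(regions):
            inside = (
                (sites["chrom"] == iv.chrom)
                & (sites["pos"] >= iv.start)
                & (sites["pos"] < iv.end)
            ).to_numpy()
            region_id[inside] = k
        keep = region_id >= 0
        sites = sites[keep].reset_index(drop=True)
        sites["region_id"] = region_id[keep]
        levels = levels[keep]

    return MethylationMatrix(
        sites=sites,
        levels=levels,
        sample_ids=[s.sample_id for s in samples],
        cohorts=cohorts,
    )


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
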