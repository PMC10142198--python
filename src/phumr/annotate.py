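"""Region-level quantification, comparator calls and genomic-context annotation.

Provides the mean-level quantification used to compare benchmarks (whole
refUMR vs its hypermethylated sub-region vs CpG island), the classical
CGI-mean comparator call (G-CIMP style: per-sample CGI means, t-test, BH,
|delta| > 0.2), CpG-island shore/shelf/open-sea context labels, gene
assignment (2 kb upstream of TSS through TES) and per-base conservation-score
averaging.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassifiedUMR
from .intervals import GenomicInterval, merge_intervals
from .methylome import MethylationMatrix
from .stats import bh_adjust, cpg_ttest_matrix


@dataclass
class RegionQuantification:
    interval: GenomicInterval
    benchmark: str  # CGI | refUMR | Hyper
    mean_normal: float
    mean_tumor: float

    @property
    def delta_region(self) -> float:
        return self.mean_tumor - self.mean_normal


@dataclass(frozen=True)
class GeneModel:
    """Minimal strand-aware gene model; tss/tes are base positions (0-based)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: + strand gene with tss > tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: - strand gene with tss < tes")


def _site_mask(matrix: MethylationMatrix, interval: GenomicInterval) -> np.ndarray:
    sites = matrix.sites
    return (
        (sites["chrom"] == interval.chrom)
        & (sites["pos"] >= interval.start)
        & (sites["pos"] < interval.end)
    ).to_numpy()


def region_mean_delta(
    matrix: MethylationMatrix, interval: GenomicInterval, benchmark: str = "refUMR"
) -> RegionQuantification:
    """Cohort mean methylation over the interval's detected CpGs."""
    mask = _site_mask(matrix, interval)
    with np.errstate(invalid="ignore"):
        mean_n = float(np.nanmean(matrix.cohort_levels("normal")[mask])) if mask.any() else np.nan
        mean_t = float(np.nanmean(matrix.cohort_levels("tumor")[mask])) if mask.any() else np.nan
    return RegionQuantification(interval, benchmark, mean_n, mean_t)


def gcimp_call(
    matrix: MethylationMatrix,
    cgis: list[GenomicInterval],
    q_max: float = 0.05,
    delta_min: float = 0.2,
) -> pd.DataFrame:
    """Classical CGI-mean comparator (G-CIMP-style) hypermethylation calls.

    Per CGI and sample, the mean level across the CGI's detected CpGs is
    computed (a sample with no detected CpG is masked for that CGI); a
    two-tailed t-test compares cohorts; BH runs over all CGIs; a CGI is called
    when q < ``q_max`` and |mean delta| > ``delta_min``.
    """
    n_samples = len(matrix.sample_ids)
    per_sample = np.full((len(cgis), n_samples), np.nan)
    for i, cgi in enumerate(cgis):
        mask = _site_mask(matrix, cgi)
        if mask.any():
            with np.errstate(invalid="ignore"):
                per_sample[i] = np.nanmean(matrix.levels[mask], axis=0)
    normal = per_sample[:, matrix.normal_idx]
    tumor = per_sample[:, matrix.tumor_idx]
    with np.errstate(invalid="ignore"):
        delta = np.nanmean(tumor, axis=1) - np.nanmean(normal, axis=1)
    p = cpg_ttest_matrix(normal, tumor)
    q = bh_adjust(p)
    with np.errstate(invalid="ignore"):
        called = (q < q_max) & (np.abs(delta) > delta_min)
    called[~np.isfinite(q) | ~np.isfinite(delta)] = False
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in cgis],
            "start": [c.start for c in cgis],
            "end": [c.end for c in cgis],
            "delta": delta,
            "p": p,
            "q": q,
            "gcimp": called,
        }
    )


def missed_fraction(classified: list[ClassifiedUMR], delta_min: float = 0.2) -> float:
    """Fraction of phUMRs invisible to whole-region mean quantification.

    A phUMR is "missed" when its whole-refUMR |mean delta| falls below the
    conventional 0.2 threshold while its hypermethylated sub-region's mean
    delta clears it — erosion confined to part of the UMR is diluted away by
    averaging over all CpGs.
    """
    phumrs = [c for c in classified if c.umr_class == "phUMR"]
    if not phumrs:
        raise ValueError("no phUMRs to evaluate")
    missed = sum(
        1
        for c in phumrs
        if abs(c.mean_delta_whole) < delta_min and c.mean_delta_hyper >= delta_min
    )
    return missed / len(phumrs)


SHORE_BP = 2000
SHELF_BP = 2000


def annotate_cgi_context(
    interval: GenomicInterval,
    cgis: list[GenomicInterval],
    one_sided: bool = False,
) -> str:
    """Label an interval CGI / shore / shelf / open_sea by highest-precedence overlap.

    Shores are the 2 kb flanking a CGI, shelves the next 2 kb. By default
    flanks apply on both sides; ``one_sided=True`` restricts them to the
    downstream (higher-coordinate) side.
    """
    cgis = merge_intervals(cgis)
    same = [c for c in cgis if c.chrom == interval.chrom]
    if any(interval.overlaps(c) for c in same):
        return "CGI"
    for band_bp, label in ((SHORE_BP, "shore"), (SHORE_BP + SHELF_BP, "shelf")):
        for c in same:
            right = GenomicInterval(c.chrom, c.end, c.end + band_bp)
            if interval.overlaps(right):
                return label
            if not one_sided and c.start > 0:
                left = GenomicInterval(c.chrom, max(0, c.start - band_bp), c.start)
                if interval.overlaps(left):
                    return label
    return "open_sea"


def assign_gene_context(
    interval: GenomicInterval,
    genes: list[GeneModel],
    promoter_up: int = 2000,
) -> list[tuple[str, str]]:
    """Map an interval to genes whose region (2 kb upstream of TSS to TES) it overlaps.

    Each hit is labeled "promoter" when the interval overlaps the promoter
    window (the TSS base plus ``promoter_up`` bases upstream), otherwise
    "gene_body". Intervals overlapping several gene windows yield several
    assignments.
    """
    hits = []
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        if g.strand == "+":
            window = GenomicInterval(g.chrom, max(0, g.tss - promoter_up), g.tes + 1)
            promoter = GenomicInterval(g.chrom, max(0, g.tss - promoter_up), g.tss + 1)
        else:
            window = GenomicInterval(g.chrom, g.tes, g.tss + promoter_up + 1)
            promoter = GenomicInterval(g.chrom, g.tss, g.tss + promoter_up + 1)
        if interval.overlaps(window):
            hits.append((g.gene_id, "promoter" if interval.overlaps(promoter) else "gene_body"))
    return hits


def conservation_mean(interval: GenomicInterval, track: pd.DataFrame) -> float:
    """Mean per-base conservation score over the interval's covered bases.

    ``track`` has columns chrom, start, end, value (bedGraph semantics);
    uncovered bases are excluded; NaN when nothing overlaps.
    """
    sub = track[track["chrom"] == interval.chrom]
    starts = np.maximum(sub["start"].to_numpy(), interval.start)
    ends = np.minimum(sub["end"].to_numpy(), interval.end)
    lengths = np.maximum(0, ends - starts)
    total = lengths.sum()
    if total == 0:
        return np.nan
    return float((lengths * sub["value"].to_numpy()).sum() / total)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    return df.astype({"start": np.int64, "end": np.int64, "value": float})


def read_wig(path) -> pd.DataFrame:
    """Parse plain-text wiggle (fixedStep / variableStep) into bedGraph rows."""
    rows = []
    opener = gzip.open if str(path).endswith(".gz") else open
    mode, chrom, start, step, span = None, None, 0, 1, 1
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = line.split()[0]
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if mode == "fixedStep":
                    start = int(fields["start"]) - 1  # wig is 1-based
                    step = int(fields.get("step", 1))
                continue
            if mode == "fixedStep":
                rows.append((chrom, start, start + span, float(line)))
                start += step
            elif mode == "variableStep":
                pos_s, val = line.split()
                pos = int(pos_s) - 1
                rows.append((chrom, pos, pos + span, float(val)))
            else:
                raise ValueError(f"{path}: data line before wig declaration")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_gene_table(path) -> list[GeneModel]:
    """Read a minimal gene table: gene_id, chrom, strand, tss, tes (TSV, header)."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss), int(r.tes))
        for r in df.itertuples(index=False)
    ]


def annotate_classified(
    classified: list[ClassifiedUMR],
    cgis: list[GenomicInterval] | None = None,
    genes: list[GeneModel] | None = None,
    conservation: pd.DataFrame | None = None,
    promoter_up: int = 2000,
) -> pd.DataFrame:
    """Join context labels onto the classified-UMR table."""
    from .classify import classified_to_frame

    df = classified_to_frame(classified)
    if cgis is not None:
        merged = merge_intervals(cgis)
        df["cgi_context"] = [
            annotate_cgi_context(c.refumr.interval, merged) for c in classified
        ]
    if genes is not None:
        df["genes"] = [
            ";".join(f"{gid}:{label}" for gid, label in
                     assign_gene_context(c.refumr.interval, genes, promoter_up))
            for c in classified
        ]
    if conservation is not None:
        df["mean_conservation"] = [
            conservation_mean(c.refumr.interval, conservation) for c in classified
        ]
    return df
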