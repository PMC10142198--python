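"""Hypermethylation-erosion classification of reference UMRs.

Hyper CpGs inside each refUMR are merged into hypermethylated regions; the
proportion of refUMR CpGs falling inside those regions drives the class:

* fhUMR  -- proportion >= 0.8 (fully hypermethylated; the whole UMR eroded),
* phUMR  -- 0 < proportion < 0.8 with at least 5 hyper CpGs (partial erosion),
* none   -- otherwise.

phUMRs are further segmented into partial-Hyper intervals (the eroded
sub-segments) and flanking-UMR intervals (the still-unmethylated remainder);
the border between them is set by the hypermethylated CpGs themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .umr import RefUMR


@dataclass
class HyperRegion:
    """A merged run of hyper CpGs inside a refUMR.

    ``first_idx``/``last_idx`` are indices into the refUMR's ordered CpG list.
    """

    interval: GenomicInterval
    n_hyper_cpg: int
    n_cpg_spanned: int
    first_idx: int
    last_idx: int

    def __post_init__(self) -> None:
        if self.n_hyper_cpg > self.n_cpg_spanned:
            raise ValueError("hyper CpG count exceeds spanned CpG count")


@dataclass
class ClassifiedUMR:
    """A refUMR with its erosion class and partial-Hyper / flanking-UMR split."""

    refumr: RefUMR
    positions: np.ndarray  # detected-in-both-cohorts CpG positions, sorted
    deltas: np.ndarray
    is_hyper: np.ndarray
    hyper_regions: list[HyperRegion]
    hyper_proportion: float
    umr_class: str  # phUMR | fhUMR | none
    partial_hyper: list[GenomicInterval] = field(default_factory=list)
    flanking_umr: list[GenomicInterval] = field(default_factory=list)
    mean_delta_hyper: float = np.nan
    mean_delta_whole: float = np.nan


def merge_hyper_cpgs(
    positions: np.ndarray,
    is_hyper: np.ndarray,
    chrom: str,
    max_gap_cpgs: int = 0,
) -> list[HyperRegion]:
    """Merge hyper CpGs into maximal hypermethylated regions.

    Runs of hyper CpGs separated by at most ``max_gap_cpgs`` consecutive
    non-hyper CpGs are bridged into one region; each region spans its first to
    last hyper CpG (half-open end = last pos + 1).
    """
    positions = np.asarray(positions)
    is_hyper = np.asarray(is_hyper, dtype=bool)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    hyper_idx = np.flatnonzero(is_hyper)
    if len(hyper_idx) == 0:
        return []
    groups: list[list[int]] = [[int(hyper_idx[0])]]
    for idx in hyper_idx[1:]:
        if idx - groups[-1][-1] - 1 <= max_gap_cpgs:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    regions = []
    for g in groups:
        first, last = g[0], g[-1]
        regions.append(
            HyperRegion(
                interval=GenomicInterval(chrom, int(positions[first]), int(positions[last]) + 1),
                n_hyper_cpg=len(g),
                n_cpg_spanned=last - first + 1,
                first_idx=first,
                last_idx=last,
            )
        )
    return regions


def classify_umr(
    refumr: RefUMR,
    positions: np.ndarray,
    deltas: np.ndarray,
    is_hyper: np.ndarray,
    hyper_regions: list[HyperRegion] | None = None,
    prop_threshold: float = 0.8,
    min_hyper_cpg: int = 5,
    max_gap_cpgs: int = 0,
) -> ClassifiedUMR:
    """Classify one refUMR as phUMR, fhUMR or none.

    The proportion denominator is the refUMR's CpGs with a defined delta
    (detected in both cohorts); the numerator counts CpGs falling inside any
    merged hypermethylated region. A proportion of exactly ``prop_threshold``
    is assigned fhUMR.
    """
    positions = np.asarray(positions)
    deltas = np.asarray(deltas, dtype=float)
    is_hyper = np.asarray(is_hyper, dtype=bool)
    n_total = len(positions)
    if n_total == 0:
        raise ValueError(f"refUMR {refumr.name} has no CpGs to classify")
    if hyper_regions is None:
        hyper_regions = merge_hyper_cpgs(positions, is_hyper, refumr.interval.chrom, max_gap_cpgs)

    spanned = np.zeros(n_total, dtype=bool)
    for hr in hyper_regions:
        spanned[hr.first_idx : hr.last_idx + 1] = True
    proportion = spanned.sum() / n_total
    n_hyper = int(is_hyper.sum())

    if proportion >= prop_threshold:
        umr_class = "fhUMR"
    elif proportion > 0 and n_hyper >= min_hyper_cpg:
        umr_class = "phUMR"
    else:
        umr_class = "none"

    mean_whole = float(np.nanmean(deltas)) if n_total else np.nan
    mean_hyper = float(np.nanmean(deltas[spanned])) if spanned.any() else np.nan

    classified = ClassifiedUMR(
        refumr=refumr,
        positions=positions,
        deltas=deltas,
        is_hyper=is_hyper,
        hyper_regions=hyper_regions,
        hyper_proportion=float(proportion),
        umr_class=umr_class,
        mean_delta_hyper=mean_hyper,
        mean_delta_whole=mean_whole,
    )
    if umr_class == "phUMR":
        classified.partial_hyper, classified.flanking_umr = segment_phumr(classified)
    elif umr_class == "fhUMR":
        classified.partial_hyper = [hr.interval for hr in hyper_regions]
    return classified


def segment_phumr(
    classified: ClassifiedUMR,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split a phUMR into partial-Hyper and flanking-UMR intervals.

    Partial-Hyper intervals are the merged hyper regions; flanking-UMR
    intervals are the maximal runs of remaining CpGs. Every refUMR CpG lands
    on exactly one side.
    """
    if classified.umr_class != "phUMR":
        raise ValueError(f"segment_phumr requires a phUMR, got {classified.umr_class}")
    chrom = classified.refumr.interval.chrom
    n = len(classified.positions)
    spanned = np.zeros(n, dtype=bool)
    for hr in classified.hyper_regions:
        spanned[hr.first_idx : hr.last_idx + 1] = True
    partial = [hr.interval for hr in classified.hyper_regions]
    flanking = []
    start = None
    for i in range(n + 1):
        inside = i < n and not spanned[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            flanking.append(
                GenomicInterval(
                    chrom,
                    int(classified.positions[start]),
                    int(classified.positions[i - 1]) + 1,
                )
            )
            start = None
    return partial, flanking


def classify_all(
    calls: pd.DataFrame,
    refumrs: list[RefUMR],
    prop_threshold: float = 0.8,
    min_hyper_cpg: int = 5,
    max_gap_cpgs: int = 0,
) -> list[ClassifiedUMR]:
    """Classify every refUMR from the per-CpG differential call table."""
    out = []
    for rid, r in enumerate(refumrs):
        sub = calls[(calls["region_id"] == rid) & np.isfinite(calls["delta"])]
        if len(sub) == 0:
            continue
        out.append(
            classify_umr(
                r,
                sub["pos"].to_numpy(),
                sub["delta"].to_numpy(),
                sub["is_hyper"].to_numpy(dtype=bool),
                prop_threshold=prop_threshold,
                min_hyper_cpg=min_hyper_cpg,
                max_gap_cpgs=max_gap_cpgs,
            )
        )
    return out


_CLASS_RGB = {"phUMR": "230,97,1", "fhUMR": "94,60,153", "none": "128,128,128"}


def classified_to_frame(classified: list[ClassifiedUMR]) -> pd.DataFrame:
    rows = []
    for c in classified:
        rows.append(
            {
                "chrom": c.refumr.interval.chrom,
                "start": c.refumr.interval.start,
                "end": c.refumr.interval.end,
                "n_cpg": len(c.positions),
                "n_hyper_cpg": int(c.is_hyper.sum()),
                "hyper_proportion": c.hyper_proportion,
                "umr_class": c.umr_class,
                "mean_delta_whole": c.mean_delta_whole,
                "mean_delta_hyper": c.mean_delta_hyper,
                "partial_hyper": ";".join(f"{iv.start}-{iv.end}" for iv in c.partial_hyper),
                "flanking_umr": ";".join(f"{iv.start}-{iv.end}" for iv in c.flanking_umr),
            }
        )
    return pd.DataFrame(rows)


def classified_to_bed(classified: list[ClassifiedUMR], path) -> None:
    """BED9: thickStart/thickEnd span first to last hyper CpG, color by class."""
    with open(path, "wt") as fh:
        for k, c in enumerate(classified):
            iv = c.refumr.interval
            if c.hyper_regions:
                thick_start = c.hyper_regions[0].interval.start
                thick_end = c.hyper_regions[-1].interval.end
            else:
                thick_start, thick_end = iv.start, iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.umr_class}_{k}\t"
                f"{round(1000 * c.hyper_proportion)}\t.\t{thick_start}\t{thick_end}\t"
                f"{_CLASS_RGB[c.umr_class]}\n"
            )
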