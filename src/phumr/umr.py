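"""Per-sample under-methylated region (UMR) calling and cross-sample consensus.

A UMR is a run of CpGs with consistently low methylation in one methylome.
Per sample, CpG levels are segmented with a two-state (Unmethylated /
Methylated) Gaussian-emission HMM refined by a few EM iterations and decoded
with Viterbi; runs of Unmethylated CpGs are kept when they contain enough
CpGs and their mean level is low enough. Reference UMRs (refUMRs) are the
base-wise consensus of per-sample UMRs across the normal cohort: maximal runs
of bases covered by UMRs in at least ``min_support`` of the samples, trimmed
to their first/last contained CpG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hmm import forward_backward, gaussian_logpdf, viterbi
from .intervals import GenomicInterval, chrom_sort_key
from .methylome import MethylomeSample

U_STATE, M_STATE = 0, 1


@dataclass
class UMRCallerParams:
    """Two-state segmentation knobs (all exposed; defaults are the study settings)."""

    init_means: tuple[float, float] = (0.1, 0.8)  # (Unmethylated, Methylated)
    init_vars: tuple[float, float] = (0.02, 0.02)
    self_transition: float = 0.99
    var_floor: float = 1e-4
    em_iters: int = 20
    em_tol: float = 1e-4
    min_cpg: int = 5
    max_umr_level: float = 0.1


@dataclass
class RefUMR:
    """A consensus under-methylated interval in the normal cohort."""

    interval: GenomicInterval
    n_cpg: int
    support: float

    @property
    def name(self) -> str:
        return f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


def _fit_two_state(levels: np.ndarray, params: UMRCallerParams):
    """EM-refined (means/vars/transitions) two-state Gaussian HMM parameters."""
    means = np.array(params.init_means, dtype=float)
    variances = np.array(params.init_vars, dtype=float)
    p_stay = params.self_transition
    trans = np.array([[p_stay, 1 - p_stay], [1 - p_stay, p_stay]])
    init = np.array([0.5, 0.5])
    prev_ll = -np.inf
    for _ in range(max(0, params.em_iters)):
        log_emit = gaussian_logpdf(levels, means, variances)
        with np.errstate(divide="ignore"):
            gamma, xi_sum, ll = forward_backward(np.log(init), np.log(trans), log_emit)
        weight = gamma.sum(axis=0)
        for k in range(2):
            if weight[k] > 1e-8:
                means[k] = float(gamma[:, k] @ levels / weight[k])
                variances[k] = max(
                    float(gamma[:, k] @ (levels - means[k]) ** 2 / weight[k]),
                    params.var_floor,
                )
        row = xi_sum.sum(axis=1, keepdims=True)
        ok = row[:, 0] > 1e-8
        trans[ok] = xi_sum[ok] / row[ok]
        init = gamma[0] / gamma[0].sum()
        if abs(ll - prev_ll) < params.em_tol:
            break
        prev_ll = ll
    if means[U_STATE] > means[M_STATE]:  # keep state identity: U is the low state
        means = means[::-1]
        variances = variances[::-1]
        trans = trans[::-1, ::-1]
        init = init[::-1]
    return means, variances, trans, init


def call_umrs_single(
    sample: MethylomeSample, params: UMRCallerParams | None = None
) -> list[GenomicInterval]:
    """Call UMRs in one (filtered, strand-merged) sample.

    Returns maximal runs of Viterbi-Unmethylated CpGs with at least
    ``min_cpg`` members and mean level <= ``max_umr_level``, each spanning its
    first to last member CpG (half-open end = last pos + 1). Chromosomes are
    decoded independently.
    """
    params = params or UMRCallerParams()
    out: list[GenomicInterval] = []
    for chrom, sub in sample.sites.groupby("chrom", sort=False):
        levels = sub["level"].to_numpy(dtype=float)
        positions = sub["pos"].to_numpy()
        if len(levels) < params.min_cpg:
            continue
        means, variances, trans, init = _fit_two_state(levels, params)
        log_emit = gaussian_logpdf(levels, means, variances)
        with np.errstate(divide="ignore"):
            path = viterbi(np.log(init), np.log(trans), log_emit, prefer=[M_STATE, U_STATE])
        for start, stop in _runs(path == U_STATE):
            if stop - start < params.min_cpg:
                continue
            if levels[start:stop].mean() > params.max_umr_level:
                continue
            out.append(GenomicInterval(chrom, int(positions[start]), int(positions[stop - 1]) + 1))
    return sorted(out, key=lambda iv: (chrom_sort_key(iv.chrom), iv.start))


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    mask = np.asarray(mask, dtype=bool)
    if len(mask) == 0:
        return
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        stops = stops + [len(mask)]
    yield from zip(starts, stops)


def consensus_refumrs(
    umr_sets: list[list[GenomicInterval]],
    consensus_sites: pd.DataFrame,
    min_support: float = 0.8,
    min_cpg: int = 5,
) -> list[RefUMR]:
    """Integrate per-sample UMRs into reference UMRs by base-wise support.

    Per-base support is the fraction of samples whose UMRs cover the base.
    Maximal runs with support >= ``min_support`` are trimmed to their first and
    last contained CpG (from ``consensus_sites``: columns chrom, pos) and kept
    when they contain at least ``min_cpg`` CpGs. The reported support of a
    refUMR is the fraction of samples whose UMRs cover its entire interval.
    """
    if not (0.0 < min_support <= 1.0):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if len(umr_sets) < 2:
        raise ValueError("consensus requires at least two samples")
    n_samples = len(umr_sets)
    chroms = sorted(
        {iv.chrom for ivs in umr_sets for iv in ivs}, key=chrom_sort_key
    )
    out: list[RefUMR] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []
        for ivs in umr_sets:
            for iv in ivs:
                if iv.chrom == chrom:
                    events.append((iv.start, 1))
                    events.append((iv.end, -1))
        if not events:
            continue
        bounds = np.array(sorted({e[0] for e in events}))
        depth = np.zeros(len(bounds), dtype=np.int64)
        for pos, step in events:
            depth[np.searchsorted(bounds, pos)] += step
        depth = np.cumsum(depth)  # coverage on [bounds[i], bounds[i+1])
        covered = depth / n_samples >= min_support
        site_pos = np.sort(
            consensus_sites.loc[consensus_sites["chrom"] == chrom, "pos"].to_numpy()
        )
        for start_i, stop_i in _runs(covered[:-1]):
            run_start, run_end = int(bounds[start_i]), int(bounds[stop_i])
            inside = site_pos[(site_pos >= run_start) & (site_pos < run_end)]
            if len(inside) < min_cpg:
                continue
            iv = GenomicInterval(chrom, int(inside[0]), int(inside[-1]) + 1)
            support = _full_cover_fraction(iv, umr_sets)
            out.append(RefUMR(interval=iv, n_cpg=len(inside), support=support))
    return out


def _full_cover_fraction(iv: GenomicInterval, umr_sets: list[list[GenomicInterval]]) -> float:
    """Fraction of samples whose UMR union covers every base of ``iv``."""
    n_cover = 0
    for ivs in umr_sets:
        pieces = sorted(
            (max(o.start, iv.start), min(o.end, iv.end))
            for o in ivs
            if o.chrom == iv.chrom and o.start < iv.end and iv.start < o.end
        )
        covered_to = iv.start
        for s, e in pieces:
            if s > covered_to:
                break
            covered_to = max(covered_to, e)
        if covered_to >= iv.end:
            n_cover += 1
    return n_cover / len(umr_sets)


def refumrs_to_bed(refumrs: list[RefUMR], path) -> None:
    """Write refUMRs as BED6 (score = round(1000 * support))."""
    with open(path, "wt") as fh:
        for k, r in enumerate(refumrs):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"refUMR_{k}\t{round(1000 * r.support)}\t.\n"
            )


def refumrs_to_frame(refumrs: list[RefUMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in refumrs],
            "start": [r.interval.start for r in refumrs],
            "end": [r.interval.end for r in refumrs],
            "n_cpg": [r.n_cpg for r in refumrs],
            "support": [r.support for r in refumrs],
        }
    )
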