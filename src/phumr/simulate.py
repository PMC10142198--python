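"""Synthetic paired WGBS cohorts with planted UMRs and erosion truth.

The generator emulates the data structure the detection framework assumes:
two cohorts of methylomes sharing a set of under-methylated regions (CpG-dense
islands of low methylation inside a highly methylated background), where each
planted region is, in the tumor cohort, either untouched, partially eroded
(a contiguous block of CpGs from one end lifted by ``erosion_delta``) or
fully eroded. Biological variation is beta-distributed around the true mean
(concentration ``kappa``), sequencing is binomial at Poisson depth, so the
observed levels carry both cross-sample and counting noise — the two noise
sources the t-test and the HMM must cope with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval
from .methylome import MethylomeSample


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts (defaults are the benchmark)."""

    n_normal: int = 10
    n_tumor: int = 10
    n_regions: int = 200
    cpg_per_region: tuple[int, int] = (25, 60)  # inclusive range
    mu_background: float = 0.85
    mu_umr: float = 0.05
    erosion_delta: float = 0.4
    class_weights: dict = field(
        default_factory=lambda: {"none": 0.2, "partial": 0.4, "full": 0.4}
    )
    partial_fraction: tuple[float, float] = (0.2, 0.6)
    partial_internal: bool = False  # erode an internal block instead of an end
    kappa: float = 50.0  # beta concentration (biological noise)
    depth: float = 30.0  # Poisson read-depth mean
    seed: int = 0
    chrom: str = "chr1"

    def validate(self) -> None:
        w = self.class_weights
        if set(w) != {"none", "partial", "full"}:
            raise ValueError("class_weights must have keys none/partial/full")
        if any(v < 0 for v in w.values()) or not np.isclose(sum(w.values()), 1.0):
            raise ValueError("class weights must be non-negative and sum to 1")
        for level in (self.mu_background, self.mu_umr):
            if not (0.0 < level < 1.0):
                raise ValueError(f"levels must lie in (0, 1), got {level}")
        if not (0.0 < self.mu_umr + self.erosion_delta < 1.0):
            raise ValueError("eroded level mu_umr + erosion_delta must lie in (0, 1)")
        lo, hi = self.partial_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("partial_fraction range must lie inside (0, 1)")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["cpg_per_region"] = list(self.cpg_per_region)
        data["partial_fraction"] = list(self.partial_fraction)
        with open(path, "wt") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["cpg_per_region"] = tuple(data["cpg_per_region"])
        data["partial_fraction"] = tuple(data["partial_fraction"])
        return cls(**data)


@dataclass
class TruthRecord:
    """Planted ground truth for one region."""

    interval: GenomicInterval
    klass: str  # none | partial | full
    positions: np.ndarray
    eroded: np.ndarray  # boolean per CpG
    border_index: int | None  # first/one-past-last eroded CpG (partial only)
    eroded_side: str | None  # left | right | internal
    normal_means: np.ndarray
    tumor_means: np.ndarray


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[MethylomeSample], list[TruthRecord]]:
    """Draw both cohorts and the planted truth. Deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cpg_per_region
    classes = list(config.class_weights)
    weights = np.array([config.class_weights[k] for k in classes])

    truth: list[TruthRecord] = []
    all_pos: list[int] = []
    normal_means: list[float] = []
    tumor_means: list[float] = []

    cursor = 10_000
    for _ in range(config.n_regions):
        # sparse background CpGs in the gap before the region
        n_bg = int(rng.integers(5, 12))
        for _ in range(n_bg):
            cursor += int(rng.integers(400, 1500))
            all_pos.append(cursor)
            normal_means.append(config.mu_background)
            tumor_means.append(config.mu_background)
        cursor += int(rng.integers(3000, 8000))

        n_cpg = int(rng.integers(lo, hi + 1))
        positions = cursor + np.cumsum(rng.integers(15, 120, size=n_cpg))
        cursor = int(positions[-1]) + int(rng.integers(3000, 8000))
        klass = classes[int(rng.choice(len(classes), p=weights))]
        eroded = np.zeros(n_cpg, dtype=bool)
        border_index = None
        side = None
        if klass == "full":
            eroded[:] = True
        elif klass == "partial":
            frac = float(rng.uniform(*config.partial_fraction))
            k = min(n_cpg - 1, max(1, round(frac * n_cpg)))
            if config.partial_internal:
                side = "internal"
                start = int(rng.integers(1, n_cpg - k))
                eroded[start : start + k] = True
                border_index = start
            elif rng.random() < 0.5:
                side = "left"
                eroded[:k] = True
                border_index = k  # first non-eroded CpG
            else:
                side = "right"
                eroded[n_cpg - k :] = True
                border_index = n_cpg - k  # first eroded CpG
        t_means = np.where(eroded, config.mu_umr + config.erosion_delta, config.mu_umr)
        n_means = np.full(n_cpg, config.mu_umr)
        truth.append(
            TruthRecord(
                interval=GenomicInterval(config.chrom, int(positions[0]), int(positions[-1]) + 1),
                klass=klass,
                positions=positions.astype(np.int64),
                eroded=eroded,
                border_index=border_index,
                eroded_side=side,
                normal_means=n_means,
                tumor_means=t_means,
            )
        )
        all_pos.extend(int(p) for p in positions)
        normal_means.extend(n_means)
        tumor_means.extend(t_means)

    positions = np.array(all_pos, dtype=np.int64)
    normal_means_arr = np.clip(np.array(normal_means), 1e-6, 1 - 1e-6)
    tumor_means_arr = np.clip(np.array(tumor_means), 1e-6, 1 - 1e-6)

    samples: list[MethylomeSample] = []
    for cohort, n_samples, means in (
        ("normal", config.n_normal, normal_means_arr),
        ("tumor", config.n_tumor, tumor_means_arr),
    ):
        for j in range(n_samples):
            levels = rng.beta(means * config.kappa, (1.0 - means) * config.kappa)
            depth = np.maximum(1, rng.poisson(config.depth, size=len(positions)))
            meth = rng.binomial(depth, levels)
            sites = pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "pos": positions,
                    "meth": meth,
                    "total": depth,
                }
            )
            samples.append(
                MethylomeSample(sample_id=f"{cohort}_{j:02d}", cohort=cohort, sites=sites)
            )
    return samples, truth


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [t.interval.chrom for t in truth],
            "start": [t.interval.start for t in truth],
            "end": [t.interval.end for t in truth],
            "class": [t.klass for t in truth],
            "n_cpg": [len(t.positions) for t in truth],
            "n_eroded": [int(t.eroded.sum()) for t in truth],
            "border_index": [t.border_index if t.border_index is not None else -1 for t in truth],
            "eroded_side": [t.eroded_side or "." for t in truth],
            "positions": [",".join(map(str, t.positions)) for t in truth],
            "eroded": [",".join("1" if e else "0" for e in t.eroded) for t in truth],
        }
    )


def truth_from_frame(df: pd.DataFrame) -> list[TruthRecord]:
    out = []
    for _, r in df.iterrows():
        positions = np.array([int(x) for x in r["positions"].split(",")], dtype=np.int64)
        eroded = np.array([x == "1" for x in r["eroded"].split(",")])
        out.append(
            TruthRecord(
                interval=GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])),
                klass=r["class"],
                positions=positions,
                eroded=eroded,
                border_index=None if r["border_index"] == -1 else int(r["border_index"]),
                eroded_side=None if r["eroded_side"] == "." else r["eroded_side"],
                normal_means=np.full(len(positions), np.nan),
                tumor_means=np.full(len(positions), np.nan),
            )
        )
    return out


def score_against_truth(
    classified,
    truth: list[TruthRecord],
    delta_min: float = 0.2,
) -> dict:
    """Score classified refUMRs against planted truth.

    Truth regions are matched to classified refUMRs by maximal interval
    overlap; an unmatched truth region counts as a miss (predicted none).
    Returns the 3x3 confusion matrix (truth x prediction over
    none/partial/full), overall accuracy, border errors in CpG-index units for
    true partials, and the missed fraction of predicted phUMRs under the
    conventional mean-difference benchmark.
    """
    from .annotate import missed_fraction as _missed

    label_of = {"phUMR": "partial", "fhUMR": "full", "none": "none"}
    order = ["none", "partial", "full"]
    confusion = pd.DataFrame(0, index=order, columns=order)
    border_errors: list[float] = []

    for t in truth:
        best, best_ov = None, 0
        for c in classified:
            ov = t.interval.overlap_len(c.refumr.interval)
            if ov > best_ov:
                best, best_ov = c, ov
        pred = label_of[best.umr_class] if best is not None else "none"
        confusion.loc[t.klass, pred] += 1
        if t.klass == "partial":
            border_errors.append(_border_error(t, best))

    accuracy = float(np.trace(confusion.to_numpy()) / confusion.to_numpy().sum())
    phumrs = [c for c in classified if c.umr_class == "phUMR"]
    metrics = {
        "confusion": confusion,
        "accuracy": accuracy,
        "border_errors": np.array(border_errors, dtype=float),
        "missed_fraction": _missed(classified, delta_min) if phumrs else np.nan,
    }
    return metrics


def _border_error(t: TruthRecord, c) -> float:
    """Border discrepancy in CpG-index units; inf when no erosion was predicted."""
    if c is None or not c.hyper_regions:
        return np.inf
    pred_eroded = np.zeros(len(t.positions), dtype=bool)
    for hr in c.hyper_regions:
        pred_eroded |= (t.positions >= hr.interval.start) & (t.positions < hr.interval.end)
    if not pred_eroded.any():
        return np.inf
    if t.eroded_side == "right":
        return abs(int(np.flatnonzero(pred_eroded)[0]) - t.border_index)
    if t.eroded_side == "left":
        return abs(int(np.flatnonzero(pred_eroded)[-1]) + 1 - t.border_index)
    # internal block: compare both edges, report the worse one
    idx = np.flatnonzero(pred_eroded)
    true_idx = np.flatnonzero(t.eroded)
    return max(abs(int(idx[0]) - int(true_idx[0])), abs(int(idx[-1]) - int(true_idx[-1])))
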