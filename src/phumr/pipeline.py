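"""End-to-end orchestration: samples -> refUMRs -> per-CpG calls -> classes.

The stages are importable individually (see `methylome`, `umr`, `diffhmm`,
`stats`, `classify`); this module wires them together under one configuration
object so the CLI, the examples and the test benchmarks all run the exact same
path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import diffhmm, methylome, umr
from .methylome import DEFAULT_CHROMS, MethylomeSample


@dataclass
class PipelineConfig:
    """All tunable parameters of the detection pipeline, with study defaults."""

    min_reads: int = 5
    main_chroms: tuple[str, ...] = DEFAULT_CHROMS
    min_support: float = 0.8
    min_cpg: int = 5
    max_umr_level: float = 0.1
    delta_threshold: float = 0.2
    q_max: float = 0.05
    delta_min: float = 0.2
    prop_threshold: float = 0.8
    min_hyper_cpg: int = 5
    max_gap_cpgs: int = 0
    promoter_up: int = 2000
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["main_chroms"] = list(self.main_chroms)
        with open(path, "wt") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "main_chroms" in data:
            data["main_chroms"] = tuple(data["main_chroms"])
        return cls(**data)


def filter_samples(
    samples: list[MethylomeSample], config: PipelineConfig
) -> list[MethylomeSample]:
    return [
        methylome.filter_sites(s, min_reads=config.min_reads, main_chroms=config.main_chroms)
        for s in samples
    ]


def call_refumrs(
    samples: list[MethylomeSample], config: PipelineConfig
) -> list[umr.RefUMR]:
    """Per-sample UMRs on the normal cohort, integrated into refUMRs."""
    normals = [s for s in samples if s.cohort == "normal"]
    if len(normals) < 2:
        raise ValueError("refUMR calling needs at least two normal samples")
    caller = umr.UMRCallerParams(min_cpg=config.min_cpg, max_umr_level=config.max_umr_level)
    umr_sets = [umr.call_umrs_single(s, caller) for s in normals]
    consensus_sites = (
        pd.concat([s.sites[["chrom", "pos"]] for s in normals])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return umr.consensus_refumrs(
        umr_sets,
        consensus_sites,
        min_support=config.min_support,
        min_cpg=config.min_cpg,
    )


def call_hyper_cpgs(
    samples: list[MethylomeSample],
    refumrs: list[umr.RefUMR],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-CpG differential calls (HMM + statistics) over refUMR CpGs."""
    matrix = methylome.build_matrix(samples, regions=[r.interval for r in refumrs])
    return diffhmm.call_differential_cpgs(
        matrix,
        delta_threshold=config.delta_threshold,
        q_max=config.q_max,
        delta_min=config.delta_min,
    )


def classify_refumrs(
    calls: pd.DataFrame,
    refumrs: list[umr.RefUMR],
    config: PipelineConfig,
) -> list[_classify.ClassifiedUMR]:
    return _classify.classify_all(
        calls,
        refumrs,
        prop_threshold=config.prop_threshold,
        min_hyper_cpg=config.min_hyper_cpg,
        max_gap_cpgs=config.max_gap_cpgs,
    )


def run_detection(
    samples: list[MethylomeSample], config: PipelineConfig | None = None
):
    """Run filter -> refUMR -> per-CpG calls -> classification in one shot.

    Returns (refumrs, calls, classified).
    """
    config = config or PipelineConfig()
    filtered = filter_samples(samples, config)
    refumrs = call_refumrs(filtered, config)
    calls = call_hyper_cpgs(filtered, refumrs, config)
    classified = classify_refumrs(calls, refumrs, config)
    return refumrs, calls, classified
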