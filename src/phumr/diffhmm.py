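"""Three-state HMM over per-CpG methylation differences within reference UMRs.

This is the core of the framework: for every CpG in a reference UMR the
tumor-minus-normal difference in mean methylation level (delta) is computed,
and a three-state hidden Markov model (Hyper / Hypo / NoDiff) with Gaussian
emissions on the delta scale assigns a differential state to each CpG at
single-base resolution.

Parameter estimation is deterministic, with no EM by default: CpGs are
provisionally partitioned by thresholding delta at +/-0.2, state means and
variances are the sample moments of each class, and transition probabilities
are counted over adjacent CpG pairs within the same region (plus a
pseudocount). Decoding is per-region Viterbi; the initial distribution puts
all mass on the provisional class of the region-mean delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hmm import forward_backward, gaussian_logpdf, viterbi
from .methylome import MethylationMatrix

HYPER, HYPO, NODIFF = 0, 1, 2
STATE_NAMES = ("Hyper", "Hypo", "NoDiff")
#: Tie-breaking preference on exact log-probability ties.
TIE_ORDER = (NODIFF, HYPER, HYPO)

VAR_FLOOR = 1e-4
FALLBACK_MEANS = (0.3, -0.3, 0.0)


@dataclass
class HMMParams:
    """Gaussian-emission parameters of the three-state differential HMM.

    Means and variances are on the methylation-difference scale in [-1, 1];
    state order is (Hyper, Hypo, NoDiff).
    """

    state_means: np.ndarray
    state_vars: np.ndarray
    transitions: np.ndarray
    delta_threshold: float = 0.2

    def __post_init__(self) -> None:
        self.state_means = np.asarray(self.state_means, dtype=float)
        self.state_vars = np.asarray(self.state_vars, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.state_means.shape != (3,) or self.state_vars.shape != (3,):
            raise ValueError("expected 3 state means and variances")
        if self.transitions.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if (self.transitions < 0).any():
            raise ValueError("negative transition probability")
        if (self.state_vars < VAR_FLOOR - 1e-12).any():
            raise ValueError(f"state variance below floor {VAR_FLOOR}")
        mu_h, mu_o, mu_n = self.state_means
        if not (mu_h > mu_n > mu_o):
            raise ValueError("state means must satisfy Hyper > NoDiff > Hypo")


def compute_delta(matrix: MethylationMatrix) -> np.ndarray:
    """Per-CpG delta: mean detected tumor level minus mean detected normal level.

    A CpG detected in only one cohort is masked (NaN) and excluded downstream.
    """
    def _masked_mean(levels: np.ndarray) -> np.ndarray:
        finite = np.isfinite(levels)
        count = finite.sum(axis=1)
        total = np.where(finite, levels, 0.0).sum(axis=1)
        return np.divide(total, count, out=np.full(len(count), np.nan), where=count > 0)

    return _masked_mean(matrix.cohort_levels("tumor")) - _masked_mean(
        matrix.cohort_levels("normal")
    )


def provisional_states(deltas: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Threshold partition: Hyper if delta >= +t, Hypo if delta <= -t, else NoDiff."""
    deltas = np.asarray(deltas, dtype=float)
    states = np.full(deltas.shape, NODIFF, dtype=np.intp)
    states[deltas >= threshold] = HYPER
    states[deltas <= -threshold] = HYPO
    return states


def estimate_params(
    deltas: np.ndarray,
    region_ids: np.ndarray,
    threshold: float = 0.2,
    pseudocount: float = 1.0,
    var_floor: float = VAR_FLOOR,
) -> HMMParams:
    """Estimate emission and transition parameters from genome-wide deltas.

    ``region_ids`` assigns every CpG (genome order) to its reference UMR;
    transitions are counted only between adjacent CpGs of the same region.
    Empty provisional classes fall back to declared default means
    (+0.3, -0.3, 0) with the overall delta variance (floored).
    """
    deltas = np.asarray(deltas, dtype=float)
    region_ids = np.asarray(region_ids)
    valid = np.isfinite(deltas)
    if not valid.any():
        raise ValueError("no finite deltas to estimate from")
    d = deltas[valid]
    rid = region_ids[valid]
    prov = provisional_states(d, threshold)

    overall_var = max(float(np.var(d, ddof=1)) if len(d) > 1 else var_floor, var_floor)
    means = np.empty(3)
    variances = np.empty(3)
    for s in (HYPER, HYPO, NODIFF):
        members = d[prov == s]
        if len(members) == 0:
            means[s] = FALLBACK_MEANS[s]
            variances[s] = overall_var
        else:
            means[s] = members.mean()
            variances[s] = max(
                float(np.var(members, ddof=1)) if len(members) > 1 else var_floor,
                var_floor,
            )
    # Degenerate partitions can violate the mean ordering; restore the
    # fallback mean for any offending state.
    if not (means[HYPER] > means[NODIFF] > means[HYPO]):
        if means[HYPER] <= means[NODIFF]:
            means[HYPER] = max(FALLBACK_MEANS[HYPER], means[NODIFF] + 0.1)
        if means[HYPO] >= means[NODIFF]:
            means[HYPO] = min(FALLBACK_MEANS[HYPO], means[NODIFF] - 0.1)

    counts = np.zeros((3, 3))
    same_region = rid[1:] == rid[:-1]
    for a, b in zip(prov[:-1][same_region], prov[1:][same_region]):
        counts[a, b] += 1
    counts += pseudocount
    transitions = counts / counts.sum(axis=1, keepdims=True)
    return HMMParams(means, variances, transitions, delta_threshold=threshold)


def refine_params_em(
    deltas: np.ndarray,
    region_ids: np.ndarray,
    params: HMMParams,
    n_iters: int = 5,
    var_floor: float = VAR_FLOOR,
) -> HMMParams:
    """Optional Baum-Welch refinement of the threshold-partition estimates.

    Posterior statistics are accumulated per region (each region keeps its own
    point-mass initial distribution, and no transition mass crosses region
    boundaries), then means, variances and transitions are re-estimated
    jointly. Off by default throughout the pipeline; the deterministic
    estimator is the reference behavior.
    """
    deltas = np.asarray(deltas, dtype=float)
    region_ids = np.asarray(region_ids)
    valid = np.isfinite(deltas)
    d_all = deltas[valid]
    rid_all = region_ids[valid]
    means = params.state_means.copy()
    variances = params.state_vars.copy()
    transitions = params.transitions.copy()
    for _ in range(max(0, n_iters)):
        gamma_sum = np.zeros(3)
        obs_sum = np.zeros(3)
        sq_sum = np.zeros(3)
        xi_total = np.zeros((3, 3))
        for rid in np.unique(rid_all):
            d = d_all[rid_all == rid]
            init_state = int(provisional_states(np.array([d.mean()]), params.delta_threshold)[0])
            log_init = np.full(3, -np.inf)
            log_init[init_state] = 0.0
            with np.errstate(divide="ignore"):
                gamma, xi_sum, _ = forward_backward(
                    log_init, np.log(transitions), gaussian_logpdf(d, means, variances)
                )
            gamma_sum += gamma.sum(axis=0)
            obs_sum += gamma.T @ d
            sq_sum += gamma.T @ (d**2)
            xi_total += xi_sum
        ok = gamma_sum > 1e-8
        means[ok] = obs_sum[ok] / gamma_sum[ok]
        variances[ok] = np.maximum(
            sq_sum[ok] / gamma_sum[ok] - means[ok] ** 2, var_floor
        )
        rows = xi_total.sum(axis=1, keepdims=True)
        nz = rows[:, 0] > 1e-8
        transitions[nz] = xi_total[nz] / rows[nz]
    order = np.argsort(-means)  # keep Hyper > NoDiff > Hypo identity
    remap = np.array([order[0], order[2], order[1]])
    return HMMParams(
        state_means=means[remap],
        state_vars=variances[remap],
        transitions=transitions[np.ix_(remap, remap)],
        delta_threshold=params.delta_threshold,
    )


def decode_region(
    deltas: np.ndarray,
    params: HMMParams,
    region_mean: float | None = None,
) -> np.ndarray:
    """Viterbi state path for one reference UMR's CpGs.

    The initial distribution is a point mass on the provisional class of the
    region-mean delta. Masked (NaN) deltas are skipped for decoding and
    returned as -1 in the output, which is aligned with the input.
    Deterministic: log-space, ties broken toward NoDiff, then Hyper.
    """
    deltas = np.asarray(deltas, dtype=float)
    valid = np.isfinite(deltas)
    if not valid.any():
        raise ValueError("decode_region requires at least one unmasked delta")
    d = deltas[valid]
    if region_mean is None:
        region_mean = float(d.mean())
    init_state = int(provisional_states(np.array([region_mean]), params.delta_threshold)[0])
    log_init = np.full(3, -np.inf)
    log_init[init_state] = 0.0
    with np.errstate(divide="ignore"):
        log_trans = np.log(params.transitions)
    log_emit = gaussian_logpdf(d, params.state_means, params.state_vars)
    path = viterbi(log_init, log_trans, log_emit, prefer=list(TIE_ORDER))
    out = np.full(deltas.shape, -1, dtype=np.intp)
    out[valid] = path
    return out


def call_differential_cpgs(
    matrix: MethylationMatrix,
    delta_threshold: float = 0.2,
    q_max: float = 0.05,
    delta_min: float = 0.2,
    pseudocount: float = 1.0,
    equal_var: bool = False,
    use_absolute: bool = False,
    em_iters: int = 0,
) -> pd.DataFrame:
    """Full per-CpG differential call table over a region-restricted matrix.

    Combines the HMM state with the statistical test: a CpG is Hyper when the
    HMM decodes it as Hyper OR it passes the q/delta gate. Returns a DataFrame
    with columns chrom, pos, region_id, delta, hmm_state, p, q, stat_hyper,
    is_hyper.
    """
    from .stats import bh_adjust, cpg_ttest_matrix, stat_hyper_flags

    if "region_id" not in matrix.sites.columns:
        raise ValueError("matrix must be built over reference UMRs (region_id column)")
    deltas = compute_delta(matrix)
    region_ids = matrix.sites["region_id"].to_numpy()
    params = estimate_params(deltas, region_ids, threshold=delta_threshold, pseudocount=pseudocount)
    if em_iters > 0:
        params = refine_params_em(deltas, region_ids, params, n_iters=em_iters)

    states = np.full(len(deltas), -1, dtype=np.intp)
    for rid in np.unique(region_ids):
        idx = np.flatnonzero(region_ids == rid)
        if np.isfinite(deltas[idx]).any():
            states[idx] = decode_region(deltas[idx], params)

    p = cpg_ttest_matrix(
        matrix.cohort_levels("normal"), matrix.cohort_levels("tumor"), equal_var=equal_var
    )
    q = bh_adjust(p)
    stat_hyper = stat_hyper_flags(deltas, q, q_max=q_max, delta_min=delta_min, use_absolute=use_absolute)
    is_hyper = (states == HYPER) | stat_hyper

    return pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "pos": matrix.sites["pos"],
            "region_id": region_ids,
            "delta": deltas,
            "hmm_state": [STATE_NAMES[s] if s >= 0 else "masked" for s in states],
            "p": p,
            "q": q,
            "stat_hyper": stat_hyper,
            "is_hyper": is_hyper,
        }
    )
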