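"""Shared fixtures: the synthetic benchmark run and independent oracles.

The oracle functions here deliberately re-derive results by direct
enumeration or definitional computation, never by calling the code paths they
check.
"""

import itertools

import numpy as np
import pytest

from phumr import (
    HMMParams,
    PipelineConfig,
    SimulationConfig,
    run_detection,
    score_against_truth,
    simulate_cohorts,
)


@pytest.fixture(scope="session")
def benchmark_run():
    """One full pipeline run on the default synthetic study conditions."""
    cfg = SimulationConfig(seed=1)
    samples, truth = simulate_cohorts(cfg)
    refumrs, calls, classified = run_detection(samples, PipelineConfig(seed=1))
    metrics = score_against_truth(classified, truth)
    return {
        "config": cfg,
        "samples": samples,
        "truth": truth,
        "refumrs": refumrs,
        "calls": calls,
        "classified": classified,
        "metrics": metrics,
    }


def brute_force_viterbi(log_init, log_trans, log_emit):
    """Exhaustive maximization over all k^n state paths."""
    n, k = log_emit.shape
    paths = np.array(list(itertools.product(range(k), repeat=n)))
    lp = log_init[paths[:, 0]] + log_emit[0, paths[:, 0]]
    for t in range(1, n):
        lp = lp + log_trans[paths[:, t - 1], paths[:, t]] + log_emit[t, paths[:, t]]
    best = int(np.argmax(lp))
    return paths[best], float(lp[best])


@pytest.fixture
def viterbi_oracle():
    return brute_force_viterbi


def bh_step_up(p):
    """Definitional Benjamini-Hochberg step-up on a fully observed p-vector."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        adjusted[i] = min(adjusted[i], adjusted[i + 1])
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@pytest.fixture
def bh_oracle():
    return bh_step_up


def random_hmm_params(rng):
    """A random but valid three-state parameterization (Hyper > NoDiff > Hypo)."""
    mu_n = rng.uniform(-0.05, 0.05)
    mu_h = mu_n + rng.uniform(0.1, 0.6)
    mu_o = mu_n - rng.uniform(0.1, 0.6)
    variances = rng.uniform(1e-4, 0.05, size=3)
    transitions = rng.dirichlet(np.ones(3) * rng.uniform(0.5, 5.0), size=3)
    return HMMParams(
        state_means=np.array([mu_h, mu_o, mu_n]),
        state_vars=variances,
        transitions=transitions,
    )


@pytest.fixture
def hmm_param_sampler():
    return random_hmm_params
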