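"""Shared hidden-Markov-model numerics: Gaussian emissions, Viterbi, forward-backward.

Everything works in log space. Viterbi tie-breaking is deterministic: candidate
states are scanned in a caller-supplied preference order and only a strictly
better score displaces the incumbent, so exact log-probability ties resolve to
the earlier-preferred state.
"""

from __future__ import annotations

import numpy as np

_LOG_2PI = np.log(2.0 * np.pi)


def gaussian_logpdf(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Log density of N(mean, var) for observations x (broadcasting)."""
    x = np.asarray(x, dtype=float)[:, None]
    mean = np.asarray(mean, dtype=float)[None, :]
    var = np.asarray(var, dtype=float)[None, :]
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def viterbi(
    log_init: np.ndarray,
    log_trans: np.ndarray,
    log_emit: np.ndarray,
    prefer: list[int] | None = None,
) -> np.ndarray:
    """Most probable state path.

    Parameters
    ----------
    log_init : (k,) log initial distribution.
    log_trans : (k, k) log transition matrix, rows = source state.
    log_emit : (n, k) log emission density of each observation under each state.
    prefer : state indices in tie-breaking preference order (default: 0..k-1).
    """
    n, k = log_emit.shape
    order = list(prefer) if prefer is not None else list(range(k))
    score = log_init + log_emit[0]
    back = np.zeros((n, k), dtype=np.intp)
    for t in range(1, n):
        new = np.empty(k)
        for j in range(k):
            best = -np.inf
            arg = order[0]
            for i in order:
                s = score[i] + log_trans[i, j]
                if s > best:
                    best, arg = s, i
            new[j] = best + log_emit[t, j]
            back[t, j] = arg
        score = new
    best = -np.inf
    last = order[0]
    for i in order:
        if score[i] > best:
            best, last = score[i], i
    path = np.empty(n, dtype=np.intp)
    path[-1] = last
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def forward_backward(
    log_init: np.ndarray, log_trans: np.ndarray, log_emit: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior state probabilities and expected transition counts.

    Returns (gamma, xi_sum, loglik): gamma is (n, k) posteriors, xi_sum is the
    (k, k) matrix of expected transition counts summed over time. Uses the
    scaled linear-space recursions; emissions are shifted by their per-step
    maximum before exponentiation so extreme observations cannot underflow.
    """
    n, k = log_emit.shape
    shift = log_emit.max(axis=1)
    emit = np.exp(log_emit - shift[:, None])
    init = np.exp(log_init - log_init.max())
    init = init / init.sum()
    trans = np.exp(log_trans)

    alpha = np.empty((n, k))
    c = np.empty(n)
    a = init * emit[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ trans) * emit[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shift.sum())

    beta = np.empty((n, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(n - 2, -1, -1):
        eb = emit[t + 1] * beta[t + 1]
        beta[t] = (trans @ eb) / c[t + 1]
        xi_sum += alpha[t][:, None] * trans * eb[None, :] / c[t + 1]
    gamma = alpha * beta
    return gamma, xi_sum, loglik
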