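"""Per-CpG cross-sample testing and false-discovery-rate control.

Each CpG inside a reference UMR is tested for a cohort difference in
methylation level with a two-tailed t-test (Welch by default), p-values are
adjusted genome-wide with Benjamini-Hochberg, and a CpG is flagged
statistically hypermethylated when q < 0.05 and the tumor-minus-normal
difference is at least +0.2.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests


def cpg_ttest(
    normal_levels: np.ndarray,
    tumor_levels: np.ndarray,
    equal_var: bool = False,
) -> float:
    """Two-sided t-test p-value for one CpG; NaN when undefined.

    Undefined (masked) when either cohort detects the CpG in fewer than two
    samples or when both cohorts are constant (zero pooled variance).
    """
    a = np.asarray(normal_levels, dtype=float)
    b = np.asarray(tumor_levels, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return np.nan
    return float(_sps.ttest_ind(a, b, equal_var=equal_var).pvalue)


def cpg_ttest_matrix(
    normal: np.ndarray, tumor: np.ndarray, equal_var: bool = False
) -> np.ndarray:
    """Row-wise two-sided t-test p-values for a site x sample matrix pair.

    Rows with fewer than two finite values in either cohort, or zero variance
    in both cohorts, are masked (NaN).
    """
    normal = np.asarray(normal, dtype=float)
    tumor = np.asarray(tumor, dtype=float)
    n_a = np.isfinite(normal).sum(axis=1)
    n_b = np.isfinite(tumor).sum(axis=1)
    with np.errstate(invalid="ignore"):
        var_a = np.nanvar(normal, axis=1, ddof=1)
        var_b = np.nanvar(tumor, axis=1, ddof=1)
        res = _sps.ttest_ind(
            normal, tumor, axis=1, equal_var=equal_var, nan_policy="omit"
        )
        p = np.asarray(res.pvalue, dtype=float)
    bad = (n_a < 2) | (n_b < 2) | ((var_a == 0.0) & (var_b == 0.0))
    p[bad] = np.nan
    return p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing (NaN) entries are excluded from the adjustment and stay NaN; all
    finite inputs must lie in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def stat_hyper_flags(
    deltas: np.ndarray,
    q_values: np.ndarray,
    q_max: float = 0.05,
    delta_min: float = 0.2,
    use_absolute: bool = False,
) -> np.ndarray:
    """Statistical Hyper flag: q < q_max and delta >= +delta_min.

    ``use_absolute=True`` applies the threshold to |delta| instead of the
    signed tumor-minus-normal difference.
    """
    deltas = np.asarray(deltas, dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    effect = np.abs(deltas) if use_absolute else deltas
    with np.errstate(invalid="ignore"):
        flags = (q_values < q_max) & (effect >= delta_min)
    flags[~np.isfinite(q_values) | ~np.isfinite(deltas)] = False
    return flags
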