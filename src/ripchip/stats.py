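"""Shared statistical primitives: pooled two-sample t-test, Benjamini-
Hochberg FDR, and signed linear fold change.

The t-test is the classical equal-variance Student's t.  Replicate groups
here are biological triplicates measured under one protocol, so a pooled
variance is the conventional choice; Welch can be substituted by callers
that compute their own statistic.  Degenerate zero-variance groups — which
tiny synthetic fixtures can produce — are resolved deterministically:
identical means give p = 1, different means give p = 0 with a +/-inf
statistic sentinel.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "t_test", "t_test_rows", "bh_fdr", "fold_change"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float


def t_test_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance two-sided t-test.

    Parameters
    ----------
    a, b : arrays of shape (n_rows, n_a) and (n_rows, n_b), n_a, n_b >= 2.

    Returns
    -------
    (statistic, p_value) arrays of length n_rows.  Rows with zero pooled
    variance get statistic 0 / p 1 when the means agree and +/-inf / p 0
    when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("a and b must be 2-D with matching row counts")
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 replicates (got {na} and {nb})")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    pooled = (ssa + ssb) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = diff / se
    p = 2.0 * scipy.stats.t.sf(np.abs(stat), df)
    zero_var = se == 0
    equal = zero_var & (diff == 0)
    unequal = zero_var & (diff != 0)
    stat[equal] = 0.0
    p[equal] = 1.0
    stat[unequal] = np.sign(diff[unequal]) * np.inf
    p[unequal] = 0.0
    return stat, p


def t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided pooled-variance Student's t-test on two replicate groups."""
    a_arr = np.asarray(a, dtype=float)[None, :]
    b_arr = np.asarray(b, dtype=float)[None, :]
    stat, p = t_test_rows(a_arr, b_arr)
    df = a_arr.shape[1] + b_arr.shape[1] - 2
    return TestResult(
        statistic=float(stat[0]),
        p_value=float(p[0]),
        df=float(df),
        mean_a=float(a_arr.mean()),
        mean_b=float(b_arr.mean()),
    )


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_i = min_{j >= rank(i)} p_(j) * m / j, clipped to 1.
    """
    p_arr = np.asarray(p, dtype=float)
    if p_arr.size == 0:
        return p_arr.copy()
    if np.any((p_arr < 0) | (p_arr > 1) | np.isnan(p_arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p_arr, method="fdr_bh")[1]


def fold_change(mean_log2_a: float, mean_log2_b: float) -> tuple[float, str]:
    """Signed linear fold between two log2 means.

    Returns (fold >= 1, direction), direction "up" when a > b else "down";
    equal means give (1.0, "up").
    """
    r = 2.0 ** (mean_log2_a - mean_log2_b)
    if r >= 1:
        return float(r), "up"
    return float(1.0 / r), "down"
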