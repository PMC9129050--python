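"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the package's own code paths: matchings are
enumerated recursively, randomization p-values are enumerated over all
sign patterns, and the meta-regression fixed point is solved by root
finding on the moment equation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import brentq


def brute_force_max_matching(edges: list[tuple[int, int]],
                             n_left: int) -> int:
    """Maximum matching cardinality by exhaustive recursion (small graphs)."""
    adj: dict[int, list[int]] = {i: [] for i in range(n_left)}
    for i, j in edges:
        adj[i].append(j)

    def rec(i: int, used: frozenset[int]) -> int:
        if i == n_left:
            return 0
        best = rec(i + 1, used)  # leave i unmatched
        for j in adj[i]:
            if j not in used:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


def enumerate_pair_flip_pvalue(pair_diffs: np.ndarray, statistic,
                               two_sided: bool = False) -> float:
    """Exact randomization p-value over all 2^P within-pair sign flips.

    ``pair_diffs`` are the observed per-pair outcome differences
    (exposed minus control); ``statistic`` maps a signed difference
    vector to a scalar.  The observed assignment is the all-+1 pattern.
    """
    P = len(pair_diffs)
    t_obs = statistic(pair_diffs)
    vals = []
    for signs in itertools.product((1, -1), repeat=P):
        vals.append(statistic(np.asarray(signs) * pair_diffs))
    vals = np.asarray(vals)
    if two_sided:
        vals, t_obs = np.abs(vals), abs(t_obs)
    return float(np.count_nonzero(vals >= t_obs) / vals.size)


def betta_oracle(y: np.ndarray, ses: np.ndarray, w: np.ndarray) -> float:
    """Meta-regression coefficient by root-finding the moment equation.

    Finds sigma_u^2 >= 0 solving sum_i w_i(s) r_i(s)^2 = n - 2 with
    w_i(s) = 1/(se_i^2 + s), then returns the GLS exposure coefficient --
    an independent route to the package's iterated fixed point.
    """
    y = np.asarray(y, float)
    s2 = np.asarray(ses, float) ** 2
    w = np.asarray(w, float)
    X = np.column_stack([np.ones_like(y), w])
    n, k = X.shape

    def gls_beta(s: float) -> np.ndarray:
        wt = 1.0 / (s2 + s)
        XtW = X.T * wt
        return np.linalg.solve(XtW @ X, XtW @ y)

    def moment(s: float) -> float:
        beta = gls_beta(s)
        r = y - X @ beta
        return float((r ** 2 / (s2 + s)).sum() - (n - k))

    if moment(0.0) <= 0:
        s_star = 0.0
    else:
        hi = 1.0
        while moment(hi) > 0:
            hi *= 10
            if hi > 1e12:
                raise RuntimeError("oracle failed to bracket sigma_u^2")
        s_star = brentq(moment, 0.0, hi, xtol=1e-12)
    return float(gls_beta(s_star)[1])


def double_center_kernel(d: np.ndarray) -> np.ndarray:
    """Gower double-centering written element-wise (independent route)."""
    d2 = d * d
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    return -0.5 * (d2 - row - col + d2.mean())
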