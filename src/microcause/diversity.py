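"""Alpha-diversity estimation and the diversity / beta-diversity tests.

Per-sample richness (Chao1) and Shannon estimates carry standard errors;
the randomization test statistic is the exposure coefficient of a
measurement-error-aware meta-regression (iterated GLS with a
Paule-Mandel-type moment estimate of the between-sample variance).
Externally computed (estimate, SE) tables can be injected in place of
the built-in estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .composition import DistanceMatrix, distance, distance_to_kernel
from .io import CountMatrix
from .matching import MatchedDesign
from .randomization import (AssignmentMatrix, NullDistribution, TestResult,
                            exposure_matrix, minp_adjust,
                            randomization_pvalue)

__all__ = [
    "DiversityEstimate",
    "plugin_shannon",
    "observed_richness",
    "chao1_richness",
    "bootstrap_se",
    "estimate_diversity",
    "betta_coefficient",
    "diversity_randomization_test",
    "mirkat_score",
    "beta_diversity_test",
]


@dataclass
class DiversityEstimate:
    """Per-sample diversity estimates with standard errors."""

    estimates: np.ndarray
    ses: np.ndarray
    estimator: str
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if self.estimates.shape != self.ses.shape:
            raise ValueError("estimates and SEs must align")
        if not np.isfinite(self.ses).all() or (self.ses < 0).any():
            raise ValueError("standard errors must be finite and >= 0")


def plugin_shannon(counts_row: np.ndarray) -> float:
    """Plug-in Shannon entropy -sum p log p in nats (zero cells contribute 0)."""
    row = np.asarray(counts_row, dtype=float)
    total = row.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon entropy of an all-zero row")
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum())


def observed_richness(counts_row: np.ndarray) -> int:
    row = np.asarray(counts_row)
    if row.sum() <= 0:
        raise ValueError("cannot compute richness of an all-zero row")
    return int((row > 0).sum())


def chao1_richness(counts_row: np.ndarray) -> tuple[float, float]:
    """Chao1 richness estimate and its classical standard error.

    Uses S_obs + f1^2/(2 f2) when doubletons exist and the bias-corrected
    form S_obs + f1(f1-1)/2 when f2 = 0.
    """
    row = np.asarray(counts_row)
    s_obs = observed_richness(row)
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    if f2 > 0:
        r = f1 / f2
        est = s_obs + f1 * f1 / (2.0 * f2)
        var = f2 * (r ** 2 / 2 + r ** 3 + r ** 4 / 4)
    elif f1 > 0:
        est = s_obs + f1 * (f1 - 1) / 2.0
        var = (f1 * (f1 - 1) / 2.0 + f1 * (2 * f1 - 1) ** 2 / 4.0
               - f1 ** 4 / (4.0 * est))
    else:
        est, var = float(s_obs), 0.0
    return float(est), float(np.sqrt(max(var, 0.0)))


def bootstrap_se(counts_row: np.ndarray, statistic: Callable[[np.ndarray], float],
                 n_boot: int = 200, seed: int | None = 0) -> float:
    """Multinomial-bootstrap SE of ``statistic`` at the row's own depth."""
    if n_boot < 50:
        raise ValueError("n_boot must be at least 50")
    row = np.asarray(counts_row, dtype=float)
    depth = int(row.sum())
    if depth <= 0:
        raise ValueError("cannot bootstrap an all-zero row")
    p = row / row.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(depth, p, size=n_boot)
    vals = np.array([statistic(d) for d in draws], dtype=float)
    return float(vals.std(ddof=1))


def estimate_diversity(cm: CountMatrix, which: str = "shannon",
                       n_boot: int = 200, seed: int | None = 0,
                       external: pd.DataFrame | None = None
                       ) -> DiversityEstimate:
    """Per-sample (estimate, SE) pairs for richness or Shannon diversity.

    ``external`` may supply a table with columns ``estimate`` and ``se``
    indexed by sample id (e.g. from model-based estimators fit outside
    this package); it overrides the built-in plug-in estimators.
    """
    if external is not None:
        ext = external.loc[cm.sample_ids]
        return DiversityEstimate(ext["estimate"].to_numpy(),
                                 ext["se"].to_numpy(),
                                 estimator="external",
                                 sample_ids=list(cm.sample_ids))
    if which == "richness":
        pairs = [chao1_richness(row) for row in cm.counts]
        est = np.array([p[0] for p in pairs])
        ses = np.array([p[1] for p in pairs])
        return DiversityEstimate(est, ses, "chao1", list(cm.sample_ids))
    if which == "shannon":
        est = np.array([plugin_shannon(row) for row in cm.counts])
        ses = np.array([bootstrap_se(row, plugin_shannon, n_boot=n_boot,
                                     seed=None if seed is None else seed + i)
                        for i, row in enumerate(cm.counts)])
        return DiversityEstimate(est, ses, "plugin_shannon",
                                 list(cm.sample_ids))
    raise ValueError(f"unknown diversity index {which!r}")


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def betta_coefficient(estimates: np.ndarray, ses: np.ndarray, w: np.ndarray,
                      covariates: np.ndarray | None = None,
                      tol: float = 1e-8, max_iter: int = 100,
                      full_output: bool = False):
    """Exposure coefficient of the measurement-error meta-regression.

    Model: estimate_i = x_i'beta + u_i + e_i with Var(e_i) = se_i^2 known
    and u_i ~ (0, sigma_u^2).  sigma_u^2 is estimated by iterating the
    Paule-Mandel moment equation sum_i w_i r_i^2 = n - k with weights
    w_i = 1/(se_i^2 + sigma_u^2), truncating at zero, followed by a GLS
    solve.  Returns the coefficient of ``w`` (or a dict with details when
    ``full_output``).
    """
    y = np.asarray(estimates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.unique(w).size < 2 or min((w == 1).sum(), (w == 0).sum()) < 2:
        raise ValueError("need at least two samples per arm")
    cols = [np.ones_like(y), w]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != y.size:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular design matrix")

    s2 = ses ** 2
    sigma_u2 = 0.0
    beta = None
    for _ in range(max_iter):
        denom = s2 + sigma_u2
        wts = np.ones(n) if denom.max() == 0 else 1.0 / np.maximum(denom, 1e-12)
        beta = _wls(X, y, wts)
        resid = y - X @ beta
        q = float((wts * resid ** 2).sum())
        step = (q - (n - k)) / wts.sum()
        new = max(0.0, sigma_u2 + step)
        if abs(new - sigma_u2) < tol:
            sigma_u2 = new
            break
        sigma_u2 = new
    denom = s2 + sigma_u2
    wts = np.ones(n) if denom.max() == 0 else 1.0 / np.maximum(denom, 1e-12)
    beta = _wls(X, y, wts)
    if full_output:
        return {"beta": beta, "beta1": float(beta[1]), "sigma_u2": sigma_u2,
                "weights": wts}
    return float(beta[1])


def _betta_columns(y: np.ndarray, ses: np.ndarray, Wmat: np.ndarray,
                   tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Vectorized intercept+exposure meta-regression over assignment columns.

    Solves the same iterated Paule-Mandel / GLS fixed point as
    :func:`betta_coefficient` for every column of ``Wmat`` (n x L) at
    once, exploiting the closed-form 2x2 normal equations.
    """
    n, L = Wmat.shape
    s2 = ses ** 2
    su2 = np.zeros(L)
    k = 2

    def _solve(su2):
        denom = s2[:, None] + su2[None, :]
        wts = np.ones((n, L)) if denom.max() == 0 \
            else 1.0 / np.maximum(denom, 1e-12)
        a = wts.sum(axis=0)
        b = (wts * Wmat).sum(axis=0)
        c = (wts * y[:, None]).sum(axis=0)
        d = (wts * Wmat * y[:, None]).sum(axis=0)
        beta1 = (a * d - b * c) / (b * (a - b))
        beta0 = (c - beta1 * b) / a
        resid = y[:, None] - beta0[None, :] - beta1[None, :] * Wmat
        q = (wts * resid ** 2).sum(axis=0)
        return beta1, a, q

    for _ in range(max_iter):
        _, a, q = _solve(su2)
        new = np.maximum(0.0, su2 + (q - (n - k)) / a)
        done = np.abs(new - su2).max() < tol
        su2 = new
        if done:
            break
    beta1, _, _ = _solve(su2)
    return beta1


def diversity_randomization_test(cm: CountMatrix, design: MatchedDesign,
                                 assignments: AssignmentMatrix,
                                 which: str = "shannon", n_boot: int = 200,
                                 seed: int | None = 0,
                                 covariates: np.ndarray | None = None,
                                 external: pd.DataFrame | None = None,
                                 sidedness: str = "less") -> TestResult:
    """Randomization test of no diversity effect via the meta-regression
    coefficient.

    Estimates and SEs are computed once on the matched samples; only the
    exposure labels are permuted within pairs.  Default sidedness is
    ``less`` (alternative: lower diversity under exposure).
    """
    sub = cm.subset_samples(design.sample_order())
    est = estimate_diversity(sub, which=which, n_boot=n_boot, seed=seed,
                             external=external)
    W = exposure_matrix(assignments)
    if covariates is None:
        stats = _betta_columns(est.estimates, est.ses, W.astype(float))
    else:
        stats = np.array([betta_coefficient(est.estimates, est.ses, W[:, l],
                                            covariates=covariates)
                          for l in range(assignments.n_iter)])
    null = NullDistribution(stats[None, :], [sidedness], [which])
    p = randomization_pvalue(null, 0)
    return TestResult(name=f"diversity_{which}", observed=float(stats[0]),
                      p=p, sidedness=sidedness, null=stats,
                      extras={"estimator": est.estimator})


def mirkat_score(K: np.ndarray, w: np.ndarray) -> float:
    """Kernel variance-component score statistic Q = r' K r, r = w - mean(w).

    ``K`` must be row/column centered (intercept-only null model).
    """
    K = np.asarray(K, dtype=float)
    scale = max(1.0, float(np.abs(K).max()))
    if np.abs(K.sum(axis=1)).max() > 1e-6 * scale * K.shape[0]:
        raise ValueError("kernel is not centered")
    r = np.asarray(w, dtype=float)
    r = r - r.mean()
    return float(r @ K @ r)


def beta_diversity_test(cm: CountMatrix, design: MatchedDesign,
                        assignments: AssignmentMatrix,
                        metrics: Sequence[str] = ("aitchison", "jaccard",
                                                  "gower_clr"),
                        tree: str | None = None, pseudocount: float = 1.0,
                        sidedness: str = "greater"
                        ) -> dict[str, TestResult]:
    """Kernel score tests across beta-diversity metrics with min-p adjustment.

    One kernel per metric; the per-metric p-values are adjusted jointly
    using the shared assignment matrix (the metrics form one hypothesis
    family).
    """
    sub = cm.subset_samples(design.sample_order())
    kernels = {}
    for metric in metrics:
        D = distance(sub, metric, tree=tree, pseudocount=pseudocount)
        kernels[metric], _ = distance_to_kernel(D)

    W = exposure_matrix(assignments).astype(float)
    R = W - W.mean(axis=0, keepdims=True)
    stats = np.empty((len(kernels), assignments.n_iter))
    for h, metric in enumerate(kernels):
        KR = kernels[metric] @ R
        stats[h] = (KR * R).sum(axis=0)
    null = NullDistribution(stats, [sidedness] * len(kernels), list(kernels))
    p_unadj, p_adj = minp_adjust(null)
    results = {}
    for h, metric in enumerate(kernels):
        results[metric] = TestResult(
            name=f"beta_{metric}", observed=float(stats[h, 0]),
            p=float(p_unadj[h]), sidedness=sidedness, null=stats[h],
            p_adjusted=float(p_adj[h]))
    return results
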