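"""Compositional mean-equivalence and per-taxon differential abundance.

The high-dimensional mean test uses the studentized max-CLR statistic;
per-taxon tests normalize each candidate taxon by a data-adaptive
reference set of low-dispersion, high-prevalence taxa and compare log
ratios between arms, with min-p multiplicity adjustment across taxa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import ClrMatrix, aggregate_rank, clr_transform
from .io import CountMatrix
from .matching import MatchedDesign
from .randomization import (AssignmentMatrix, NullDistribution, TestResult,
                            exposure_matrix, minp_adjust,
                            randomization_pvalue)

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSet",
    "tm_statistic",
    "compositional_mean_test",
    "select_references",
    "normalize_by_ratio",
    "logfold_statistic",
    "differential_abundance_test",
]


@dataclass
class ReferenceSet:
    """Presumed non-differential taxa used as the normalization denominator."""

    taxon_ids: list[str]
    scores: pd.DataFrame = field(repr=False)     # dispersion + prevalence
    dispersion_threshold: float = np.nan
    prevalence_threshold: float = np.nan
    relaxed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxon_ids) < 1:
            raise ValueError("reference set must contain at least one taxon")


def _tm_columns(values: np.ndarray, W: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Max studentized squared CLR mean difference for every assignment column.

    The pooled variance is the n-denominator pooled within-arm variance
    (sum of squared deviations around each arm mean over n), which makes
    the statistic exactly invariant to duplicating every sample apart
    from the doubled N-factor.
    """
    n = values.shape[0]
    W = W.astype(float)
    n_e = W.sum(axis=0)
    n_c = n - n_e
    X, X2 = values, values ** 2
    se = X.T @ W                   # (taxa, iters) sums over exposed
    sc = X.T.sum(axis=1, keepdims=True) - se
    me, mc = se / n_e, sc / n_c
    qe = X2.T @ W
    qc = X2.T.sum(axis=1, keepdims=True) - qe
    pooled = ((qe - n_e * me ** 2) + (qc - n_c * mc ** 2)) / n
    pooled = np.maximum(pooled, 0.0)          # guard fp cancellation
    diff2 = (me - mc) ** 2
    degenerate = pooled <= 1e-12
    if degenerate.any():
        bad_and_shifted = degenerate & (diff2 > 1e-20)
        if bad_and_shifted.any():
            raise ValueError(
                "taxon with zero pooled CLR variance but nonzero mean "
                "difference: statistic undefined")
        warnings.warn("taxa with zero pooled CLR variance dropped from the "
                      "max statistic", stacklevel=2)
        diff2 = np.where(degenerate, 0.0, diff2)
        pooled = np.where(degenerate, 1.0, pooled)
    ratio = diff2 / pooled
    factor = n_e * n_c / (n_e + n_c)
    stats = factor * ratio.max(axis=0)
    argmax = ratio.argmax(axis=0)
    return stats, argmax


def tm_statistic(L: ClrMatrix, w: np.ndarray) -> tuple[float, str]:
    """Studentized max-CLR mean-difference statistic.

    T = (N_E N_C / (N_E + N_C)) * max_a (mean_E L_a - mean_C L_a)^2 /
    pooled variance of L_a.  Returns the statistic and the argmax taxon.
    """
    w = np.asarray(w)
    if w.sum() == 0 or w.sum() == w.size:
        raise ValueError("both arms must be nonempty")
    stats, argmax = _tm_columns(L.values, w.astype(float)[:, None])
    return float(stats[0]), L.taxon_ids[int(argmax[0])]


def compositional_mean_test(cm: CountMatrix, design: MatchedDesign,
                            assignments: AssignmentMatrix,
                            ranks: Sequence[str] = ("Genus",),
                            pseudocount: float = 1.0,
                            sidedness: str = "greater"
                            ) -> dict[str, TestResult]:
    """Mean-equivalence randomization test at each requested rank.

    Each rank is aggregated, CLR transformed, and tested with the max
    statistic; p-values are one-sided and reported per rank without
    cross-rank adjustment.
    """
    sub = cm.subset_samples(design.sample_order())
    W = exposure_matrix(assignments).astype(float)
    results = {}
    for rank in ranks:
        agg = aggregate_rank(sub, rank)
        L = clr_transform(agg, pseudocount)
        stats, argmax = _tm_columns(L.values, W)
        null = NullDistribution(stats[None, :], [sidedness], [str(rank)])
        p = randomization_pvalue(null, 0)
        results[rank] = TestResult(
            name=f"tm_{rank}", observed=float(stats[0]), p=p,
            sidedness=sidedness, null=stats,
            extras={"argmax_taxon": agg.taxon_ids[int(argmax[0])],
                    "n_taxa": agg.n_taxa})
    return results


def select_references(cm: CountMatrix, dispersion_threshold: float = 2.0,
                      prevalence_threshold: float = 0.9,
                      pseudocount: float = 1.0) -> ReferenceSet:
    """Data-adaptive reference taxa: low dispersion, high prevalence.

    The dispersion score of taxon a is the median over the other taxa a'
    of the across-sample SD of log((C_a + pc)/(C_a' + pc)).  Taxa with
    score < ``dispersion_threshold`` and prevalence > ``prevalence_threshold``
    enter the set.  If some sample then has a zero reference sum, the
    next-lowest-dispersion taxa with prevalence above the threshold are
    added (logged as a relaxation) until every sample is covered.
    """
    if dispersion_threshold <= 0 or prevalence_threshold <= 0:
        raise ValueError("thresholds must be positive")
    counts = cm.counts.astype(float)
    logc = np.log(counts + pseudocount)
    A = cm.n_taxa
    disp = np.empty(A)
    for a in range(A):
        sds = (logc[:, [a]] - logc).std(axis=0, ddof=1)
        disp[a] = np.median(np.delete(sds, a))
    prevalence = (counts > 0).mean(axis=0)
    scores = pd.DataFrame({"dispersion": disp, "prevalence": prevalence},
                          index=pd.Index(cm.taxon_ids, name="taxon_id"))

    selected = (disp < dispersion_threshold) & (prevalence > prevalence_threshold)
    relaxed: list[str] = []
    order = np.argsort(disp, kind="stable")
    ref_counts = counts[:, selected].sum(axis=1) if selected.any() \
        else np.zeros(cm.n_samples)
    for a in order:
        if (ref_counts > 0).all() and selected.any():
            break
        if selected[a] or prevalence[a] <= prevalence_threshold:
            continue
        selected[a] = True
        relaxed.append(cm.taxon_ids[a])
        ref_counts = ref_counts + counts[:, a]
    if not selected.any() or not (ref_counts > 0).all():
        raise ValueError("no admissible reference set covers every sample")
    if relaxed:
        logger.warning("reference set relaxed beyond the dispersion "
                       "threshold to cover all samples: %s", relaxed)
    ids = [t for t, s in zip(cm.taxon_ids, selected) if s]
    return ReferenceSet(taxon_ids=ids, scores=scores,
                        dispersion_threshold=dispersion_threshold,
                        prevalence_threshold=prevalence_threshold,
                        relaxed=relaxed)


def normalize_by_ratio(cm: CountMatrix, taxon: str,
                       refs: ReferenceSet) -> np.ndarray:
    """Per-sample value v_i = C_ia / (C_ia + sum of reference counts)."""
    if taxon in refs.taxon_ids:
        raise ValueError(f"taxon {taxon!r} is in the reference set")
    j = cm.taxon_ids.index(taxon)
    ridx = [cm.taxon_ids.index(r) for r in refs.taxon_ids]
    ref_sum = cm.counts[:, ridx].sum(axis=1).astype(float)
    c = cm.counts[:, j].astype(float)
    denom = c + ref_sum
    if (denom <= 0).any():
        raise ValueError("zero reference sum encountered: reference-set "
                         "invariant violated")
    return np.where(c > 0, c / denom, 0.0)


def logfold_statistic(v: np.ndarray, w: np.ndarray,
                      eps: float) -> float:
    """Difference of arm means of log(v + eps) (exposed minus control)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    lv = np.log(np.asarray(v, dtype=float) + eps)
    w = np.asarray(w).astype(bool)
    return float(lv[w].mean() - lv[~w].mean())


def differential_abundance_test(cm: CountMatrix, design: MatchedDesign,
                                assignments: AssignmentMatrix,
                                refs: ReferenceSet | None = None,
                                eps: float | None = None,
                                dispersion_threshold: float = 2.0,
                                prevalence_threshold: float = 0.9,
                                pseudocount: float = 1.0) -> pd.DataFrame:
    """Two-sided randomization tests of no differential abundance per taxon.

    Reference taxa are excluded from testing; the remaining taxa share
    one assignment matrix and are adjusted jointly by the min-p method.
    ``eps`` defaults to 1/(2 * max sequencing depth).
    """
    sub = cm.subset_samples(design.sample_order())
    if refs is None:
        refs = select_references(sub, dispersion_threshold,
                                 prevalence_threshold, pseudocount)
    if eps is None:
        eps = 1.0 / (2.0 * float(sub.counts.sum(axis=1).max()))
    tested = [t for t in sub.taxon_ids if t not in refs.taxon_ids]
    if not tested:
        raise ValueError("no taxa left to test outside the reference set")

    logv = np.empty((sub.n_samples, len(tested)))
    for j, taxon in enumerate(tested):
        logv[:, j] = np.log(normalize_by_ratio(sub, taxon, refs) + eps)

    W = exposure_matrix(assignments).astype(float)
    n_e = W.sum(axis=0)
    n_c = W.shape[0] - n_e
    sums_e = logv.T @ W
    sums_all = logv.T.sum(axis=1, keepdims=True)
    stats = sums_e / n_e - (sums_all - sums_e) / n_c     # (taxa, iters)

    null = NullDistribution(stats, ["two-sided"] * len(tested), tested)
    p_unadj, p_adj = minp_adjust(null)
    return pd.DataFrame({
        "taxon": tested,
        "statistic": stats[:, 0],
        "p": p_unadj,
        "p_adj": p_adj,
        "sign": np.sign(stats[:, 0]).astype(int),
        "eps": eps,
    })
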