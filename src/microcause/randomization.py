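"""Matched-pair randomization inference.

Within-pair label permutations, Fisher-style randomization p-values, and
the fully permutation-based min-p multiple-comparison adjustment.  The
observed assignment is always column 0 of the assignment matrix and is
counted in every p-value numerator, so p >= 1/n_iter by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssignmentMatrix",
    "NullDistribution",
    "TestResult",
    "generate_assignments",
    "randomization_pvalue",
    "minp_adjust",
    "run_test",
    "exposure_matrix",
]

VALID_SIDEDNESS = ("greater", "less", "two-sided")


@dataclass
class AssignmentMatrix:
    """Per-pair exposure flips, one column per hypothetical assignment.

    ``flips[k, l] == 0`` means pair ``k`` keeps its observed orientation in
    iteration ``l`` (the originally exposed member is labelled exposed);
    ``1`` means the labels are swapped.  Column 0 is the observed
    assignment (all zeros).
    """

    flips: np.ndarray          # (n_pairs, n_iter) of uint8
    seed: int | None
    exhaustive: bool

    @property
    def n_pairs(self) -> int:
        return self.flips.shape[0]

    @property
    def n_iter(self) -> int:
        return self.flips.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.flips,
                     index=[f"pair_{k}" for k in range(self.n_pairs)],
                     columns=[f"iter_{l}" for l in range(self.n_iter)]
                     ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AssignmentMatrix":
        """Import a pairs x iterations 0/1 matrix, validating the contract.

        Columns must be unique; entries binary; the observed (all-zero)
        column must be present and is moved to position 0 if necessary.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        flips = df.to_numpy()
        if not np.isin(flips, (0, 1)).all():
            raise ValueError("assignment matrix entries must be 0 or 1")
        flips = flips.astype(np.uint8)
        keys = [flips[:, l].tobytes() for l in range(flips.shape[1])]
        if len(set(keys)) != len(keys):
            raise ValueError("assignment matrix contains duplicate columns")
        zero = bytes(flips.shape[0])
        if zero not in keys:
            raise ValueError("observed (all-zero) assignment column missing")
        j = keys.index(zero)
        if j != 0:
            order = [j] + [l for l in range(flips.shape[1]) if l != j]
            flips = flips[:, order]
        exhaustive = (flips.shape[0] <= 30
                      and flips.shape[1] == 2 ** flips.shape[0])
        return cls(flips=flips, seed=None, exhaustive=exhaustive)


@dataclass
class NullDistribution:
    """Statistics for H hypotheses across every assignment column.

    ``stats[h, 0]`` is the observed statistic of hypothesis ``h``.
    """

    stats: np.ndarray               # (H, n_iter)
    sidedness: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stats = np.atleast_2d(np.asarray(self.stats, dtype=float))
        if self.stats.shape[0] < 1:
            raise ValueError("need at least one hypothesis")
        if isinstance(self.sidedness, str):
            self.sidedness = [self.sidedness] * self.stats.shape[0]
        if len(self.sidedness) != self.stats.shape[0]:
            raise ValueError("one sidedness per hypothesis required")
        for s in self.sidedness:
            if s not in VALID_SIDEDNESS:
                raise ValueError(f"unknown sidedness {s!r}")
        if not self.names:
            self.names = [f"h{h}" for h in range(self.stats.shape[0])]
        bad = np.argwhere(np.isnan(self.stats))
        if bad.size:
            h, l = bad[0]
            raise ValueError(
                f"NaN statistic for hypothesis {self.names[h]!r} "
                f"at iteration {l}")


@dataclass
class TestResult:
    """Outcome of a single randomization test."""

    name: str
    observed: float
    p: float
    sidedness: str
    null: np.ndarray = field(repr=False)
    p_adjusted: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"name": self.name, "observed": float(self.observed),
             "p": float(self.p), "sidedness": self.sidedness,
             "n_iter": int(self.null.size)}
        if self.p_adjusted is not None:
            d["p_adjusted"] = float(self.p_adjusted)
        d.update({k: v for k, v in self.extras.items()
                  if np.isscalar(v) or isinstance(v, str)})
        return d


def generate_assignments(design, n_iter: int,
                         seed: int | None = 0) -> AssignmentMatrix:
    """Generate within-pair assignment permutations.

    ``design`` may be a :class:`~microcause.matching.MatchedDesign` or an
    integer number of pairs.  If ``2**n_pairs <= n_iter`` all assignments
    are enumerated (exact test); otherwise ``n_iter`` distinct columns are
    sampled uniformly without replacement, with the observed assignment
    included as column 0.
    """
    n_pairs = design if isinstance(design, (int, np.integer)) \
        else design.n_pairs
    if n_pairs < 1:
        raise ValueError("need at least one pair")
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")

    if n_pairs <= 62 and 2 ** n_pairs <= n_iter:
        total = 2 ** n_pairs
        cols = np.arange(total, dtype=np.uint64)
        flips = ((cols[None, :] >> np.arange(n_pairs, dtype=np.uint64)[:, None])
                 & 1).astype(np.uint8)
        return AssignmentMatrix(flips=flips, seed=seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    flips = np.zeros((n_pairs, n_iter), dtype=np.uint8)
    seen = {flips[:, 0].tobytes()}
    filled = 1
    while filled < n_iter:
        # draw in blocks, rejecting duplicates via a hash set
        block = rng.integers(0, 2, size=(n_pairs, 2 * (n_iter - filled)),
                             dtype=np.uint8)
        for l in range(block.shape[1]):
            key = block[:, l].tobytes()
            if key in seen:
                continue
            seen.add(key)
            flips[:, filled] = block[:, l]
            filled += 1
            if filled == n_iter:
                break
    return AssignmentMatrix(flips=flips, seed=seed, exhaustive=False)


def exposure_matrix(assignments: AssignmentMatrix) -> np.ndarray:
    """Per-sample exposure indicators for every assignment column.

    Rows follow the design's canonical sample order: the P observed
    exposed members first, then their P matched controls.  Returns a
    (2P, n_iter) 0/1 array.
    """
    f = assignments.flips
    return np.vstack([1 - f, f]).astype(np.int8)


def _extremize(stats: np.ndarray, sidedness: str) -> np.ndarray:
    """Map statistics onto a 'larger is more extreme' scale."""
    if sidedness == "greater":
        return stats
    if sidedness == "less":
        return -stats
    return np.abs(stats)


def _row_pvalues(t: np.ndarray) -> np.ndarray:
    """p_l = (1/L) * #{l': t_l' >= t_l}, for every l, via sorting."""
    L = t.size
    order = np.sort(t)
    # count strictly-less, so that ties count in the numerator
    n_lt = np.searchsorted(order, t, side="left")
    return (L - n_lt) / L


def randomization_pvalue(null: NullDistribution, h: int = 0) -> float:
    """Fisher randomization p-value for hypothesis ``h``.

    p = (1/N_iter) * sum_l 1{T_l >= T_obs}; two-sided tests take absolute
    values of both first.  The observed column counts toward the
    numerator, so p >= 1/N_iter.
    """
    t = _extremize(null.stats[h], null.sidedness[h])
    return float(np.count_nonzero(t >= t[0]) / t.size)


def minp_adjust(null: NullDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Permutation min-p multiplicity adjustment over all hypotheses.

    All rows of ``null.stats`` must come from the same assignment matrix
    so their joint randomization distribution is preserved.  Returns
    ``(p_unadjusted, p_adjusted)``; the adjusted p of hypothesis ``h`` is
    the proportion of per-iteration minimum p-values that are <= its
    unadjusted p.
    """
    H, L = null.stats.shape
    pmat = np.empty((H, L))
    for h in range(H):
        pmat[h] = _row_pvalues(_extremize(null.stats[h], null.sidedness[h]))
    p_unadj = pmat[:, 0].copy()
    m = pmat.min(axis=0)
    p_adj = np.array([np.count_nonzero(m <= p) / L for p in p_unadj])
    return p_unadj, p_adj


def run_test(statistic_fn: Callable[[np.ndarray], float],
             assignments: AssignmentMatrix,
             sidedness: str = "greater",
             name: str = "statistic") -> TestResult:
    """Apply ``statistic_fn`` under every assignment column.

    ``statistic_fn`` receives the per-sample exposure vector (canonical
    order: exposed block then control block) and must be a pure function
    of it and of data captured in its closure.
    """
    if sidedness not in VALID_SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    W = exposure_matrix(assignments)
    stats = np.empty(assignments.n_iter)
    for l in range(assignments.n_iter):
        try:
            stats[l] = statistic_fn(W[:, l])
        except Exception as exc:               # noqa: BLE001 - annotate column
            raise RuntimeError(
                f"statistic {name!r} failed at assignment column {l}: {exc}"
            ) from exc
    null = NullDistribution(stats[None, :], [sidedness], [name])
    p = randomization_pvalue(null, 0)
    return TestResult(name=name, observed=float(stats[0]), p=p,
                      sidedness=sidedness, null=stats)
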