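"""Compositional transforms, taxonomic aggregation, distances and kernels.

The centered log-ratio (CLR) transform is the shared currency of the
compositional analyses; four beta-diversity distances (unweighted
UniFrac, Aitchison, Jaccard, Gower-on-CLR) and the distance-to-kernel
construction used by the kernel score test live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import RANKS, CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClrMatrix",
    "DistanceMatrix",
    "clr_transform",
    "aggregate_rank",
    "prevalence_filter",
    "distance",
    "distance_to_kernel",
    "unweighted_unifrac",
]

METRICS = ("aitchison", "jaccard", "gower_clr", "unifrac_unweighted")


@dataclass
class ClrMatrix:
    """Centered log-ratio values; every row sums to zero."""

    values: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    pseudocount: float
    gmeans: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        rows = np.abs(self.values.sum(axis=1))
        if rows.max(initial=0.0) > 1e-9:
            raise ValueError("CLR rows must sum to zero")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    metric: str
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix must have a zero diagonal")


def _as_counts(data) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(data, CountMatrix):
        return data.counts.astype(float), data.sample_ids, data.taxon_ids
    arr = np.asarray(data, dtype=float)
    return arr, [f"s{i}" for i in range(arr.shape[0])], \
        [f"t{j}" for j in range(arr.shape[1])]


def clr_transform(data, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform L_ia = log((C_ia+pc)/g(C_i+pc)).

    ``pseudocount`` must be positive whenever zeros are present; with
    ``pseudocount=0`` the transform is exactly scale invariant.
    """
    counts, sample_ids, taxon_ids = _as_counts(data)
    if (counts.sum(axis=1) <= 0).any():
        raise ValueError("all-zero rows cannot be CLR transformed")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (counts <= 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    logc = np.log(counts + pseudocount)
    gmean_log = logc.mean(axis=1, keepdims=True)
    values = logc - gmean_log
    return ClrMatrix(values=values, sample_ids=list(sample_ids),
                     taxon_ids=list(taxon_ids), pseudocount=pseudocount,
                     gmeans=np.exp(gmean_log[:, 0]))


def aggregate_rank(cm: CountMatrix, rank: str) -> CountMatrix:
    """Sum counts over taxa sharing the same label at ``rank``.

    ``rank='ASV'`` (or ``None``) is the identity.  Taxa with an
    unassigned label at the rank are pooled per parent lineage (the
    nearest assigned coarser rank).
    """
    if rank is None or rank.upper() == "ASV":
        return cm
    if cm.taxonomy is None:
        raise ValueError("count matrix has no taxonomy attached")
    if rank not in cm.taxonomy.columns:
        raise ValueError(f"rank {rank!r} not present in taxonomy")
    missing = [t for t in cm.taxon_ids if t not in cm.taxonomy.index]
    if missing:
        raise ValueError(f"taxa missing from taxonomy: {missing}")

    coarser = [r for r in RANKS if r in cm.taxonomy.columns]
    labels = []
    for t in cm.taxon_ids:
        lab = cm.taxonomy.loc[t, rank]
        if pd.isna(lab) or lab == "":
            parent = "root"
            for r in coarser:
                if r == rank:
                    break
                val = cm.taxonomy.loc[t, r]
                if not (pd.isna(val) or val == ""):
                    parent = str(val)
            lab = f"unassigned_{rank}_of_{parent}"
        labels.append(str(lab))

    order = list(dict.fromkeys(labels))          # first-appearance order
    pos = {lab: i for i, lab in enumerate(order)}
    out = np.zeros((cm.n_samples, len(order)), dtype=cm.counts.dtype)
    for j, lab in enumerate(labels):
        out[:, pos[lab]] += cm.counts[:, j]
    return CountMatrix(out, list(cm.sample_ids), order, taxonomy=None)


def prevalence_filter(cm: CountMatrix, min_prevalence: float) -> CountMatrix:
    """Keep taxa with a positive count in at least ``min_prevalence`` of samples."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must lie in [0, 1]")
    prev = (cm.counts > 0).mean(axis=0)
    keep = prev >= min_prevalence
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    return cm.subset_taxa([t for t, k in zip(cm.taxon_ids, keep) if k])


def _gower_clr(values: np.ndarray) -> np.ndarray:
    """Gower distance on CLR columns: range-normalized mean |difference|."""
    rng = values.max(axis=0) - values.min(axis=0)
    scale = np.where(rng > 0, rng, 1.0)
    return squareform(pdist(values / scale, metric="cityblock") / values.shape[1])


def unweighted_unifrac(presence: np.ndarray, taxon_ids: list[str],
                       newick: str) -> np.ndarray:
    """Pairwise unweighted UniFrac from a presence matrix and a rooted tree.

    For each pair, the branch length found on the paths to exactly one
    sample's tip set, divided by the branch length on the paths to either
    tip set.  Tips of the tree not among ``taxon_ids`` are ignored; every
    analyzed taxon must map to exactly one tip.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tip_pos = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if label is not None:
            tip_pos[label.replace(" ", "_")] = leaf
    missing = [t for t in taxon_ids if t not in tip_pos]
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")

    # incidence of analyzed taxa below each edge, via postorder accumulation
    col = {t: j for j, t in enumerate(taxon_ids)}
    edges, lengths, below = [], [], {}
    for node in tree.postorder_node_iter():
        vec = np.zeros(len(taxon_ids), dtype=bool)
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_") if node.taxon else None
            if label in col:
                vec[col[label]] = True
        else:
            for child in node.child_nodes():
                vec |= below[child]
        below[node] = vec
        length = node.edge.length
        if node.parent_node is not None and length and vec.any():
            edges.append(vec)
            lengths.append(float(length))
    if not edges:
        raise ValueError("tree has no branches covering the analyzed taxa")
    E = np.array(edges)                       # (n_edges, n_taxa)
    bl = np.array(lengths)

    occupied = (presence.astype(bool) @ E.T)  # (n_samples, n_edges)
    wb = occupied * bl
    shared = wb @ occupied.T
    totals = occupied @ bl
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - shared) / union, 0.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2                      # symmetrize fp noise


def distance(data, metric: str, tree: str | None = None,
             pseudocount: float = 1.0) -> DistanceMatrix:
    """Pairwise distances under one of the four supported metrics.

    aitchison
        Euclidean distance between CLR rows.
    jaccard
        1 - |A & B| / |A | B| on presence/absence sets.
    gower_clr
        Gower's range-normalized mean absolute difference on CLR columns.
    unifrac_unweighted
        Requires ``tree`` (Newick string).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if isinstance(data, ClrMatrix):
        if metric in ("jaccard", "unifrac_unweighted"):
            raise ValueError(f"{metric} needs counts, not CLR values")
        values, sample_ids = data.values, data.sample_ids
    else:
        counts, sample_ids, taxon_ids = _as_counts(data)
        if metric in ("aitchison", "gower_clr"):
            values = clr_transform(counts, pseudocount).values
    if metric == "aitchison":
        d = squareform(pdist(values, metric="euclidean"))
    elif metric == "gower_clr":
        d = _gower_clr(values)
    elif metric == "jaccard":
        pres = counts > 0
        d = squareform(pdist(pres, metric="jaccard"))
    else:
        if tree is None:
            raise ValueError("unweighted UniFrac requires a tree")
        d = unweighted_unifrac(counts > 0, taxon_ids, tree)
    return DistanceMatrix(metric=metric, values=d, sample_ids=list(sample_ids))


def distance_to_kernel(D: DistanceMatrix | np.ndarray) -> tuple[np.ndarray, int]:
    """Centered kernel K = -1/2 J (D*D) J with PSD projection.

    J is the centering projector I - 11'/n.  Negative eigenvalues (which
    arise for non-Euclidean distances) are truncated to zero; the number
    truncated is returned alongside the kernel.  Row and column sums of K
    are zero.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * J @ (d * d) @ J
    K = (K + K.T) / 2
    vals, vecs = np.linalg.eigh(K)
    n_trunc = int(np.count_nonzero(vals < -1e-10 * max(1.0, vals.max(initial=0.0))))
    if n_trunc:
        logger.info("kernel PSD projection truncated %d negative eigenvalues",
                    n_trunc)
    K = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return (K + K.T) / 2, n_trunc
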