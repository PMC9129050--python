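"""Synthetic paired observational cohorts with known ground truth.

Counts follow a logistic-normal-multinomial model: per-arm latent
log-abundances are multivariate normal with a sparse precision matrix
(so network structure is carried natively), closed by softmax to
relative abundances and sampled multinomially at a negative-binomial
sequencing depth.  Exposure assignment is confounded by covariates via a
logistic model with fixed arm sizes.  Effects are injected on the latent
log scale (per-taxon log-fold shifts, a global evenness temperature) and
as deleted precision entries in the exposed arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, softmax

from .io import CountMatrix, write_json, write_newick
from .matching import CohortTable

__all__ = [
    "CohortConfig",
    "EffectSpec",
    "NetworkSpec",
    "DepthSpec",
    "SimulationTruth",
    "SimulatedCohort",
    "SimulationError",
    "simulate_cohort",
    "emit_cohort",
]

#: Default covariate distributions: family name -> (generator kwargs).
DEFAULT_COVARIATE_SPEC: dict[str, tuple[str, dict]] = {
    "age": ("normal", {"mean": 55.0, "sd": 8.0}),
    "sex": ("bernoulli", {"p": 0.5}),
    "bmi": ("normal", {"mean": 27.0, "sd": 4.0}),
    "alcohol": ("gamma", {"shape": 1.5, "scale": 10.0}),
    "diabetes": ("bernoulli", {"p": 0.10}),
    "activity": ("bernoulli", {"p": 0.55}),
}

#: Default log-odds of exposure per covariate unit.
DEFAULT_CONFOUNDING: dict[str, float] = {
    "age": 0.05, "sex": 0.8, "bmi": 0.06, "alcohol": 0.015,
    "diabetes": 0.5, "activity": -0.5,
}


class SimulationError(RuntimeError):
    pass


@dataclass
class NetworkSpec:
    """Latent association topology and base partial-correlation magnitude.

    ``edge_overrides`` assigns individual edges a different magnitude
    (e.g. one deliberately strong association), added on top of the
    topology's edge set.
    """

    topology: str = "chain"
    magnitude: float = 0.35
    edge_overrides: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology not in ("chain", "hub", "random"):
            raise ValueError("topology must be chain, hub or random")
        if not 0 <= self.magnitude < 0.5:
            raise ValueError("magnitude must lie in [0, 0.5)")


@dataclass
class DepthSpec:
    """Negative-binomial sequencing depth: mean and dispersion (size)."""

    mean: float = 10_000.0
    dispersion: float = 8.0

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.dispersion <= 0:
            raise ValueError("depth mean and dispersion must be positive")


@dataclass
class EffectSpec:
    """Injectable exposure effects; an empty spec is the sharp null."""

    taxon_log_folds: dict[int, float] = field(default_factory=dict)
    diversity_shift: float = 0.0
    removed_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_null(self) -> bool:
        return (not self.taxon_log_folds and self.diversity_shift == 0.0
                and not self.removed_edges)


@dataclass
class CohortConfig:
    """Full generative configuration; identical config + seed reproduces
    bit-identical output."""

    n_units_exposed: int
    n_units_control: int
    n_taxa: int
    seed: int = 0
    covariate_spec: Mapping[str, tuple[str, dict]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_SPEC))
    confounding_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDING))
    depth_spec: DepthSpec = field(default_factory=DepthSpec)
    network_spec: NetworkSpec = field(default_factory=NetworkSpec)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    #: bounds of the uniform per-taxon latent SD multipliers; set both to 1
    #: for homogeneous taxa (e.g. in network-recovery experiments)
    latent_scale_range: tuple[float, float] = (0.3, 1.25)

    def __post_init__(self) -> None:
        if min(self.n_units_exposed, self.n_units_control, self.n_taxa) <= 0:
            raise ValueError("unit and taxon counts must be positive")
        for a, lf in self.effect_spec.taxon_log_folds.items():
            if not 0 <= a < self.n_taxa:
                raise ValueError(f"affected taxon index {a} out of range")
            if not np.isfinite(lf):
                raise ValueError("log-fold shifts must be finite")
        for i, j in self.effect_spec.removed_edges:
            if not (0 <= i < self.n_taxa and 0 <= j < self.n_taxa and i != j):
                raise ValueError(f"invalid edge ({i}, {j})")
        lo, hi = self.latent_scale_range
        if not 0 < lo <= hi:
            raise ValueError("latent_scale_range must satisfy 0 < lo <= hi")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated cohort."""

    potential_relative_abundances: dict[int, np.ndarray]  # arm -> (N, A)
    potential_counts: dict[int, np.ndarray]               # arm -> (N, A)
    true_exposure_model: np.ndarray                       # (N,) probabilities
    true_differential_taxa: set[int]
    true_differential_edges: set[tuple[int, int]]
    true_network_precision: dict[int, np.ndarray]         # arm -> (A, A)

    def __post_init__(self) -> None:
        for w in (0, 1):
            z = self.potential_relative_abundances[w]
            if np.abs(z.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError("relative abundances must close to 1")


@dataclass
class SimulatedCohort:
    cohort: CohortTable
    counts: CountMatrix
    truth: SimulationTruth
    tree_newick: str
    config: CohortConfig


def _draw_covariate(rng: np.random.Generator, family: str, params: dict,
                    n: int) -> np.ndarray:
    if family == "normal":
        return rng.normal(params["mean"], params["sd"], n)
    if family == "bernoulli":
        return rng.binomial(1, params["p"], n).astype(float)
    if family == "gamma":
        return rng.gamma(params["shape"], params["scale"], n)
    if family == "uniform":
        return rng.uniform(params["low"], params["high"], n)
    raise ValueError(f"unknown covariate family {family!r}")


def _base_precision(A: int, spec: NetworkSpec,
                    rng: np.random.Generator) -> np.ndarray:
    m = spec.magnitude
    omega = np.eye(A)
    if A == 1:
        return omega
    if spec.topology == "chain":
        for i in range(A - 1):
            omega[i, i + 1] = omega[i + 1, i] = -m
    elif spec.topology == "hub":
        group = max(2, min(10, A))
        for start in range(0, A, group):
            hub = start
            for j in range(start + 1, min(start + group, A)):
                omega[hub, j] = omega[j, hub] = -m
    else:  # random: expected degree ~2
        prob = min(1.0, 2.0 / max(A - 1, 1))
        for i in range(A):
            for j in range(i + 1, A):
                if rng.random() < prob:
                    omega[i, j] = omega[j, i] = -m
    for (i, j), mag in spec.edge_overrides.items():
        omega[i, j] = omega[j, i] = -mag
    return _load_pd(omega, "base network")


def _load_pd(omega: np.ndarray, what: str,
             min_eig: float = 1e-3, max_loading: float = 1.0) -> np.ndarray:
    """Diagonal loading until the smallest eigenvalue exceeds ``min_eig``."""
    lam = float(np.linalg.eigvalsh(omega)[0])
    if lam >= min_eig:
        return omega
    loading = min_eig - lam + 1e-6
    if loading > max_loading:
        raise SimulationError(
            f"{what}: cannot restore positive definiteness by diagonal "
            f"loading (required {loading:.3g})")
    out = omega + loading * np.eye(omega.shape[0])
    if np.linalg.eigvalsh(out)[0] <= 0:
        raise SimulationError(f"{what}: loading failed")
    return out


def _effect_precision(omega0: np.ndarray,
                      edges: Sequence[tuple[int, int]]) -> np.ndarray:
    omega = omega0.copy()
    for i, j in edges:
        omega[i, j] = omega[j, i] = 0.0
    omega = (omega + omega.T) / 2
    try:
        return _load_pd(omega, f"precision after removing edges {sorted(edges)}")
    except SimulationError:
        raise SimulationError(
            f"precision not positive definite after deleting edges "
            f"{sorted(set(map(tuple, map(sorted, edges))))}") from None


def _random_tree(taxon_ids: Sequence[str], rng: np.random.Generator) -> str:
    """Random bifurcating topology with Exp(1) branch lengths (Newick)."""
    nodes = [f"{t}:{rng.exponential():.6f}" for t in taxon_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({a},{b})")
        else:
            nodes.append(f"({a},{b}):{rng.exponential():.6f}")
    return nodes[0] + ";"


def _default_taxonomy(taxon_ids: Sequence[str]) -> pd.DataFrame:
    """Deterministic nested lineage over the taxon list."""
    recs = []
    for a, t in enumerate(taxon_ids):
        genus = a // 3
        family = genus // 2
        order = family // 2
        clazz = order // 2
        phylum = clazz // 2
        recs.append({"taxon_id": t, "Phylum": f"P{phylum}",
                     "Class": f"C{clazz}", "Order": f"O{order}",
                     "Family": f"F{family}", "Genus": f"G{genus}"})
    return pd.DataFrame(recs).set_index("taxon_id")


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw a full paired cohort with both potential outcome arms.

    Observed counts are assembled as W*Y(1) + (1-W)*Y(0).  Under a null
    effect spec the two arms share the same latent draw and the same
    multinomial draw, so the sharp null holds exactly unit by unit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_units_exposed + config.n_units_control
    A = config.n_taxa

    cov = pd.DataFrame({k: _draw_covariate(rng, fam, par, n)
                        for k, (fam, par) in config.covariate_spec.items()})
    kinds = {k: ("categorical" if fam == "bernoulli" else "continuous")
             for k, (fam, par) in config.covariate_spec.items()}

    z = np.zeros(n)
    for k, coef in config.confounding_coefficients.items():
        if k in cov.columns:
            z += coef * cov[k].to_numpy()
    # fixed-margin confounded assignment: Gumbel-top-k is an exponential-
    # weight draw without replacement proportional to exp(z)
    scores = z + rng.gumbel(size=n)
    w_obs = np.zeros(n, dtype=int)
    w_obs[np.argsort(-scores, kind="stable")[:config.n_units_exposed]] = 1
    lo, hi = z.min() - 30, z.max() + 30
    c = brentq(lambda t: expit(z - t).sum() - config.n_units_exposed, lo, hi)
    probs = expit(z - c)

    mu = rng.normal(1.0, 1.5, A)
    # heterogeneous per-taxon latent scales: some taxa are tight (candidate
    # normalization references), most are variable; partial correlations are
    # invariant to this diagonal scaling so the network truth is unchanged
    scale = rng.uniform(*config.latent_scale_range, A)
    omega0 = _base_precision(A, config.network_spec, rng)
    omega1 = _effect_precision(omega0, config.effect_spec.removed_edges) \
        if config.effect_spec.removed_edges else omega0
    chol0 = np.linalg.cholesky(np.linalg.inv(omega0)) * scale[:, None]
    chol1 = chol0 if omega1 is omega0 \
        else np.linalg.cholesky(np.linalg.inv(omega1)) * scale[:, None]
    omega0 = omega0 / np.outer(scale, scale)
    omega1 = omega1 / np.outer(scale, scale)

    tau = np.exp(config.effect_spec.diversity_shift)
    shift = np.zeros(A)
    for a, lf in config.effect_spec.taxon_log_folds.items():
        shift[a] += lf
    mu1 = tau * mu + shift

    u = rng.standard_normal((n, A))
    eta0 = mu + u @ chol0.T
    eta1 = mu1 + u @ chol1.T
    z0 = softmax(eta0, axis=1)
    z1 = softmax(eta1, axis=1)

    ds = config.depth_spec
    p_nb = ds.dispersion / (ds.dispersion + ds.mean)
    depth = np.maximum(rng.negative_binomial(ds.dispersion, p_nb, n), 50)

    y0 = np.empty((n, A), dtype=np.int64)
    for i in range(n):
        y0[i] = rng.multinomial(depth[i], z0[i])
    if config.effect_spec.is_null:
        y1 = y0
    else:
        y1 = np.empty((n, A), dtype=np.int64)
        for i in range(n):
            y1[i] = rng.multinomial(depth[i], z1[i])

    observed = np.where(w_obs[:, None] == 1, y1, y0)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    taxon_ids = [f"T{a:03d}" for a in range(A)]
    counts = CountMatrix(observed, sample_ids, taxon_ids,
                         taxonomy=_default_taxonomy(taxon_ids))
    cohort = CohortTable(sample_ids, cov, kinds, w_obs)
    truth = SimulationTruth(
        potential_relative_abundances={0: z0, 1: z1},
        potential_counts={0: y0, 1: y1},
        true_exposure_model=probs,
        true_differential_taxa=set(config.effect_spec.taxon_log_folds),
        true_differential_edges={tuple(sorted(e))
                                 for e in config.effect_spec.removed_edges},
        true_network_precision={0: omega0, 1: omega1},
    )
    tree = _random_tree(taxon_ids, rng)
    return SimulatedCohort(cohort=cohort, counts=counts, truth=truth,
                           tree_newick=tree, config=config)


def emit_cohort(sim: SimulatedCohort, outdir: str | Path,
                overwrite: bool = False) -> dict[str, Path]:
    """Write counts/metadata/taxonomy TSVs, the Newick tree and a truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("counts", "counts.tsv"), ("metadata", "metadata.tsv"),
        ("taxonomy", "taxonomy.tsv"), ("tree", "tree.nwk"),
        ("truth", "truth.json")]}
    clashes = [str(p) for p in paths.values() if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(f"refusing to overwrite: {clashes}")

    sim.counts.write_tsv(paths["counts"])
    meta = sim.cohort.covariates.copy()
    meta.insert(0, "sample_id", sim.cohort.ids)
    meta["exposure"] = sim.cohort.exposure
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    sim.counts.taxonomy.to_csv(paths["taxonomy"], sep="\t")
    write_newick(sim.tree_newick, paths["tree"])

    taxon_ids = sim.counts.taxon_ids
    truth = {
        "differential_taxa": sorted(taxon_ids[a]
                                    for a in sim.truth.true_differential_taxa),
        "differential_edges": sorted([taxon_ids[i], taxon_ids[j]]
                                     for i, j in
                                     sim.truth.true_differential_edges),
        "exposure_probabilities": dict(zip(sim.cohort.ids,
                                           sim.truth.true_exposure_model)),
        "diversity_shift": sim.config.effect_spec.diversity_shift,
        "taxon_log_folds": {taxon_ids[a]: lf for a, lf in
                            sim.config.effect_spec.taxon_log_folds.items()},
        "seed": sim.config.seed,
    }
    write_json(truth, paths["truth"])
    return paths
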