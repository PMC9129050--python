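"""Design stage: constrained bipartite pair matching and balance checks.

Exposed units are paired to controls only when every covariate-wise
difference falls inside its threshold (strict inequality for continuous
covariates, exact equality for categorical ones).  The largest set of
admissible pairs is extracted with maximum bipartite matching; a greedy
caliper-based propensity-score matcher is provided for sensitivity
analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "MatchingThresholds",
    "MatchedDesign",
    "MatchingError",
    "pair_admissible",
    "build_match_graph",
    "maximum_matching",
    "balance_diagnostics",
    "propensity_match",
]


class MatchingError(RuntimeError):
    """Raised when a design cannot be constructed from the inputs."""


@dataclass
class CohortTable:
    """Unit-level covariates and binary exposure.

    Parameters
    ----------
    ids : sequence of str
        Unit identifiers.
    covariates : DataFrame
        One row per unit, aligned with ``ids``.
    kinds : mapping
        Covariate name -> ``"continuous"`` or ``"categorical"``.
    exposure : ndarray of 0/1
    """

    ids: list[str]
    covariates: pd.DataFrame
    kinds: dict[str, str]
    exposure: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.exposure = np.asarray(self.exposure)
        if len(self.ids) != len(self.covariates) or \
                len(self.ids) != self.exposure.size:
            raise ValueError("ids, covariates and exposure must align")
        if np.isnan(self.exposure.astype(float)).any():
            raise ValueError("missing exposure values are not allowed")
        if not np.isin(self.exposure, (0, 1)).all():
            raise ValueError("exposure must be binary 0/1")
        for k in self.covariates.columns:
            if k not in self.kinds:
                raise ValueError(f"covariate kind not declared for {k!r}")
        self.covariates = self.covariates.set_axis(self.ids, axis=0)

    @classmethod
    def from_metadata(cls, meta: pd.DataFrame, exposure_col: str = "exposure",
                      kinds: Mapping[str, str] | None = None) -> "CohortTable":
        """Build from a metadata table indexed by sample id.

        Covariate kinds default to ``categorical`` for non-numeric columns
        and for numeric columns with at most two distinct values.
        """
        if exposure_col not in meta.columns:
            raise ValueError(f"metadata lacks exposure column {exposure_col!r}")
        cov = meta.drop(columns=[exposure_col])
        if kinds is None:
            kinds = {}
            for k in cov.columns:
                if not pd.api.types.is_numeric_dtype(cov[k]) or \
                        cov[k].nunique(dropna=True) <= 2:
                    kinds[k] = "categorical"
                else:
                    kinds[k] = "continuous"
        return cls(list(meta.index.astype(str)), cov.reset_index(drop=True),
                   dict(kinds), meta[exposure_col].to_numpy())

    @property
    def exposed_ids(self) -> list[str]:
        return [i for i, w in zip(self.ids, self.exposure) if w == 1]

    @property
    def control_ids(self) -> list[str]:
        return [i for i, w in zip(self.ids, self.exposure) if w == 0]


@dataclass
class MatchingThresholds:
    """Per-covariate matching tolerances delta_k.

    Continuous: maximum absolute difference, strict.  Categorical: must be
    0, meaning exact equality is required.
    """

    deltas: dict[str, float]

    def __post_init__(self) -> None:
        for k, d in self.deltas.items():
            if d < 0:
                raise ValueError(f"threshold for {k!r} must be >= 0")

    def validate_against(self, cohort: CohortTable) -> None:
        missing = [k for k in self.deltas if k not in cohort.covariates.columns]
        if missing:
            raise ValueError(f"thresholds refer to unknown covariates: {missing}")


@dataclass
class MatchedDesign:
    """An ordered list of (exposed, control) unit pairs."""

    pairs: list[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e, c in self.pairs:
            if e in seen or c in seen:
                raise ValueError("a unit appears in more than one pair")
            seen.add(e)
            seen.add(c)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_exposed(self) -> int:
        return len(self.pairs)

    @property
    def n_control(self) -> int:
        return len(self.pairs)

    @property
    def exposed_ids(self) -> list[str]:
        return [e for e, _ in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [c for _, c in self.pairs]

    def sample_order(self) -> list[str]:
        """Canonical analysis order: exposed block, then control block."""
        return self.exposed_ids + self.control_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair_id": [f"pair_{k}" for k in range(self.n_pairs)],
            "exposed_id": self.exposed_ids,
            "control_id": self.control_ids,
        })


def pair_admissible(x_i: Mapping[str, object], x_j: Mapping[str, object],
                    thresholds: MatchingThresholds,
                    kinds: Mapping[str, str]) -> float:
    """Constrained covariate distance: 0 if admissible, +inf otherwise.

    A pair is admissible iff |x_i(k) - x_j(k)| < delta_k for every
    continuous covariate k and x_i(k) == x_j(k) for every categorical one.
    Missing values make the pair inadmissible (conservative).
    """
    for k, delta in thresholds.deltas.items():
        a, b = x_i[k], x_j[k]
        if pd.isna(a) or pd.isna(b):
            logger.warning("missing covariate %r; pair treated as inadmissible", k)
            return math.inf
        if kinds.get(k) == "categorical" or delta == 0:
            if a != b:
                return math.inf
        else:
            if abs(float(a) - float(b)) >= delta:
                return math.inf
    return 0.0


def build_match_graph(cohort: CohortTable,
                      thresholds: MatchingThresholds) -> list[tuple[str, str]]:
    """Bipartite edges (exposed id, control id) with zero constrained distance."""
    thresholds.validate_against(cohort)
    e_idx = np.where(cohort.exposure == 1)[0]
    c_idx = np.where(cohort.exposure == 0)[0]
    if e_idx.size == 0 or c_idx.size == 0:
        raise MatchingError("need at least one exposed and one control unit")
    ok = np.ones((e_idx.size, c_idx.size), dtype=bool)
    for k, delta in thresholds.deltas.items():
        col = cohort.covariates[k]
        if cohort.kinds.get(k) == "categorical" or delta == 0:
            xe = col.to_numpy()[e_idx]
            xc = col.to_numpy()[c_idx]
            good = (xe[:, None] == xc[None, :])
            miss = pd.isna(xe)[:, None] | pd.isna(xc)[None, :]
        else:
            xe = col.to_numpy(dtype=float)[e_idx]
            xc = col.to_numpy(dtype=float)[c_idx]
            good = np.abs(xe[:, None] - xc[None, :]) < delta
            miss = np.isnan(xe)[:, None] | np.isnan(xc)[None, :]
        if miss.any():
            logger.warning("missing values in covariate %r; edges dropped", k)
        ok &= good & ~miss
    ids = np.asarray(cohort.ids)
    return [(ids[e_idx[i]], ids[c_idx[j]]) for i, j in zip(*np.nonzero(ok))]


def maximum_matching(edges: Sequence[tuple[str, str]],
                     provenance: dict | None = None) -> MatchedDesign:
    """Maximum-cardinality matching on a bipartite edge list.

    Deterministic for a fixed edge-list ordering (node indices are
    assigned in first-appearance order, and the underlying Hopcroft-Karp
    augmenting search is deterministic on the resulting CSR structure).
    """
    if not edges:
        return MatchedDesign(pairs=[], provenance=dict(provenance or {}))
    exposed: dict[str, int] = {}
    control: dict[str, int] = {}
    for e, c in edges:
        exposed.setdefault(e, len(exposed))
        control.setdefault(c, len(control))
    rows = [exposed[e] for e, _ in edges]
    cols = [control[c] for _, c in edges]
    bi = csr_matrix((np.ones(len(edges), dtype=np.int8), (rows, cols)),
                    shape=(len(exposed), len(control)))
    match = maximum_bipartite_matching(bi, perm_type="column")
    e_names = list(exposed)
    c_names = list(control)
    pairs = [(e_names[i], c_names[match[i]])
             for i in range(len(e_names)) if match[i] >= 0]
    return MatchedDesign(pairs=pairs, provenance=dict(provenance or {}))


def threshold_match(cohort: CohortTable,
                    thresholds: MatchingThresholds) -> MatchedDesign:
    """Convenience: build the constrained graph and take a maximum matching."""
    edges = build_match_graph(cohort, thresholds)
    return maximum_matching(
        edges, provenance={"method": "threshold", "deltas": dict(thresholds.deltas)})


def balance_diagnostics(cohort: CohortTable,
                        design: MatchedDesign | None = None) -> pd.DataFrame:
    """Standardized mean differences (continuous) and proportion
    differences (categorical) between arms.

    With a ``design``, only matched units are compared.  SMD uses the
    pooled standard deviation sqrt((var_E + var_C)/2); a zero pooled SD
    yields SMD 0 when the means agree and a ``degenerate`` flag otherwise.
    Rows with |SMD| > 0.1 are flagged.
    """
    if design is not None:
        if design.n_pairs == 0:
            raise MatchingError("cannot diagnose balance of an empty design")
        cov = cohort.covariates
        e_rows = cov.loc[design.exposed_ids]
        c_rows = cov.loc[design.control_ids]
    else:
        cov = cohort.covariates
        e_rows = cov.loc[np.asarray(cohort.ids)[cohort.exposure == 1]]
        c_rows = cov.loc[np.asarray(cohort.ids)[cohort.exposure == 0]]

    records = []
    for k in cov.columns:
        kind = cohort.kinds.get(k, "continuous")
        if kind == "continuous":
            me, mc = e_rows[k].mean(), c_rows[k].mean()
            pooled = math.sqrt((e_rows[k].var(ddof=1) + c_rows[k].var(ddof=1)) / 2)
            degenerate = False
            if pooled == 0 or math.isnan(pooled):
                smd = 0.0 if np.isclose(me, mc) else math.inf
                degenerate = not np.isclose(me, mc)
            else:
                smd = (me - mc) / pooled
            records.append({"covariate": k, "kind": kind,
                            "mean_exposed": me, "mean_control": mc,
                            "smd": smd, "degenerate": degenerate,
                            "flagged": abs(smd) > 0.1})
        else:
            levels = pd.unique(pd.concat([e_rows[k], c_rows[k]]).dropna())
            diffs = []
            for lv in levels:
                pe = (e_rows[k] == lv).mean()
                pc = (c_rows[k] == lv).mean()
                diffs.append(pe - pc)
            worst = diffs[int(np.argmax(np.abs(diffs)))] if diffs else 0.0
            records.append({"covariate": k, "kind": kind,
                            "mean_exposed": e_rows[k].mean()
                            if pd.api.types.is_numeric_dtype(e_rows[k]) else np.nan,
                            "mean_control": c_rows[k].mean()
                            if pd.api.types.is_numeric_dtype(c_rows[k]) else np.nan,
                            "smd": worst, "degenerate": False,
                            "flagged": abs(worst) > 0.1})
    return pd.DataFrame.from_records(records)


def _design_matrix(cohort: CohortTable) -> np.ndarray:
    """Numeric covariate matrix for the propensity model (one-hot categoricals)."""
    cols = []
    for k in cohort.covariates.columns:
        col = cohort.covariates[k]
        if cohort.kinds.get(k) == "categorical" and \
                not pd.api.types.is_numeric_dtype(col):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            cols.append(dummies.to_numpy())
        else:
            cols.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(cols)


def propensity_match(cohort: CohortTable, caliper: float = 0.2,
                     seed: int = 0) -> MatchedDesign:
    """Greedy 1:1 nearest-neighbour matching on the propensity linear predictor.

    A logistic model of exposure on the declared covariates supplies the
    linear predictor; exposed units are processed in random order (fixed
    by ``seed``) and matched without replacement to the nearest control
    within ``caliper`` standard deviations of the score.
    """
    import statsmodels.api as sm

    X = _design_matrix(cohort)
    n_e = int(cohort.exposure.sum())
    n_c = int((1 - cohort.exposure).sum())
    k = X.shape[1]
    if n_e < k + 2 or n_c < k + 2:
        raise MatchingError(f"need at least {k + 2} units per arm for a "
                            f"{k}-covariate propensity model")
    Xc = sm.add_constant((X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0,
                                                         X.std(axis=0), 1.0))
    try:
        fit = sm.Logit(cohort.exposure, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params, dtype=float)
    except Exception as exc:                        # noqa: BLE001
        raise MatchingError(
            "propensity model failed (possible separation); consider "
            "threshold matching instead") from exc
    if not np.isfinite(params).all() or np.abs(params[1:]).max() > 50:
        raise MatchingError(
            "propensity model shows signs of separation; consider "
            "threshold matching instead")
    lp = Xc @ params
    sd = lp.std(ddof=1)
    tol = caliper * sd

    rng = np.random.default_rng(seed)
    e_idx = np.where(cohort.exposure == 1)[0]
    c_idx = np.where(cohort.exposure == 0)[0]
    order = rng.permutation(e_idx.size)
    available = np.ones(c_idx.size, dtype=bool)
    ids = np.asarray(cohort.ids)
    pairs = []
    for o in order:
        i = e_idx[o]
        d = np.abs(lp[c_idx] - lp[i])
        d[~available] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol and np.isfinite(d[j]):
            available[j] = False
            pairs.append((ids[i], ids[c_idx[j]]))
    # restore a deterministic pair order (by exposed id) for reporting
    pairs.sort(key=lambda p: p[0])
    return MatchedDesign(pairs=pairs,
                         provenance={"method": "propensity",
                                     "caliper": caliper, "seed": seed})
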