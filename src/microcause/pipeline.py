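"""End-to-end orchestration: design -> shared assignments -> test battery.

One assignment matrix is generated per run and shared by every stage
that needs joint multiplicity adjustment, so all adjusted p-values
within a family refer to the same joint null.  Reports are deterministic
for a fixed config and seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, composition, diversity, networks
from .io import (CountMatrix, read_counts_tsv, read_metadata_tsv,
                 read_newick, read_taxonomy_tsv, write_json)
from .matching import (CohortTable, MatchedDesign, MatchingThresholds,
                       balance_diagnostics, propensity_match, threshold_match)
from .randomization import AssignmentMatrix, generate_assignments

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline", "import_assignment_matrix"]

ALL_STAGES = ("diversity", "beta", "composition", "abundance", "network")


@dataclass
class AnalysisConfig:
    """Serializable description of a complete analysis run."""

    counts: str
    metadata: str
    taxonomy: str | None = None
    tree: str | None = None
    thresholds: dict[str, float] | None = None
    use_propensity: bool = False
    caliper: float = 0.2
    n_iter: int = 1000
    seed: int = 0
    pseudocount: float = 1.0
    min_prevalence: float = 0.05
    beta_metrics: tuple[str, ...] = ("aitchison", "jaccard", "gower_clr")
    composition_ranks: tuple[str, ...] = ("Genus", "Family", "Phylum")
    da_rank: str | None = "Genus"
    da_dispersion: float = 2.0
    da_prevalence: float = 0.9
    network_rank: str | None = "Genus"
    network_n_iter: int | None = None
    lam_mode: str = "fixed"
    stars_subsamples: int = 20
    stages: tuple[str, ...] = ALL_STAGES
    assignment_matrix: str | None = None
    outdir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for k in ("beta_metrics", "composition_ranks", "stages"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def import_assignment_matrix(path: str | Path) -> AssignmentMatrix:
    """Load and validate a pairs x iterations 0/1 assignment TSV."""
    return AssignmentMatrix.from_tsv(path)


def _result_dicts(results) -> list[dict]:
    if isinstance(results, dict):
        return [r.to_dict() for r in results.values()]
    return [results.to_dict()]


def run_pipeline(config: AnalysisConfig,
                 cm: CountMatrix | None = None,
                 cohort: CohortTable | None = None,
                 tree: str | None = None) -> dict:
    """Execute the configured stages and return the study report.

    Inputs may be passed in memory (``cm``, ``cohort``, ``tree``) or read
    from the paths in ``config``.  Stage failures are recorded in the
    report and do not abort the remaining stages; a design failure does.
    """
    report: dict = {"config": config.to_dict(), "stages": {}, "errors": {}}

    if cm is None:
        taxonomy = read_taxonomy_tsv(config.taxonomy) if config.taxonomy else None
        cm = read_counts_tsv(config.counts, taxonomy=taxonomy)
    if cohort is None:
        cohort = CohortTable.from_metadata(read_metadata_tsv(config.metadata))
    if tree is None and config.tree:
        tree = read_newick(config.tree)

    if config.min_prevalence > 0:
        cm = composition.prevalence_filter(cm, config.min_prevalence)
    report["n_taxa_analyzed"] = cm.n_taxa

    # ---- design stage -------------------------------------------------
    t0 = time.perf_counter()
    balance_before = balance_diagnostics(cohort)
    if config.use_propensity:
        design = propensity_match(cohort, caliper=config.caliper,
                                  seed=config.seed)
    else:
        if not config.thresholds:
            raise ValueError("thresholds required unless use_propensity is set")
        design = threshold_match(cohort, MatchingThresholds(dict(config.thresholds)))
    if design.n_pairs == 0:
        raise RuntimeError("matching produced no pairs")
    balance_after = balance_diagnostics(cohort, design)
    logger.info("design stage: %d pairs in %.2fs", design.n_pairs,
                time.perf_counter() - t0)
    report["design"] = {
        "n_pairs": design.n_pairs,
        "n_exposed_before": int(cohort.exposure.sum()),
        "n_control_before": int((1 - cohort.exposure).sum()),
        "provenance": design.provenance,
        "balance_before": balance_before.to_dict(orient="records"),
        "balance_after": balance_after.to_dict(orient="records"),
    }

    if config.assignment_matrix:
        assignments = import_assignment_matrix(config.assignment_matrix)
        if assignments.n_pairs != design.n_pairs:
            raise ValueError("imported assignment matrix does not match the "
                             "design's number of pairs")
    else:
        assignments = generate_assignments(design, config.n_iter, config.seed)
    report["assignments"] = {"n_iter": assignments.n_iter,
                             "exhaustive": assignments.exhaustive,
                             "seed": config.seed}

    def _stage(name, fn):
        if name not in config.stages:
            return
        t = time.perf_counter()
        try:
            report["stages"][name] = fn()
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t)
        except Exception as exc:                  # noqa: BLE001
            logger.exception("stage %s failed", name)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    def _diversity():
        out = []
        for which in ("richness", "shannon"):
            res = diversity.diversity_randomization_test(
                cm, design, assignments, which=which, seed=config.seed)
            out.append(res.to_dict())
        return out

    def _beta():
        res = diversity.beta_diversity_test(
            cm, design, assignments, metrics=config.beta_metrics,
            tree=tree, pseudocount=config.pseudocount)
        return _result_dicts(res)

    def _composition():
        res = abundance.compositional_mean_test(
            cm, design, assignments, ranks=config.composition_ranks,
            pseudocount=config.pseudocount)
        return _result_dicts(res)

    def _abundance():
        data = composition.aggregate_rank(cm, config.da_rank) \
            if config.da_rank else cm
        table = abundance.differential_abundance_test(
            data, design, assignments,
            dispersion_threshold=config.da_dispersion,
            prevalence_threshold=config.da_prevalence,
            pseudocount=config.pseudocount)
        return table.to_dict(orient="records")

    def _network():
        data = composition.aggregate_rank(cm, config.network_rank) \
            if config.network_rank else cm
        n_it = config.network_n_iter or min(assignments.n_iter, 200)
        net_assign = assignments if n_it >= assignments.n_iter else \
            AssignmentMatrix(assignments.flips[:, :n_it], assignments.seed,
                             exhaustive=False)
        table = networks.network_permutation_test(
            data, design, net_assign, lam_mode=config.lam_mode,
            n_subsamples=config.stars_subsamples,
            pseudocount=config.pseudocount, seed=config.seed)
        return table.to_dict(orient="records")

    _stage("diversity", _diversity)
    _stage("beta", _beta)
    _stage("composition", _composition)
    _stage("abundance", _abundance)
    _stage("network", _network)

    if config.outdir:
        _write_report(report, design, assignments, Path(config.outdir))
    return report


def _write_report(report: dict, design: MatchedDesign,
                  assignments: AssignmentMatrix, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_json(report, outdir / "report.json")
    design.to_frame().to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame(report["design"]["balance_after"]).to_csv(
        outdir / "balance.tsv", sep="\t", index=False)
    assignments.to_tsv(outdir / "assignments.tsv")
    for name in ("abundance", "network"):
        if name in report["stages"]:
            pd.DataFrame(report["stages"][name]).to_csv(
                outdir / f"{name}.tsv", sep="\t", index=False)
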