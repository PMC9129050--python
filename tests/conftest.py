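import numpy as np
import pandas as pd
import pytest

from microcause.cohort import CohortConfig, EffectSpec, simulate_cohort
from microcause.io import CountMatrix
from microcause.matching import MatchedDesign
from microcause.randomization import generate_assignments


@pytest.fixture(scope="session")
def null_sim():
    """A small sharp-null cohort shared across tests."""
    cfg = CohortConfig(n_units_exposed=20, n_units_control=20, n_taxa=30,
                       seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_design(null_sim):
    return MatchedDesign(pairs=list(zip(null_sim.cohort.exposed_ids,
                                        null_sim.cohort.control_ids)))


@pytest.fixture(scope="session")
def null_assignments(null_design):
    return generate_assignments(null_design, 256, seed=7)


@pytest.fixture()
def toy_counts():
    """6 ASVs in 3 genera over 4 samples, with taxonomy."""
    counts = np.array([
        [3, 5, 2, 0, 7, 1],
        [1, 0, 4, 4, 2, 2],
        [6, 2, 0, 1, 3, 5],
        [2, 2, 2, 2, 2, 2],
    ])
    taxa = [f"asv{j}" for j in range(6)]
    taxonomy = pd.DataFrame({
        "taxon_id": taxa,
        "Phylum": ["P1"] * 4 + ["P2"] * 2,
        "Class": ["C1"] * 4 + ["C2"] * 2,
        "Order": ["O1"] * 4 + ["O2"] * 2,
        "Family": ["F1", "F1", "F2", "F2", "F3", "F3"],
        "Genus": ["g1", "g1", "g2", "g2", "g3", "g3"],
    }).set_index("taxon_id")
    return CountMatrix(counts, [f"s{i}" for i in range(4)], taxa, taxonomy)
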