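import numpy as np
import pandas as pd
import pytest

from pathchemo import simulate
from pathchemo.data_io import ClinicalTable, OmicsMatrix
from pathchemo.signatures import RankedSignature, ResponseGroups


@pytest.fixture(scope="session")
def small_cohort():
    """Planted dual-level cohort at reduced size for unit tests."""
    cfg = simulate.SyntheticConfig(n_pathways=20, genes_per_pathway=10,
                                   n_planted=2)
    return simulate.generate(cfg, seed=11)


@pytest.fixture
def toy_signature():
    return RankedSignature(pd.Series({"A": 3.0, "B": 2.0, "C": 1.0}), "welch_t")


@pytest.fixture
def toy_groups():
    return ResponseGroups({"p1", "p2", "p3"}, {"f1", "f2", "f3"}, set(),
                          (365.0, 730.0))


@pytest.fixture
def toy_matrix():
    # one informative gene, one flat gene
    vals = pd.DataFrame(
        {
            "p1": [2.0, 1.0], "p2": [4.0, 1.0], "p3": [6.0, 1.0],
            "f1": [1.0, 1.0], "f2": [2.0, 1.0], "f3": [3.0, 1.0],
        },
        index=["HIT", "FLAT"],
    )
    return OmicsMatrix(vals, "expression")


@pytest.fixture
def toy_clinical():
    n = 6
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"p{i}" for i in (1, 2, 3)] + [f"f{i}" for i in (1, 2, 3)],
        "therapy": "carboplatin-paclitaxel",
        "time_to_event": [100.0, 200.0, 300.0, 900.0, 1000.0, 1100.0],
        "event": [1, 1, 1, 0, 0, 0],
        "age": [60.0] * n,
        "gender": ["male", "female"] * 3,
        "stage": ["II"] * n,
        "neoadjuvant": 0,
    }))
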