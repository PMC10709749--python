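import numpy as np
import pandas as pd
import pytest

from rtdysbiosis import (
    AbundanceTable,
    CohortDesign,
    CohortMetadata,
    default_planted_effect,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default planted cohort (16 patients, 300 taxa, seed 0)."""
    design = CohortDesign(seed=0)
    return simulate_cohort(design, default_planted_effect(design))


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples count table."""
    return AbundanceTable(
        pd.DataFrame(
            {"s1": [2, 2, 4], "s2": [1, 0, 3]},
            index=pd.Index(["A", "B", "C"], name="taxon_id"),
        ),
        unit="counts",
    )


@pytest.fixture
def tiny_metadata():
    rows = []
    for i, (pid, tox) in enumerate([("P01", 1), ("P02", 0)]):
        rows.append(
            {
                "sample_id": f"s{i + 1}",
                "patient_id": pid,
                "timepoint": "prRT",
                "days": 0,
                "toxicity": tox,
                "field": "local",
                "antihormone": 0,
                "age": 70,
            }
        )
    return CohortMetadata(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
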