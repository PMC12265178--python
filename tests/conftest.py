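import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from periscope.io_formats import CountMatrix, GeneSet, GeneSetCollection, SampleTable
from periscope.preprocess import TransformedMatrix
from periscope.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(30)]
    samples = [f"S{j}" for j in range(8)]
    return CountMatrix(genes, samples, rng.integers(0, 200, size=(30, 8)))


@pytest.fixture(scope="session")
def small_transformed(small_counts) -> TransformedMatrix:
    from periscope.preprocess import normalize_transform

    return normalize_transform(small_counts, "log_cpm")


@pytest.fixture(scope="session")
def marker_sets() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("SET_A", "first block", [f"G{i:03d}" for i in range(0, 6)]),
            GeneSet("SET_B", "second block", [f"G{i:03d}" for i in range(6, 12)]),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One medium synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture()
def sample_table() -> SampleTable:
    rows = []
    for p in range(4):
        for tp in ("Baseline", "EarlyTreatment"):
            rows.append(
                {
                    "sample_id": f"P{p}_{tp}",
                    "patient_id": f"P{p}",
                    "timepoint": tp,
                    "arm": "ChemoPembro",
                    "clinical_subtype": "TNBC" if p % 2 else "HRpos",
                    "response": "pCR" if p < 2 else "RD",
                }
            )
    return SampleTable(pd.DataFrame(rows))
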