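import numpy as np
import pandas as pd
import pytest

from txclust import CohortTable, VariableSpec


@pytest.fixture
def toy_cohort() -> CohortTable:
    """Five subjects, four mixed-type variables, complete."""
    schema = {
        "age": VariableSpec("age", "continuous"),
        "sex": VariableSpec("sex", "binary", levels=[0, 1]),
        "race": VariableSpec("race", "categorical", levels=["A", "B", "C"]),
        "stage": VariableSpec("stage", "ordinal", levels=["I", "II", "III"]),
    }
    data = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(5)],
            "age": [40.0, 60.0, 50.0, 45.0, 55.0],
            "sex": [0, 1, 0, 1, 1],
            "race": ["A", "B", "A", "C", "B"],
            "stage": ["I", "III", "II", "I", "II"],
        }
    )
    return CohortTable(data=data, schema=schema)


@pytest.fixture
def two_blob_distance():
    """12 subjects in two well-separated blobs; within ~0.05, between ~0.9."""
    rng = np.random.default_rng(0)
    n_half = 6
    D = np.zeros((12, 12))
    for i in range(12):
        for j in range(i + 1, 12):
            same = (i < n_half) == (j < n_half)
            base = 0.05 if same else 0.9
            D[i, j] = D[j, i] = base + rng.uniform(0, 0.02)
    return D, np.array([1] * n_half + [2] * n_half)
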