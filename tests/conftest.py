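import numpy as np
import pandas as pd
import pytest

from isoratio.synthetic import ArraySpec, CohortSpec, generate_cohort, generate_microarray_batch


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down cohort with planted effects, shared across read-only tests."""
    spec = CohortSpec(
        n_grade2=20, n_grade3=30, n_grade4=40,
        n_null_genes=60, n_low_malignant=10, n_high_malignant=10, n_survival_genes=2,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort (55/105/150 patients)."""
    return generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_array_batch():
    """A small recombinant-design batch with two planted fold changes."""
    spec = ArraySpec(
        n_genes=60,
        planted_log2fc={"G0001": {"GFAPdelta_plus": 1.0}, "G0002": {"GFAPalpha_plus": -1.0}},
        seed=5,
    )
    return generate_microarray_batch(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_clinical():
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(6)],
            "grade": ["II", "II", "III", "III", "IV", "IV"],
            "os_days": [100.0, 200.0, 150.0, 300.0, 80.0, 90.0],
            "os_event": [1, 0, 1, 1, 1, 0],
            "pfs_days": [50.0, 120.0, 90.0, 200.0, np.nan, np.nan],
            "pfs_event": [1, 0, 1, 0, np.nan, np.nan],
        }
    )
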