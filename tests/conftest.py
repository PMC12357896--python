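import numpy as np
import pandas as pd
import pytest

from twinsift.fixtures import CohortSpec, generate_cohort
from twinsift.preprocess import apply_exclusions, build_analytical


@pytest.fixture(scope="session")
def small_cohort():
    """Raw cohort of 400 subjects (deterministic)."""
    return generate_cohort(CohortSpec(n_subjects=400, seed=11))


@pytest.fixture(scope="session")
def analytical(small_cohort):
    """Exclusion-filtered analytical table for the 400-subject cohort."""
    clean, _ = apply_exclusions(small_cohort)
    return build_analytical(clean)


@pytest.fixture(scope="session")
def clean_bundle(small_cohort):
    clean, _ = apply_exclusions(small_cohort)
    return clean


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def mixed_table(rng):
    """Small mixed-type table for metric unit tests."""
    n = 80
    return pd.DataFrame({
        "x": rng.normal(0, 1, n),
        "y": rng.normal(5, 2, n),
        "cat": rng.choice(["a", "b", "c"], n, p=[0.5, 0.3, 0.2]),
        "flag": rng.integers(0, 2, n),
    })
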