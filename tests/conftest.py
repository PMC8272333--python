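import numpy as np
import pandas as pd
import pytest

from cehrisk.catalog import default_catalog
from cehrisk.io import COHORT_COLUMNS
from cehrisk.presets import discrimination_config, study_like_config
from cehrisk.simulate import simulate_cohort


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_cohort(records):
    """Build a cohort frame from compact tuples.

    Each record: (status, sex, mhc_h1, mhc_h2, d1, d2, d3) with d values as
    copy counts 0/1/2 (phased arbitrarily as h1-first).
    """
    rows = []
    for i, (status, sex, m1, m2, k1, k2, k3) in enumerate(records):
        row = {
            "sample_id": f"s{i:05d}",
            "status": status,
            "sex": sex,
            "mhc_h1": m1,
            "mhc_h2": m2,
        }
        for locus, k in zip(("d1", "d2", "d3"), (k1, k2, k3)):
            row[f"{locus}_h1"] = "risk" if k >= 1 else "0"
            row[f"{locus}_h2"] = "risk" if k >= 2 else "0"
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


@pytest.fixture(scope="session")
def study_cohort():
    """A moderately sized cohort from the calibrated study-like preset —
    large enough that the (AP,AP) baseline clears the 15-representation
    floor the model evaluation requires."""
    return simulate_cohort(study_like_config(seed=11, n_cases=7000, n_controls=12000))


@pytest.fixture(scope="session")
def multiplicative_cohort():
    """A clean multiplicative-composition cohort (no overrides)."""
    return simulate_cohort(
        discrimination_config("multiplicative", seed=12, n_cases=7000, n_controls=12000)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
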