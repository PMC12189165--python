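import numpy as np
import pandas as pd
import pytest

from petrodim import CohortTable, SimConfig, simulate_cohort


def make_cohort(rows):
    """Build a CohortTable from (id, collection, sex, age, angle, aub)."""
    return CohortTable.from_records([
        {"specimen_id": r[0], "collection": r[1], "sex": r[2],
         "age_years": r[3], "lateral_angle_deg": r[4], "aub_mm": r[5]}
        for r in rows
    ])


@pytest.fixture
def toy_cohort():
    return make_cohort([
        ("a", "Vienna", "F", 2.0, 44.0, 95.0),
        ("b", "Vienna", "M", 3.5, np.nan, 99.0),
        ("c", "Graz", "M", 10.0, 38.0, 110.0),
        ("d", "Graz", "F", 25.0, 36.0, 120.0),
        ("e", "NMDID", "F", 20.0, np.nan, 119.0),
    ])


@pytest.fixture
def default_cohort():
    """Four-collection synthetic cohort under default parameters."""
    return simulate_cohort(SimConfig.default(seed=11))


def random_table(rng, n, n_pred=2):
    """Random numeric frame for regression property checks."""
    cols = {f"x{j}": rng.normal(size=n) for j in range(n_pred)}
    cols["y"] = rng.normal(size=n)
    return pd.DataFrame(cols)
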