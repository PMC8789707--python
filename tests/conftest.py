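import numpy as np
import pandas as pd
import pytest

from fabnorms.cohort import Cohort
from fabnorms.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic normative cohort (n=475, seed 1)."""
    return generate_cohort(default_config(seed=1))


@pytest.fixture()
def tiny_cohort():
    """Four hand-built records spanning the stratification bins."""
    rows = [
        # id, sex, age, education, items...
        ("a", "F", 30, 5, 3, 3, 3, 3, 3, 3, 28),
        ("b", "M", 40, 8, 2, 3, 1, 2, 0, 3, 25),
        ("c", "F", 70, 13, 3, 2, 3, 3, 2, 3, 24),
        ("d", "M", 88, 22, 1, 2, 2, 2, 3, 2, 22),
    ]
    df = pd.DataFrame(rows, columns=["id", "sex", "age", "education",
                                     "fab1", "fab2", "fab3", "fab4", "fab5",
                                     "fab6", "moca_total"])
    for c in ("moca_ef", "moca_a", "moca_l", "moca_m", "moca_vs", "moca_o"):
        df[c] = pd.array([2, 3, 3, 2], dtype="Int64")
    df["moca_total"] = df["moca_total"].astype("Int64")
    return Cohort(df, provenance="hand-built")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
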