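import numpy as np
import pandas as pd
import pytest

from aortrend.io_survey import build_catch_table
from aortrend.synthetic_data import constant_scenario, generate_survey


@pytest.fixture
def toy_records():
    """Two-year, one-region toy table with hand-checkable totals.

    Species A: 100 individuals over both years; B: 50 in one year;
    C: 100 in one year.
    """
    rows = [
        ("R", 2000, "t1", "A", 60),
        ("R", 2000, "t2", "A", 0),
        ("R", 2000, "t1", "C", 100),
        ("R", 2001, "t1", "A", 40),
        ("R", 2001, "t2", "B", 50),
    ]
    return pd.DataFrame(rows, columns=["region", "year", "tow", "species", "count"])


@pytest.fixture
def toy_table(toy_records):
    return build_catch_table(toy_records)


@pytest.fixture(scope="session")
def small_survey():
    """Deterministic 10-species, 12-year stationary survey (40 tows/year)."""
    return generate_survey(constant_scenario(n_species=10, n_years=12, tows_per_year=40, seed=11))
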