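import numpy as np
import pandas as pd
import pytest

from varzea import SurveyTable, assign_seasons


def make_records(rows):
    """rows: (lake, year_month, unit, species, count, biomass_g) tuples."""
    return pd.DataFrame(
        rows, columns=["lake", "year_month", "unit", "species", "count", "biomass_g"]
    )


@pytest.fixture
def tiny_table():
    """Two lakes, two months, three species; hand-checkable totals."""
    records = make_records(
        [
            ("L1", "2003-10", 1, "spA", 3, 30.0),
            ("L1", "2003-10", 2, "spA", 1, 10.0),
            ("L1", "2003-10", 1, "spB", 1, 2.5),
            ("L3", "2004-02", 1, "spC", 5, 12.0),
            ("L3", "2004-02", 2, "spA", 2, 19.0),
        ]
    )
    return SurveyTable(records=records)


@pytest.fixture
def tiny_table_seasons(tiny_table):
    return assign_seasons(tiny_table)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
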