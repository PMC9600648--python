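import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from shesd import (
    DailyCountSeries,
    default_admissions_spec,
    default_readmissions_spec,
    generate,
)


def make_series(values, start="2000-01-01", **kwargs) -> DailyCountSeries:
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailyCountSeries(dates, values, label="test", **kwargs)


@pytest.fixture(scope="session")
def admissions_series():
    """One full-length calibrated admissions series (4748 days)."""
    return generate(default_admissions_spec(seed=1996))


@pytest.fixture(scope="session")
def readmissions_series():
    """One full-length calibrated readmissions series (zero-dominated)."""
    return generate(default_readmissions_spec(seed=1996))


@pytest.fixture(scope="session")
def short_admissions_spec():
    """Four-year admissions spec for tests where full length is not needed."""
    return replace(default_admissions_spec(), end_date=dt.date(2000, 6, 30))


@pytest.fixture(scope="session")
def short_admissions_series(short_admissions_spec):
    return generate(replace(short_admissions_spec, seed=5))
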