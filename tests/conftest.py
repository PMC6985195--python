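import numpy as np
import pandas as pd
import pytest

from emanet import SimConfig, build_basis, standardize_basis
from emanet.synthetic_data import _prompt_schedule


@pytest.fixture(scope="session")
def schedule100():
    """Timestamps of the default protocol: 20 days x 5 prompts, schedule A."""
    ts, t, clock = _prompt_schedule(SimConfig())
    return ts


@pytest.fixture(scope="session")
def basis100(schedule100):
    """Standardized 7-column temporal basis on the default 100-prompt schedule."""
    return standardize_basis(build_basis(schedule100))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def clock_timestamps(hours, day="2024-03-01"):
    """Timestamps at given fractional clock hours, advancing days as needed."""
    base = pd.Timestamp(day)
    out, last = [], None
    offset = 0
    for h in hours:
        stamp = base + pd.Timedelta(days=offset) + pd.Timedelta(hours=h)
        if last is not None and stamp <= last:
            offset += 1
            stamp = base + pd.Timedelta(days=offset) + pd.Timedelta(hours=h)
        out.append(stamp)
        last = stamp
    return pd.DatetimeIndex(out)
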