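from datetime import datetime

import numpy as np
import pytest

from herdstress.ibi import IBISeries


@pytest.fixture
def make_series():
    """Factory for small hand-built IBI series."""

    def _make(values, start=datetime(2013, 1, 7, 12, 0, 0), cow="cow01",
              farm="farm1", session="B-d2-day"):
        return IBISeries(cow=cow, farm=farm, session=session, start=start,
                         intervals=np.asarray(values, dtype=float))

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20130107)
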