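import numpy as np
import pytest

from rookery import ColonySeries


def make_series(counts, start=1981, colony_id="test", region="southern",
                seasons=None, **kw):
    counts = np.asarray(counts, dtype=float)
    if seasons is None:
        seasons = np.arange(start, start + counts.size)
    return ColonySeries(colony_id, region, np.asarray(seasons), counts, **kw)


@pytest.fixture
def simple_series():
    return make_series([100, 110, 120, 130, 140])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
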