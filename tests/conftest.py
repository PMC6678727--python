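import numpy as np
import pytest

from greymtd import TimeSeries, china_so2


@pytest.fixture(scope="session")
def china():
    """China SO2 emissions 2007-2015, million tons."""
    return china_so2()


@pytest.fixture(scope="session")
def example_window(china):
    """The four 2007-2010 observations of the worked example."""
    return china.window(4, end=2010)


@pytest.fixture
def make_series():
    """Build a TimeSeries from bare values with consecutive periods."""

    def _make(values, start=2000):
        values = np.asarray(values, dtype=float)
        return TimeSeries(start + np.arange(len(values)), values)

    return _make
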