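import numpy as np
import pytest
from hypothesis import settings

from pdt import ABSeries, load_fitnet_example

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fitnet():
    """The packaged worked-example series, made equidistant (38 markers, week 22 missing)."""
    return load_fitnet_example()


@pytest.fixture
def small_series():
    """Tiny clean AB series for structural tests."""
    return ABSeries(
        time=np.arange(1, 9),
        phase=np.array(["A"] * 4 + ["B"] * 4),
        y=np.array([1.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0, 9.0]),
    )


def make_series(y_a, y_b, start=0):
    ya = np.asarray(y_a, dtype=float)
    yb = np.asarray(y_b, dtype=float)
    n = len(ya) + len(yb)
    return ABSeries(
        time=np.arange(start, start + n),
        phase=np.array(["A"] * len(ya) + ["B"] * len(yb)),
        y=np.concatenate([ya, yb]),
    )
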