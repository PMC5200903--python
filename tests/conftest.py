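import numpy as np
import pytest

from tosmat import CellPixels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_cell():
    """100 distinct-intensity pixels, identical in both channels."""
    vals = np.arange(1.0, 101.0)
    return CellPixels(vals, vals.copy(), cell_id="ramp")


@pytest.fixture
def reversed_cell():
    """Channel 2 is the rank reversal of channel 1."""
    vals = np.arange(1.0, 101.0)
    return CellPixels(vals, vals[::-1].copy(), cell_id="reversed")


def brute_force_overlap(signal1, signal2, f1, f2):
    """Independent oracle: explicit sort + set intersection.

    Selection rule mirrors the declared convention (round half away from
    zero, never empty, never the whole cell; ties broken by ascending
    index) but is computed with plain Python data structures.
    """
    import math

    n = len(signal1)

    def top(values, f):
        k = max(1, min(n - 1, math.floor(f * n + 0.5)))
        order = sorted(range(n), key=lambda i: (-values[i], i))
        return set(order[:k]), k

    s1, k1 = top(list(signal1), f1)
    s2, k2 = top(list(signal2), f2)
    inter = len(s1 & s2)
    ao1 = inter / k1
    ao2 = inter / k2
    ratio = ao1 / (k2 / n)
    return {"ao1": ao1, "ao2": ao2, "ratio": ratio, "k1": k1, "k2": k2}
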