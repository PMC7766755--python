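import numpy as np
import pytest

from causalplane import FeedforwardLayer


@pytest.fixture
def single_edge():
    """Factory for 1-input/1-output layers."""

    def make(activation: str, w: float) -> FeedforwardLayer:
        return FeedforwardLayer(np.array([[w]]), activation)

    return make


@pytest.fixture
def two_to_one():
    """Factory for 2-input/1-output layers."""

    def make(activation: str, wa: float, wb: float) -> FeedforwardLayer:
        return FeedforwardLayer(np.array([[wa], [wb]]), activation)

    return make
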