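import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_class_data(totals, cases):
    """Expand per-genotype-class (totals, cases) into (y, g) vectors."""
    g = np.repeat([0.0, 1.0, 2.0], totals)
    y = np.concatenate(
        [
            np.r_[np.ones(int(c)), np.zeros(int(t) - int(c))]
            for t, c in zip(totals, cases)
        ]
    )
    return y, g


@pytest.fixture
def class_data():
    return make_class_data
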