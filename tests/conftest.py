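import numpy as np
import pytest

from tycausal.synthetic import SyntheticTruth, gen_var_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bivariate_panel():
    """Fixed 30-year bivariate panel with a genuine lag-1 X -> Y link."""
    truth = SyntheticTruth(
        variables=("X", "Y"),
        edges=(("X", "Y", 1, 0.6),),
        ar={"X": 0.5, "Y": 0.3},
        n=30,
        seed=2024,
    )
    return gen_var_panel(truth)


@pytest.fixture
def trivariate_panel():
    """Fixed trivariate panel (n=80) with X -> M -> Y chain, no direct path."""
    truth = SyntheticTruth(
        variables=("X", "M", "Y"),
        edges=(("X", "M", 1, 0.7), ("M", "Y", 1, 0.7)),
        ar={"X": 0.5, "M": 0.4, "Y": 0.4},
        n=80,
        seed=77,
    )
    return gen_var_panel(truth)
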