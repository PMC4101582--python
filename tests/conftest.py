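import numpy as np
import pytest

from dca import SpectraMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_panel(n_samples=8, n_channels=64, seed=0, labels=None):
    """Random positive panel with an increasing m/z axis."""
    r = np.random.default_rng(seed)
    X = r.normal(10.0, 2.0, (n_samples, n_channels))
    mz = np.linspace(1000.0, 5000.0, n_channels)
    ids = [f"s{i}" for i in range(n_samples)]
    return SpectraMatrix(X, mz, ids, labels)


@pytest.fixture
def small_panel():
    return make_panel()


@pytest.fixture
def labelled_panel():
    labels = np.array(["a"] * 4 + ["b"] * 4)
    return make_panel(labels=labels)
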