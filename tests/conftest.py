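import numpy as np
import pytest

from coulombfit.dataset import SplitSpec, add_united_atom
from coulombfit.schemes import TrainConfig, fit_scheme_b
from coulombfit.synthetic import generate_diatomic_table, h2plus_like


@pytest.fixture(scope="session")
def h2plus_spec():
    return h2plus_like()


@pytest.fixture(scope="session")
def h2plus_table(h2plus_spec):
    """The 401-point noise-free one-electron-cation-like curve."""
    return generate_diatomic_table(h2plus_spec)


@pytest.fixture(scope="session")
def h2plus_table_ua(h2plus_table):
    """Same table with the hydrogenic united-atom record prepended."""
    return add_united_atom(h2plus_table, "hydrogenic", n_electrons=1)


@pytest.fixture(scope="session")
def small_table(h2plus_spec):
    """A coarse 21-point diatomic table for fast fitting tests."""
    spec = h2plus_like()
    spec.n_points = 21
    return generate_diatomic_table(spec)


@pytest.fixture(scope="session")
def quick_scheme_b(small_table):
    """A cheaply trained scheme-B surface (quality irrelevant, structure not)."""
    split = SplitSpec(0.8, "random", seed=11)
    config = TrainConfig(target_mse=0.04, max_epochs=40, seed=11)
    return fit_scheme_b(small_table, (5,), split, config)
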