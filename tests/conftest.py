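import numpy as np
import pytest

from gipso.data import (
    GeneratorConfig,
    chronological_split,
    concat_windows,
    generate_synthetic_series,
    make_windows,
)
from gipso.search_space import HyperparameterSet


@pytest.fixture(scope="session")
def synthetic_splits():
    """Chronological train/val/test windows from two generated series."""
    cfg = GeneratorConfig(n_series=2, length=600)
    series = generate_synthetic_series(cfg, seed=7)
    ds = concat_windows([make_windows(s) for s in series])
    return chronological_split(ds)


@pytest.fixture
def tiny_hp():
    return HyperparameterSet(
        learning_rate=0.005, dropout=0.05, epochs=6, num_layers=1, neurons=(8,)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
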