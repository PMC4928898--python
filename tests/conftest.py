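import numpy as np
import pytest

import bisqc as b


@pytest.fixture(scope="session")
def benchmark():
    """Full study-condition dataset: 700 spectra (100/class), seed 1.

    Returns the spectra collection and the extracted 31-feature dataset.
    """
    coll = b.generate_dataset(b.GeneratorConfig(rng_seed=1))
    return coll, b.build_feature_dataset(coll)


@pytest.fixture(scope="session")
def mini():
    """Small dataset (20/class, seed 3) for fast pipeline-level tests."""
    cfg = b.GeneratorConfig(rng_seed=3,
                            class_counts={c: 20 for c in b.ErrorClass})
    coll = b.generate_dataset(cfg)
    return coll, b.build_feature_dataset(coll)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def cole_params():
    return b.ColeParameters(450.0, 250.0, 0.75, 1.0 / (2 * np.pi * 40e3))


@pytest.fixture()
def log_grid():
    return np.logspace(np.log10(2 * np.pi * 1e3), np.log10(2 * np.pi * 1e6), 50)
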