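import numpy as np
import pytest

from pepagg.synthetic import (ToyModelSpec, enumerate_partition_model,
                              sample_ensemble)


@pytest.fixture(scope="session")
def toy_spec():
    """Default 8-chain study conditions with a mid-ladder dissociation."""
    return ToyModelSpec(n_sweeps=2500, exchange_interval=5,
                        burn_in_sweeps=500, seed=3)


@pytest.fixture(scope="session")
def oracle(toy_spec):
    return enumerate_partition_model(toy_spec)


@pytest.fixture(scope="session")
def sampled_ensemble(toy_spec):
    """One replica-exchange ensemble (6000 frames, 500 per rung), shared by
    the reweighting/melting/pipeline tests."""
    return sample_ensemble(toy_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
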