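import numpy as np
import pytest

from polyorigin import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast configuration exercising every generator."""
    return simdata.SimulationConfig(
        seed=1,
        ancestral_length=5_000,
        divergence_per_branch=0.02,
        coverage=10.0,
        n_ortholog_groups=40,
        peptide_length=200,
    )


@pytest.fixture
def ortholog_sim(small_config):
    return simdata.simulate_ortholog_groups(
        small_config.with_(gap_fraction=0.0, gap_heavy_fraction=0.0)
    )
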