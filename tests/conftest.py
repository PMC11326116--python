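import numpy as np
import pytest

from idcsim import (BatchProtocol, E_CROSS, MediaConfig, ModelParams, S_CROSS,
                    initial_state, run_batch_protocol)
from idcsim.genotypes import PAIRING_PRESETS
from idcsim.synth import make_fixture_suite


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def lw15_media():
    return MediaConfig(f_L=0.15, f_W=0.15)


@pytest.fixture(scope="session")
def short_protocol():
    return BatchProtocol(n_days=2)


@pytest.fixture(scope="session")
def crossfeeder_trajectory(default_params, lw15_media):
    """6-day crossfeeder-pairing run on the screening integrator."""
    proto = BatchProtocol(n_days=6)
    return run_batch_protocol(
        initial_state(lw15_media), default_params, E_CROSS, S_CROSS,
        lw15_media, proto, method="rk4")


@pytest.fixture(scope="session")
def pseudo_experiment():
    """Single-pairing pseudo-experiment bundle used by fitting tests."""
    return make_fixture_suite(
        1, pairings={"Ecross-Scross": PAIRING_PRESETS["Ecross-Scross"]},
        lw_levels=(0.15,), include_monocultures=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
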