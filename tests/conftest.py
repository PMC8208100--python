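import numpy as np
import pytest

from spinephys import synthetic as syn
from spinephys.membrane import detect_spikes


def simulate_family(name: str, seed: int = 1, noise_sd: float = 0.5):
    spec = syn.preset(name, noise_sd=noise_sd)
    sweeps, truth = syn.simulate_current_clamp(spec, seed=seed)
    trains = [detect_spikes(sw) for sw in sweeps]
    return sweeps, trains, truth


@pytest.fixture(scope="session")
def tf_family():
    return simulate_family("TF")


@pytest.fixture(scope="session")
def gf_family():
    return simulate_family("GF")


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: draws never depend on which
    # other tests ran first
    return np.random.default_rng(20260928)
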