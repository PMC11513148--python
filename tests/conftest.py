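import numpy as np
import pytest

from qcprof import synthetic as syn


@pytest.fixture(scope="session")
def small_proteome():
    spec = syn.SyntheticProteomeSpec(n_proteins=30, seed=7)
    return syn.generate_proteome(spec)


@pytest.fixture(scope="session")
def dimple_frames():
    """Full-resolution dimple trajectory shared by map-recovery tests."""
    spec = syn.SyntheticBilayerSpec(seed=3)
    return spec, syn.generate_bilayer_trajectory(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
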