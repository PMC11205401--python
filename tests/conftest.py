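import numpy as np
import pytest

from membranekit import BilayerSpec, gen_bilayer_trajectory


@pytest.fixture(scope="session")
def small_traj():
    """Small but fully featured synthetic bilayer trajectory."""
    spec = BilayerSpec(
        n_lipids_per_leaflet=16,
        n_solutes=6,
        n_frames=120,
        target_scd=(0.14, 0.14, 0.14),
        seed=42,
    )
    return gen_bilayer_trajectory(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
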