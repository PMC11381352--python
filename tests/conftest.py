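import numpy as np
import pytest

from smtrack import synthetic as syn


@pytest.fixture(scope="session")
def unit_cell():
    """A single ideal 3.5 x 0.7 μm spherocylinder."""
    return syn.make_cells(1, (3.5, 0.0), (0.7, 0.0), seed=1)[0]


@pytest.fixture(scope="session")
def fixed_tracks_short():
    """Fixed-cell (all-static) tracks with the short-exposure noise pair."""
    cfg = syn.SimulationConfig(
        n_cells=12,
        n_molecules=10,
        n_frames=150,
        loc_noise_sigma=(0.0265, 0.0260),
        rng_seed=42,
    )
    _, tracks, _ = syn.simulate_fixed_cells(cfg)
    return tracks


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
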