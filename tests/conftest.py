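import numpy as np
import pytest

import fretcycle as fc
from fretcycle import presets


@pytest.fixture(scope="session")
def two_state_scheme():
    return presets.composite_scheme(2.0, 3.0, fret_if=0.3, fret_of=0.8)


@pytest.fixture(scope="session")
def clean_two_state_dataset(two_state_scheme):
    """Noise-controlled 2-state dataset with bleaching, for QC/HMM tests."""
    cfg = fc.SimulationConfig(
        scheme=two_state_scheme,
        n_traces=60,
        n_frames=400,
        frame_interval=0.1,
        photophysics=fc.PhotophysicsParams(
            total_intensity=1000.0, noise_sigma=60.0, background_sigma=40.0,
            k_bleach=0.05, k_blink_off=0.0,
        ),
        seed=101,
    )
    return fc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def five_state_dataset():
    """Five-state 25 ms dataset, molecules starting inward-facing."""
    cfg = fc.SimulationConfig(
        scheme=presets.five_state_scheme("atp_ltc4"),
        n_traces=150,
        n_frames=400,
        frame_interval=0.025,
        photophysics=presets.photophysics_preset("25ms"),
        initial_state=("IF4", "IF3", "IF2", "IF1"),
        seed=103,
    )
    return fc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def five_state_passing(five_state_dataset):
    passing, _ = fc.filter_traces(five_state_dataset)
    return passing
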