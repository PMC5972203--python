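import numpy as np
import pytest

from chemotrack.simulate import (
    BackgroundModel,
    NoiseModel,
    SimulationConfig,
    simulate_stack,
)


@pytest.fixture(scope="session")
def small_static_stack():
    """Noise-free stack of static emitters (fast shared fixture)."""
    config = SimulationConfig(
        frame_count=20,
        components=[(0.0, 1.0)],
        foci_per_frame=6,
        truncation_prob=0.0,
        seed=3,
    )
    return simulate_stack(config)


@pytest.fixture(scope="session")
def small_mobile_stack():
    """Noise-free stack of D=1.6 µm²/s emitters."""
    config = SimulationConfig(
        frame_count=120,
        components=[(1.6, 1.0)],
        foci_per_frame=5,
        seed=7,
    )
    return simulate_stack(config)


@pytest.fixture(scope="session")
def noisy_static_stack():
    """Static emitters with paper-like readout noise and background."""
    from chemotrack.pipeline import PAPER_BACKGROUND_LEVEL, PAPER_NOISE

    config = SimulationConfig(
        frame_count=150,
        components=[(0.0, 1.0)],
        foci_per_frame=6,
        truncation_prob=0.02,
        noise=PAPER_NOISE,
        background=BackgroundModel(mean_level=PAPER_BACKGROUND_LEVEL),
        seed=5,
    )
    return simulate_stack(config)
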