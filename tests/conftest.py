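import numpy as np
import pytest

from crowdactin.synthetic_data import (
    BrownianParams,
    GrowthParams,
    PyreneParams,
    simulate_filament_timelapse,
    simulate_monomer_trajectory,
    simulate_pyrene_timecourse,
)


@pytest.fixture
def static_trajectory():
    """Zero-diffusion, zero-drift trajectory: every frame equals frame 0."""
    return simulate_monomer_trajectory(
        BrownianParams(diffusion_coefficient=0.0, n_steps=20, seed=3)
    )


@pytest.fixture
def noiseless_stack():
    """Noiseless timelapse at the dilute-buffer control rate."""
    params = GrowthParams(elongation_rate=35.9, noise_sd=0.0, seed=0)
    track, stack = simulate_filament_timelapse(params)
    return params, track, stack


@pytest.fixture
def noiseless_logistic():
    """Noiseless pyrene curve with Δt·k = 0.05 (well-resolved sigmoid)."""
    params = PyreneParams(
        amplitude=1000.0, rate_constant=0.005, half_time=2400.0,
        noise_sd=0.0, seed=0,
    )
    return params, simulate_pyrene_timecourse(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
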