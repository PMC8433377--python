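import numpy as np
import pytest

from metapanel import presets
from metapanel.signal_processing import default_channel_map
from metapanel.synthetic_data import (
    SensorModel,
    control_kinetics,
    linear_kinetics,
    simulate_frame_stack,
)


@pytest.fixture(scope="session")
def cmap():
    return default_channel_map()


@pytest.fixture(scope="session")
def quiet_sensor():
    """No noise, no dead sensors, fine ADC: the idealized acquisition."""
    return SensorModel(noise_sd=0.0, dead_fraction=0.0, adc_bits=20)


@pytest.fixture(scope="session")
def glutamate_run(cmap):
    """One realistic 60-s standard-addition style acquisition (seeded)."""
    kin = linear_kinetics("glutamate")
    return simulate_frame_stack(
        {1: 0.0, 2: 50.0, 3: 150.0, 4: 250.0},
        cmap,
        {1: control_kinetics(), 2: kin, 3: kin, 4: kin},
        SensorModel(),
        seed=42,
        duration=60.0,
    )


@pytest.fixture(scope="session")
def laa_params():
    return presets.MM_PARAMS["LAA"]


def make_noise_stack(seed=0, n_frames=400, sd=1e-3, level=1.73, frame_rate=36.5):
    """Flat noisy 16×16 stack around a constant level (no drift)."""
    from metapanel.synthetic_data import FrameStack

    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) / frame_rate
    frames = level + rng.normal(0.0, sd, (n_frames, 16, 16))
    return FrameStack(times=times, frames=frames, metadata={"frame_rate": frame_rate})
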