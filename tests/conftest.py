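import numpy as np
import pytest

from vitalchirp.radar_sim import (
    RadarConfig,
    Reflector,
    Scene,
    Trajectory,
)


@pytest.fixture
def single_channel_config():
    """Noise-free single-channel radar for exact-arithmetic tests."""
    return RadarConfig(noise_sigma=0.0, channels=("TX1-RX1",))


@pytest.fixture
def oracle_config():
    """Single-scan trains: the LPF is transparent, so the closed-form
    descriptor holds to machine precision."""
    return RadarConfig(noise_sigma=0.0, channels=("TX1-RX1",), train_len=1)


def make_single_reflector_scene(amplitude=1.0, if_freq=0.1, phase0=0.0,
                                traj=None, label=0):
    traj = traj or Trajectory("static")
    label = 1 if traj.kind == "breathing" else label
    return Scene(
        (Reflector(amplitude, if_freq, traj, phase0=phase0),),
        label=label, name="fixture",
    )


@pytest.fixture
def static_scene():
    return make_single_reflector_scene()


def random_breathing_scene(rng, jitter=False):
    """One breathing reflector with parameters drawn from realistic ranges."""
    params = {
        "rate": float(rng.uniform(0.125, 0.5)),
        "amplitude": float(rng.uniform(0.002, 0.006)),
        "phase": float(rng.uniform(0, 2 * np.pi)),
    }
    if jitter:
        params.update(rate_jitter=0.15, amp_jitter=0.2,
                      jitter_seed=int(rng.integers(2**31)))
    return make_single_reflector_scene(
        amplitude=float(rng.uniform(0.5, 2.0)),
        if_freq=float(rng.uniform(0.05, 0.45)),
        phase0=float(rng.uniform(0, 2 * np.pi)),
        traj=Trajectory("breathing", params),
    )
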