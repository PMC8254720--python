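import numpy as np
import pandas as pd
import pytest

from ponzopupil.preprocess import PreprocessingParams, RawTrace
from ponzopupil.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params():
    return PreprocessingParams()


@pytest.fixture
def quiet_cfg():
    """Simulation config with all noise and artifact processes off."""
    return SimulationConfig(
        n_participants=2,
        seed=7,
        noise_sd_mm=0.0,
        amplitude_jitter_mm=0.0,
        baseline_trial_sd_mm=0.0,
        baseline_between_sd_mm=0.0,
        blink_rate_hz=0.0,
        loss_rate_hz=0.0,
        spike_rate_hz=0.0,
        gaze_jitter_deg=0.0,
        report_weber=0.0,
    )


def make_trace(pupil, t_ms=None, rate=500.0):
    """Build a RawTrace with constant gaze from a pupil vector."""
    pupil = np.asarray(pupil, dtype=float)
    if t_ms is None:
        t_ms = np.arange(len(pupil)) * 1000.0 / rate
    n = len(pupil)
    return RawTrace(t_ms=np.asarray(t_ms, dtype=float), pupil_mm=pupil,
                    gaze_x_px=np.full(n, 512.0), gaze_y_px=np.full(n, 384.0),
                    nominal_rate_hz=rate)


def random_artifact_trace(rng, n=2000, rate=500.0):
    """Random trace with planted blinks, spikes and drifts (for oracles)."""
    t = np.arange(n) * 1000.0 / rate
    pupil = 4.26 + 0.3 * np.sin(t / 900.0) + rng.normal(0, 0.003, n)
    # slow drift
    pupil += rng.normal(0, 0.2) * t / t[-1]
    # blinks: runs forced to ~0
    for _ in range(rng.integers(0, 3)):
        start = rng.integers(0, n - 60)
        length = rng.integers(20, 60)
        pupil[start:start + length] = rng.uniform(0.0, 0.09)
    # spikes
    for _ in range(rng.integers(0, 6)):
        pupil[rng.integers(0, n)] += rng.choice([-1, 1]) * rng.uniform(0.8, 2.5)
    # occasional dropped samples (irregular sampling)
    keep = rng.random(n) > 0.02
    return make_trace(pupil[keep], t_ms=t[keep], rate=rate)
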