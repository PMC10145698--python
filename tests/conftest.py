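import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

RATE = 500.0


@pytest.fixture(scope="session")
def clean_ecg_fixture():
    """60 s of noise-free constant-RR (800 ms) ECG at 500 Hz, off-grid beats.

    Returns (ecg, true_beat_times_ms, rate).
    """
    from teamhrv import RRModulationSpec, generate_rr_series, render_ecg

    rr, beats = generate_rr_series(RRModulationSpec(mean_rr_ms=800.0), 60.0)
    phase = 0.7  # deliberately off the 2 ms sample grid
    # default duration extends past the last beat so its peak is rendered
    ecg = render_ecg(beats, RATE, phase_offset_ms=phase)
    return ecg, beats + phase, RATE


@pytest.fixture(scope="session")
def noisy_ecg_fixture(clean_ecg_fixture):
    """The clean fixture plus baseline wander and white noise."""
    from teamhrv import NoiseSpec, add_noise

    ecg, beats, rate = clean_ecg_fixture
    spec = NoiseSpec(baseline_amp_mv=0.2, white_sd_mv=0.05)
    return add_noise(ecg, rate, spec, seed=11), beats, rate
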