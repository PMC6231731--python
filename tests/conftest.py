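import numpy as np
import pytest

from ppgkit.synthetic import (
    HRVParams,
    PulseShapeParams,
    RespModulationParams,
    synthesize_session,
)

FS = 86.0


@pytest.fixture(scope="session")
def clean_session():
    """Default 2-minute session: 70 bpm, moderate HRV, 15 brpm, no noise."""
    return synthesize_session(duration_s=120.0, seed=7)


@pytest.fixture(scope="session")
def noisy_session():
    """Same conditions at pulsatile SNR 10."""
    return synthesize_session(duration_s=120.0, seed=7, snr=10.0)


@pytest.fixture(scope="session")
def hr60_session():
    """63-s, 60 bpm session used by the beat-detection examples."""
    return synthesize_session(
        hrv=HRVParams(hr_mean_bpm=60.0, jitter_sd_ms=20.0, lf_amp_ms=10.0),
        resp=RespModulationParams(rr_brpm=15.0),
        pulse=PulseShapeParams(),
        duration_s=63.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def motion_session():
    """2-minute clean session with one 4-s motion transient at 60 s."""
    return synthesize_session(
        duration_s=120.0, seed=3, motion_events=((60.0, 4.0, 5.0),)
    )
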