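import numpy as np
import pytest

from tinnisynth import Audiogram, SynthesisConfig, TinnitusProfile


@pytest.fixture(scope="session")
def sloping_audiogram():
    """Normal hearing through 500 Hz, sloping sensorineural loss 1-8 kHz,
    50 dB HL at 4 kHz (the worked-example configuration)."""
    return Audiogram(
        "right",
        [
            (125, 5), (250, 5), (500, 10), (1000, 20), (2000, 35),
            (3000, 45), (4000, 50), (6000, 60), (8000, 65),
        ],
    )


@pytest.fixture(scope="session")
def matched_profile():
    """Tonal, chronic, RI-positive tinnitus at 4 kHz with TLL 60 / MML 55."""
    return TinnitusProfile(
        laterality="right", pitch=4000, tll=60, mml=55,
        ri="positive", duration_months=24, tonal=True,
    )


@pytest.fixture(scope="session")
def fast_config():
    """Short-duration synthesis config for spectral tests (>= several
    Welch segments at 8192 samples but far below the 60 s delivery length)."""
    return SynthesisConfig(seed=7, duration=6.0)
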