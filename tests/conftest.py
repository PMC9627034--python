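"""Shared fixtures: synthesized stimuli with known parameters.

Everything is generated at test time; module-scoped fixtures keep the more
expensive syntheses (vowel audio, cohorts) to one run per session.
"""

import numpy as np
import pytest

from silenttrack.types import AudioWave, FeaturePlan
from silenttrack.synth import synthesize_vowel_audio

VOWEL_FORMANTS = (500.0, 1500.0, 2500.0, 3500.0, 4500.0)
VOWEL_F0 = 120.0
VOWEL_DURATION_S = 2.0


@pytest.fixture(scope="session")
def vowel_audio() -> AudioWave:
    """Five-formant synthetic vowel at f0 = 120 Hz (2 s, 48 kHz)."""
    plans = [FeaturePlan.constant(f, VOWEL_DURATION_S) for f in VOWEL_FORMANTS]
    pitch = FeaturePlan.constant(VOWEL_F0, VOWEL_DURATION_S)
    return synthesize_vowel_audio(plans, pitch, VOWEL_DURATION_S, 48000.0)


@pytest.fixture(scope="session")
def harmonic_150hz() -> AudioWave:
    """Five-harmonic complex tone at f0 = 150 Hz (3 s, 48 kHz)."""
    fs = 48000.0
    t = np.arange(0, 3, 1 / fs)
    x = sum(np.sin(2 * np.pi * 150 * k * t) / k for k in range(1, 6))
    return AudioWave(x, rate_hz=fs)


@pytest.fixture(scope="session")
def am_tone() -> AudioWave:
    """1-kHz carrier amplitude-modulated at 4 Hz, depth 1 (5 s, 48 kHz)."""
    fs = 48000.0
    t = np.arange(0, 5, 1 / fs)
    mod = 0.5 * (1 + np.sin(2 * np.pi * 4 * t))
    return AudioWave(mod * np.sin(2 * np.pi * 1000 * t), rate_hz=fs)
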