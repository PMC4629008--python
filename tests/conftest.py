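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


@pytest.fixture
def tone_signal():
    """2 s pure 110 Hz tone at 44.1 kHz."""
    from prososcreen import AudioSignal

    fs = 44100
    t = np.arange(2 * fs) / fs
    return AudioSignal(0.5 * np.sin(2 * np.pi * 110.0 * t), fs)


@pytest.fixture
def small_utterance():
    """10-syllable synthetic utterance with 2 true pauses (seed fixed)."""
    from prososcreen import UtteranceSpec, synth_utterance

    spec = UtteranceSpec(n_syllables=10, pause_positions=(3, 7), seed=42)
    return synth_utterance(spec)
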