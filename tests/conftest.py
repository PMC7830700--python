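import numpy as np
import pytest

from semglove import Motion, SemgRecording, SequenceProtocol, SyntheticConfig


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    """Scaled-down generator config for fast unit tests."""
    return SyntheticConfig(trial_s=4.0, trials_per_motion=3)


@pytest.fixture
def re_protocol() -> SequenceProtocol:
    return SequenceProtocol((Motion.REST, Motion.EXTENSION))


def make_sinusoid(freq: float, duration_s: float = 8.0, fs: float = 250.0,
                  amplitude: float = 1.0) -> SemgRecording:
    """Recording with the same unit sinusoid on all four channels."""
    t = np.arange(round(duration_s * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return SemgRecording(np.tile(x[:, None], (1, 4)), sample_rate=fs)
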