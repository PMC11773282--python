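import numpy as np
import pytest

from pedscreen.stimuli import Waveform

FS = 44_100


@pytest.fixture
def sine():
    """Factory for steady sine waveforms."""

    def _make(freq: float, duration: float = 1.0, amplitude: float = 0.5,
              sample_rate: int = FS) -> Waveform:
        t = np.arange(int(duration * sample_rate)) / sample_rate
        return Waveform(amplitude * np.sin(2 * np.pi * freq * t), sample_rate)

    return _make


@pytest.fixture
def band_500_spec():
    from pedscreen.stimuli import StimulusSpec

    return StimulusSpec("drum", "noisemaker", 500, 250, 750, 24, 2.5)
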