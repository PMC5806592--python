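import numpy as np
import pytest

from speechabr import simulate, stimuli

FS_EEG = 10000.0


@pytest.fixture(scope="session")
def speech_audio():
    """8 s of seeded speech-like audio at the hardware rate."""
    return simulate.make_speechlike_audio(8.0, seed=7, include_pauses=False)


@pytest.fixture(scope="session")
def prepared_epochs():
    """Two 8-s stimulus epochs pushed through the standard stimulus chain."""
    audio = simulate.make_speechlike_audio(16.0, seed=11, include_pauses=False)
    audio = stimuli.normalize_rms(stimuli.highpass_speech(audio))
    return simulate.split_audio_epochs(audio, 2)


@pytest.fixture(scope="session")
def noiseless_truth():
    """Noise-free truth whose kernel support (<=100 ms) fits entirely inside
    the epoch's 100-ms post-stimulus tail, so the linear model is exact."""
    return simulate.SimulationTruth(
        waves=tuple(w for w in simulate.DEFAULT_WAVES if w[0] <= 30.0),
        kernel_duration_ms=100.0,
        noise_rms=0.0,
        line_amps=(),
        excursion_rate_per_min=0.0,
        seed=5,
    )
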