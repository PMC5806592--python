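"""Response quantification: Wave V, morphology correlation, SNR, split halves.

Wave V — the prominent positive ABR peak near 6 ms generated principally by
the lateral lemniscus — is picked as the maximum of the 1-kHz zero-phase
low-passed waveform within a 5-7 ms search window.  Morphology similarity
between two responses is Pearson's r over 0-20 ms.  Evoked SNR compares the
waveform variance in a post-stimulus signal window (0-20 ms) against a
pre-stimulus noise window (-125 to -10 ms):

    SNR = 10 log10[(sigma^2_ABR - sigma^2_noise) / sigma^2_noise]

which is undefined (NaN, never clamped) when the signal window carries no
more variance than the noise window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._filters import butter_filter
from .response import ResponseWaveform

SIGNAL_WINDOW_MS = (0.0, 20.0)
NOISE_WINDOW_MS = (-125.0, -10.0)


@dataclass
class WaveVMeasurement:
    latency_ms: float
    amplitude_uv: float
    search_window_ms: tuple[float, float] = (5.0, 7.0)
    smoothing_hz: float = 1000.0


@dataclass
class SnrMeasurement:
    snr_db: float
    signal_window_ms: tuple[float, float] = SIGNAL_WINDOW_MS
    noise_window_ms: tuple[float, float] = NOISE_WINDOW_MS
    n_epochs_used: int | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.snr_db)


def find_wave_v(
    resp: ResponseWaveform,
    window_ms: tuple[float, float] = (5.0, 7.0),
    smoothing_hz: float | None = 1000.0,
) -> WaveVMeasurement:
    """Latency and amplitude of the largest peak in the search window.

    The waveform is first smoothed with a zero-phase 1-kHz low-pass; the
    amplitude is the smoothed value at the peak (baseline-to-peak).  Ties
    resolve to the earliest lag.
    """
    amp = resp.amplitude
    if smoothing_hz is not None:
        amp = butter_filter(amp, resp.fs, smoothing_hz, "lowpass", 1, "zerophase")
    mask = resp.window_mask(window_ms)
    idx = np.flatnonzero(mask)
    peak = idx[np.argmax(amp[mask])]  # argmax returns the first maximum
    lat = float(resp.lags_ms[peak])
    return WaveVMeasurement(lat, float(amp[peak]), tuple(window_ms),
                            smoothing_hz if smoothing_hz is not None else 0.0)


def correlate_window(
    a: ResponseWaveform,
    b: ResponseWaveform,
    window_ms: tuple[float, float] = SIGNAL_WINDOW_MS,
) -> float:
    """Pearson product-moment correlation of two waveforms over a lag window."""
    if a.fs != b.fs or a.n_pre != b.n_pre or a.n_samples != b.n_samples:
        raise ValueError("responses must share an identical lag grid")
    xa = a.window_values(window_ms)
    xb = b.window_values(window_ms)
    return float(stats.pearsonr(xa, xb).statistic)


def snr(
    resp: ResponseWaveform,
    signal_window_ms: tuple[float, float] = SIGNAL_WINDOW_MS,
    noise_window_ms: tuple[float, float] = NOISE_WINDOW_MS,
    n_epochs_used: int | None = None,
) -> SnrMeasurement:
    """Evoked SNR in dB from signal- and noise-window variances."""
    var_sig = float(np.var(resp.window_values(signal_window_ms)))
    var_noise = float(np.var(resp.window_values(noise_window_ms)))
    if var_noise <= 0 or var_sig <= var_noise:
        value = np.nan
    else:
        value = 10.0 * np.log10((var_sig - var_noise) / var_noise)
    if n_epochs_used is None:
        n_epochs_used = resp.provenance.get("n_epochs")
    return SnrMeasurement(value, tuple(signal_window_ms), tuple(noise_window_ms), n_epochs_used)


def snr_curve(
    cumulative_responses: list[ResponseWaveform],
    signal_window_ms: tuple[float, float] = SIGNAL_WINDOW_MS,
    noise_window_ms: tuple[float, float] = NOISE_WINDOW_MS,
) -> list[SnrMeasurement]:
    """SNR of each cumulative response (one per growing epoch count)."""
    if len(cumulative_responses) < 2:
        raise ValueError("need cumulative responses for at least two epoch counts")
    return [snr(r, signal_window_ms, noise_window_ms) for r in cumulative_responses]


@dataclass
class SplitHalfSummary:
    correlations: np.ndarray
    median: float
    iqr: tuple[float, float]
    label: str = ""


def split_half(
    pairs: list[tuple[ResponseWaveform, ResponseWaveform]],
    window_ms: tuple[float, float] = SIGNAL_WINDOW_MS,
    label: str = "",
) -> SplitHalfSummary:
    """Correlate paired split responses (one pair per subject) over a window.

    The pairing defines the split — even/odd epochs, first/second session
    half, or narrator — and the summary reports the median and interquartile
    range of the per-subject correlations.
    """
    if not pairs:
        raise ValueError("no split pairs given")
    r = np.array([correlate_window(a, b, window_ms) for a, b in pairs])
    q1, q3 = np.percentile(r, [25, 75])
    return SplitHalfSummary(r, float(np.median(r)), (float(q1), float(q3)), label)


def even_odd_split(n_epochs: int) -> tuple[np.ndarray, np.ndarray]:
    """Epoch indices of the even/odd-trial split (0-based: trials 1,3,... are even rows)."""
    idx = np.arange(n_epochs)
    return idx[::2], idx[1::2]


def session_half_split(n_epochs: int) -> tuple[np.ndarray, np.ndarray]:
    """Epoch indices of the first/second session-half split."""
    idx = np.arange(n_epochs)
    half = n_epochs // 2
    return idx[:half], idx[half:]
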