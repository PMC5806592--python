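"""Electromagnetic stimulus-artifact ("leakage") estimation and subtraction.

Headphone drivers can couple electromagnetically into the EEG leads, placing a
filtered copy of the stimulus audio into the recording.  Because the acoustic
signal reaches the ear through a sound tube (~1 ms delay) while the
electromagnetic artifact is instantaneous, the artifact appears *before*
acoustic time zero, centred near -0.9 ms lag.

The artifact is itself a linear system from audio to electrode, so it is
estimated per epoch by direct spectral division (EEG DFT / signed-audio DFT),
inverse transformed, cropped to a 10-ms lag window centred at -0.9 ms,
detrended with a sixth-order polynomial (speech has almost no energy below
~100 Hz, so the division is noise-dominated there), averaged across epochs
and tapered with a Hann window.  The audio convolved with this kernel is then
subtracted from each epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.signal.windows import hann

from .eeg import EegEpochs

logger = logging.getLogger(__name__)

DEFAULT_CENTER_MS = -0.9
DEFAULT_WINDOW_MS = 10.0


@dataclass
class LeakageKernel:
    """Estimated artifact impulse response over a short window of lags.

    ``impulse_response`` covers ``n_lags`` samples starting at ``lag_start``
    samples (negative = before acoustic zero); units are uV per unit of the
    signed stimulus audio.
    """

    impulse_response: np.ndarray
    fs: float
    lag_start: int
    polynomial_order: int = 6

    def __post_init__(self) -> None:
        self.impulse_response = np.asarray(self.impulse_response, dtype=float)

    @property
    def n_lags(self) -> int:
        return self.impulse_response.size

    @property
    def lags_ms(self) -> np.ndarray:
        return (self.lag_start + np.arange(self.n_lags)) / self.fs * 1000.0


def _window_indices(fs: float, center_ms: float, window_ms: float) -> tuple[int, int]:
    n_lags = int(round(window_ms / 1000.0 * fs))
    lag_start = int(round((center_ms - window_ms / 2.0) / 1000.0 * fs))
    return lag_start, n_lags


def estimate_leakage(
    epochs: EegEpochs,
    raw_audio_epochs: np.ndarray,
    center_ms: float = DEFAULT_CENTER_MS,
    window_ms: float = DEFAULT_WINDOW_MS,
    polynomial_order: int | None = 6,
    detrend_per_epoch: bool = True,
) -> LeakageKernel:
    """Estimate the leakage kernel from epoched EEG and signed audio.

    ``raw_audio_epochs`` is the un-rectified stimulus audio resampled to the
    EEG rate, one row per epoch (see
    :func:`speechabr.stimuli.downsample_signed_audio`).  Bins where the
    stimulus spectrum is within 1e-8 of zero are excluded from the division.
    The sixth-order polynomial detrend runs on each epoch's cropped window
    (``detrend_per_epoch=False`` fits once after averaging, for comparison;
    ``polynomial_order=None`` disables the detrend altogether).
    """
    audio = np.atleast_2d(np.asarray(raw_audio_epochs, dtype=float))
    if audio.shape[0] != epochs.n_epochs:
        raise ValueError("audio and EEG epoch counts differ")
    fs = epochs.fs
    n = epochs.n_samples
    lag_start, n_lags = _window_indices(fs, center_ms, window_ms)
    crop_idx = (lag_start + np.arange(n_lags)) % n
    t = np.linspace(-1.0, 1.0, n_lags)

    kernels = []
    for e in range(epochs.n_epochs):
        if not epochs.usable[e]:
            continue
        x = np.zeros(n)
        x[: audio.shape[1]] = audio[e]
        X = sp_fft.fft(x)
        Y = sp_fft.fft(epochs.data[e])
        mag = np.abs(X)
        good = mag > 1e-8 * mag.max()
        if not good.all():
            logger.warning(
                "leakage estimate: excluded %d zero-magnitude stimulus bins",
                int((~good).sum()),
            )
        H = np.zeros_like(Y)
        H[good] = Y[good] / X[good]
        h = sp_fft.ifft(H).real[crop_idx]
        if detrend_per_epoch and polynomial_order is not None:
            coef = np.polynomial.polynomial.polyfit(t, h, polynomial_order)
            h = h - np.polynomial.polynomial.polyval(t, coef)
        kernels.append(h)
    if not kernels:
        raise ValueError("no usable epochs for leakage estimation")
    avg = np.mean(kernels, axis=0)
    if not detrend_per_epoch and polynomial_order is not None:
        coef = np.polynomial.polynomial.polyfit(t, avg, polynomial_order)
        avg = avg - np.polynomial.polynomial.polyval(t, coef)
    avg = avg * hann(n_lags, sym=True)
    return LeakageKernel(avg, fs, lag_start, polynomial_order)


def leakage_signal(
    kernel: LeakageKernel, audio_epoch: np.ndarray, n_out: int
) -> np.ndarray:
    """Signed audio convolved with the kernel, honouring its negative lags."""
    full = np.convolve(audio_epoch, kernel.impulse_response)
    # sample t of the artifact is sum_k h[k] * a[t - (lag_start + k)]
    out = np.zeros(n_out)
    shift = kernel.lag_start
    src_lo = max(0, -shift)
    dst_lo = max(0, shift)
    length = min(full.size - src_lo, n_out - dst_lo)
    if length > 0:
        out[dst_lo : dst_lo + length] = full[src_lo : src_lo + length]
    return out


def subtract_leakage(
    epochs: EegEpochs,
    kernel: LeakageKernel,
    raw_audio_epochs: np.ndarray,
) -> EegEpochs:
    """Subtract kernel * audio from every epoch (zeroed samples stay zero)."""
    audio = np.atleast_2d(np.asarray(raw_audio_epochs, dtype=float))
    if audio.shape[0] != epochs.n_epochs:
        raise ValueError("audio and EEG epoch counts differ")
    if kernel.fs != epochs.fs:
        raise ValueError("kernel sampling rate does not match the epochs")
    data = epochs.data.copy()
    for e in range(epochs.n_epochs):
        art = leakage_signal(kernel, audio[e], epochs.n_samples)
        data[e] = data[e] - art
        data[e, epochs.rejection_mask[e]] = 0.0
    return EegEpochs(
        data,
        epochs.fs,
        epochs.onsets,
        epochs.rejection_mask.copy(),
        epochs.n_rejected.copy(),
        epochs.g_r.copy(),
        epochs.usable.copy(),
    )
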