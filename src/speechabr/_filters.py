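"""Shared IIR filtering helpers with explicit causality control.

Latency bookkeeping is central to brainstem work: a zero-phase filter can smear
later (cortical) activity backwards into brainstem lags.  Every filter in this
package therefore takes an explicit ``direction``:

``causal``
    plain forward `lfilter` (impulse response at non-negative lags only);
``anticausal``
    time-reverse, filter causally, time-reverse back (non-positive lags only);
``zerophase``
    forward-backward `filtfilt` (symmetric impulse response, doubled order).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

Direction = str
_DIRECTIONS = ("causal", "anticausal", "zerophase")


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")


def butter_filter(
    x: np.ndarray,
    fs: float,
    cutoff: float,
    btype: str,
    order: int = 1,
    direction: Direction = "causal",
    axis: int = -1,
) -> np.ndarray:
    """Apply a Butterworth filter with the stated causality.

    ``cutoff`` must lie strictly inside (0, fs/2).
    """
    _check_direction(direction)
    nyq = fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    return _apply_sos(sos, np.asarray(x, dtype=float), direction, axis)


def notch_cascade(
    x: np.ndarray,
    fs: float,
    freqs: tuple[float, ...] = (60.0, 180.0, 300.0),
    bandwidth: float = 5.0,
    direction: Direction = "causal",
    axis: int = -1,
) -> np.ndarray:
    """Cascade of second-order IIR notches with a -3 dB bandwidth in Hz.

    The quality factor of each notch is f0/bandwidth, the conventional
    parameterization of `scipy.signal.iirnotch`.
    """
    _check_direction(direction)
    y = np.asarray(x, dtype=float)
    for f0 in freqs:
        if f0 >= fs / 2.0:
            raise ValueError(f"notch frequency {f0} Hz at or above Nyquist ({fs / 2} Hz)")
        b, a = signal.iirnotch(f0, Q=f0 / bandwidth, fs=fs)
        sos = np.concatenate([b, a])[np.newaxis, :]
        y = _apply_sos(sos, y, direction, axis)
    return y


def _apply_sos(sos: np.ndarray, x: np.ndarray, direction: Direction, axis: int) -> np.ndarray:
    if direction == "causal":
        return signal.sosfilt(sos, x, axis=axis)
    if direction == "anticausal":
        rev = np.flip(x, axis=axis)
        return np.flip(signal.sosfilt(sos, rev, axis=axis), axis=axis)
    return signal.sosfiltfilt(sos, x, axis=axis)


def raised_cosine_fade(n_total: int, n_fade: int) -> np.ndarray:
    """Unit window with raised-cosine fade-in and fade-out of ``n_fade`` samples."""
    if 2 * n_fade > n_total:
        raise ValueError("fade longer than half the segment")
    w = np.ones(n_total)
    if n_fade > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        w[:n_fade] = ramp
        w[-n_fade:] = ramp[::-1]
    return w
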