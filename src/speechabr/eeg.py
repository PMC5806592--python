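"""Continuous-EEG conditioning: causal filtering, excursion zeroing, epoching.

All EEG filtering is causal so that no activity can leak backwards in time —
essential when peak latency is the evidence for a subcortical origin.  Instead
of rejecting whole (minute-long) epochs, brief high-amplitude excursions are
zeroed: whenever the potential crosses +/-100 uV a 1-s segment centred on the
offending sample is set to zero.  Zeroing removes energy, so each epoch
carries a corrective gain g_r = N / (N - N_r) (N samples per epoch, N_r zeroed
samples) that is applied to the data at regression time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._filters import butter_filter, notch_cascade

logger = logging.getLogger(__name__)


@dataclass
class EegRecording:
    """Single-channel continuous EEG in microvolts with epoch-onset markers."""

    potential: np.ndarray
    fs: float = 10000.0
    markers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    channel_label: str = "EEG"

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        self.markers = np.asarray(self.markers, dtype=int)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.potential.ndim != 1:
            raise ValueError("single-channel recording expected (1-D potential)")
        if not np.all(np.isfinite(self.potential)):
            raise ValueError("EEG contains NaN/inf; clean the recording at load time")
        if np.any(np.diff(self.markers) < 0):
            raise ValueError("markers must be sorted")
        if self.markers.size and (
            self.markers[0] < 0 or self.markers[-1] >= self.potential.size
        ):
            raise ValueError("markers must lie within the record")

    @property
    def n_samples(self) -> int:
        return self.potential.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EegEpochs:
    """Epoch-segmented EEG with per-epoch rejection bookkeeping.

    ``rejection_mask`` is True where samples were zeroed; ``g_r`` is the
    corrective gain N/(N-N_r) and ``usable`` flags epochs that were not
    entirely zeroed.  The stored data are zeroed but *not* g_r-scaled; the
    gain is applied when the epochs enter a regression.
    """

    data: np.ndarray
    fs: float
    onsets: np.ndarray | None = None
    rejection_mask: np.ndarray = None  # type: ignore[assignment]
    n_rejected: np.ndarray = None  # type: ignore[assignment]
    g_r: np.ndarray = None  # type: ignore[assignment]
    usable: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        n_ep = self.data.shape[0]
        if self.rejection_mask is None:
            self.rejection_mask = np.zeros(self.data.shape, dtype=bool)
        if self.n_rejected is None:
            self.n_rejected = np.zeros(n_ep, dtype=int)
        if self.g_r is None:
            self.g_r = np.ones(n_ep)
        if self.usable is None:
            self.usable = np.ones(n_ep, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def select(self, idx) -> "EegEpochs":
        idx = np.atleast_1d(np.asarray(idx))
        onsets = self.onsets[idx] if self.onsets is not None else None
        return EegEpochs(
            self.data[idx],
            self.fs,
            onsets,
            self.rejection_mask[idx],
            self.n_rejected[idx],
            self.g_r[idx],
            self.usable[idx],
        )


def filter_eeg(
    rec: EegRecording,
    hp: float = 1.0,
    hp_order: int = 1,
    notches: tuple[float, ...] = (60.0, 180.0, 300.0),
    notch_bandwidth: float = 5.0,
) -> EegRecording:
    """Causal 1-Hz first-order Butterworth high-pass, then 60/180/300 Hz
    second-order notches with a 5-Hz (-3 dB) bandwidth."""
    y = butter_filter(rec.potential, rec.fs, hp, "highpass", hp_order, "causal")
    if notches:
        y = notch_cascade(y, rec.fs, tuple(notches), notch_bandwidth, "causal")
    return EegRecording(y, rec.fs, rec.markers.copy(), rec.channel_label)


def epoch_recording(
    rec: EegRecording,
    stim_durations,
    tail: float = 0.1,
) -> EegEpochs:
    """Cut the record into epochs of stimulus duration + ``tail`` seconds.

    ``stim_durations`` is a scalar or one duration (s) per marker.  A final
    epoch running past the end of the record is an error, never silent
    padding.
    """
    durations = np.broadcast_to(np.asarray(stim_durations, dtype=float), rec.markers.shape)
    if rec.markers.size == 0:
        raise ValueError("recording has no epoch-onset markers")
    lengths = np.round((durations + tail) * rec.fs).astype(int)
    if np.unique(lengths).size > 1:
        raise ValueError("all epochs must have the same length")
    n = int(lengths[0])
    rows = []
    for m in rec.markers:
        if m + n > rec.n_samples:
            raise ValueError(
                f"epoch starting at sample {m} runs past the end of the record"
            )
        rows.append(rec.potential[m : m + n])
    return EegEpochs(np.vstack(rows), rec.fs, onsets=rec.markers.copy())


def zero_excursions(
    epochs: EegEpochs | EegRecording,
    threshold: float = 100.0,
    window: float = 1.0,
) -> EegEpochs:
    """Zero a ``window``-s segment centred on every +/-``threshold`` crossing.

    The zeroed span for an offender at sample i is the half-open range
    [i - w//2, i - w//2 + w) with w = round(window * fs), clipped at epoch
    edges.  N_r counts the union of zeroed samples per epoch and
    g_r = N/(N - N_r).  Epochs zeroed in full are flagged unusable.  The
    operation is idempotent.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if isinstance(epochs, EegRecording):
        epochs = EegEpochs(epochs.potential[np.newaxis, :], epochs.fs)
    fs = epochs.fs
    w = int(round(window * fs))
    n = epochs.n_samples
    data = epochs.data.copy()
    mask = epochs.rejection_mask.copy()
    n_rej = np.zeros(epochs.n_epochs, dtype=int)
    g_r = np.ones(epochs.n_epochs)
    usable = np.ones(epochs.n_epochs, dtype=bool)
    for e in range(epochs.n_epochs):
        offenders = np.flatnonzero(np.abs(data[e]) > threshold)
        for i in offenders:
            start = max(0, i - w // 2)
            stop = min(n, i - w // 2 + w)
            mask[e, start:stop] = True
        data[e, mask[e]] = 0.0
        n_rej[e] = int(mask[e].sum())
        if n_rej[e] == n:
            usable[e] = False
            g_r[e] = np.nan
            logger.warning("epoch %d fully rejected; excluded from analysis", e)
        else:
            g_r[e] = n / (n - n_rej[e])
    return EegEpochs(data, fs, epochs.onsets, mask, n_rej, g_r, usable)
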