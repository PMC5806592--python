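"""Deconvolved evoked responses and the traditional averaged ABR.

The brain is modelled as a linear time-invariant system: the EEG is the
regressor (rectified audio or click impulse train) convolved with an unknown
impulse response, plus noise.  The response is the least-squares solution over
a window of lags, computed in the frequency domain: cross-spectra between
regressor and EEG and regressor power spectra are accumulated across epochs
and divided (no regularization — the regressors are broadband).  Each epoch is
zero-padded by the lag span so the estimate is linear, not circular.

For impulse-train regressors the train is white by construction, so the
autocorrelation is treated as diagonal (division by the summed regressor
energy).  This makes the estimate *exactly* the click-triggered average — the
standard ABR computation — so clicks and speech share one analysis path.

The two rectified-polarity branches are solved as independent single-regressor
problems and averaged; a joint two-column solve is available for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from ._filters import butter_filter, notch_cascade
from .eeg import EegEpochs
from .stimuli import ClickTrain, Regressor

logger = logging.getLogger(__name__)

DEFAULT_LAGS_MS = (-150.0, 350.0)


@dataclass
class ResponseWaveform:
    """Evoked-response amplitude versus lag on a uniform 1/fs grid.

    ``n_pre`` is the number of samples before zero lag; the waveform spans
    lags from ``-n_pre/fs`` to ``(len-1-n_pre)/fs``.  ``provenance`` records
    the processing chain (regressor kind, filters, constituents) so a waveform
    can be reproduced; ``normalized`` marks speech responses that have been
    scaled by the cohort normalization factor g_n.
    """

    amplitude: np.ndarray
    fs: float
    n_pre: int
    provenance: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 1:
            raise ValueError("response amplitude must be 1-D")

    @property
    def n_samples(self) -> int:
        return self.amplitude.size

    @property
    def lags_ms(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.n_pre) / self.fs * 1000.0

    @property
    def lag_range_ms(self) -> tuple[float, float]:
        lags = self.lags_ms
        return float(lags[0]), float(lags[-1])

    def window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        lags = self.lags_ms
        mask = (lags >= lo - 1e-9) & (lags <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"window {window_ms} ms outside lag range {self.lag_range_ms}")
        return mask

    def window_values(self, window_ms: tuple[float, float]) -> np.ndarray:
        return self.amplitude[self.window_mask(window_ms)]

    def replace(self, amplitude=None, provenance=None, normalized=None) -> "ResponseWaveform":
        return ResponseWaveform(
            self.amplitude.copy() if amplitude is None else amplitude,
            self.fs,
            self.n_pre,
            dict(self.provenance) if provenance is None else provenance,
            self.normalized if normalized is None else normalized,
        )

    def plot(self, ax=None, window_ms=None, **kwargs):
        """Plot amplitude against lag (ms); returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lags, amp = self.lags_ms, self.amplitude
        if window_ms is not None:
            m = self.window_mask(window_ms)
            lags, amp = lags[m], amp[m]
        ax.plot(lags, amp, **kwargs)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("amplitude (µV)" if self.normalized else "amplitude (a.u.)")
        return ax


@dataclass
class NormalizationFactor:
    """Cohort ratio g_n = E_i(sigma_click,i) / E_i(sigma_speech,i).

    sigma_*,i is the standard deviation of subject i's response over the
    0-20 ms window; g_n puts speech-derived responses on a microvolt scale
    comparable to click-evoked ones.
    """

    g_n: float
    sigma_click: np.ndarray
    sigma_speech: np.ndarray
    window_ms: tuple[float, float] = (0.0, 20.0)


def _lag_counts(lags_ms: tuple[float, float], fs: float) -> tuple[int, int]:
    lo, hi = lags_ms
    if hi <= lo:
        raise ValueError("lag window must have positive length")
    return int(round(-lo / 1000.0 * fs)), int(round(hi / 1000.0 * fs))


def _branch_arrays(epochs: EegEpochs, regressor: Regressor) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if regressor.fs != epochs.fs:
        raise ValueError("regressor and epochs must share a sampling rate")
    if regressor.n_epochs != epochs.n_epochs:
        raise ValueError("regressor and epochs must have matching epoch counts")
    if regressor.n_samples > epochs.n_samples:
        raise ValueError("regressor epochs longer than EEG epochs")
    keep = np.flatnonzero(epochs.usable)
    if keep.size == 0:
        raise ValueError("no usable epochs")
    y = epochs.data[keep] * epochs.g_r[keep, np.newaxis]
    return regressor.pos[keep], regressor.neg[keep], y


def deconvolve(
    epochs: EegEpochs,
    regressor: Regressor,
    lags_ms: tuple[float, float] = DEFAULT_LAGS_MS,
    polarity_mode: str = "average",
) -> ResponseWaveform:
    """Frequency-domain least-squares impulse response over a lag window.

    Cross-spectra and regressor power spectra are summed over all usable
    epochs before dividing (one joint regression, variance-optimal).  Epochs
    are zero-padded by the lag span, making the correlation linear rather
    than circular.  Impulse-train regressors use the white-autocorrelation
    normalization (summed energy), which equals the click-triggered average.

    ``polarity_mode='average'`` solves pos and neg branches independently and
    averages; ``'joint'`` solves the 2x2 cross-spectral system per frequency.
    """
    pos, neg, y = _branch_arrays(epochs, regressor)
    fs = epochs.fs
    n_pre, n_post = _lag_counts(lags_ms, fs)
    n = epochs.n_samples
    nfft = sp_fft.next_fast_len(n + n_pre + n_post, real=True)

    Y = sp_fft.rfft(y, nfft, axis=1)
    if regressor.kind == "impulse_train" or np.array_equal(pos, neg):
        branches = [pos]  # identical branches: solve once
    else:
        branches = [pos, neg]

    if polarity_mode == "joint" and len(branches) == 2:
        h = _joint_solve(branches[0], branches[1], Y, nfft)
    elif polarity_mode in ("average", "joint"):
        hs = [_single_solve(b, Y, nfft, regressor.kind) for b in branches]
        h = np.mean(hs, axis=0)
    else:
        raise ValueError("polarity_mode must be 'average' or 'joint'")

    amplitude = np.concatenate([h[nfft - n_pre :], h[: n_post + 1]])
    prov = {
        "regressor_kind": regressor.kind,
        "lags_ms": tuple(lags_ms),
        "polarity_mode": polarity_mode,
        "n_epochs": int(np.count_nonzero(epochs.usable)),
        "filters": [],
    }
    return ResponseWaveform(amplitude, fs, n_pre, prov)


def _single_solve(x: np.ndarray, Y: np.ndarray, nfft: int, kind: str) -> np.ndarray:
    energy = float(np.sum(x * x))
    if energy <= 0:
        raise ValueError("degenerate regressor: zero total power")
    X = sp_fft.rfft(x, nfft, axis=1)
    sxy = np.sum(np.conj(X) * Y, axis=0)
    if kind == "impulse_train":
        return sp_fft.irfft(sxy, nfft) / energy
    sxx = np.sum(np.abs(X) ** 2, axis=0)
    good = sxx > 1e-12 * sxx.max()
    if not good.all():
        logger.warning("excluded %d near-zero regressor bins", int((~good).sum()))
    quot = np.zeros_like(sxy)
    quot[good] = sxy[good] / sxx[good]
    return sp_fft.irfft(quot, nfft)


def _joint_solve(pos: np.ndarray, neg: np.ndarray, Y: np.ndarray, nfft: int) -> np.ndarray:
    if pos.shape[0] < 2:
        # with one epoch the per-frequency 2x2 system is rank deficient
        raise ValueError("joint polarity solve needs at least two epochs")
    P = sp_fft.rfft(pos, nfft, axis=1)
    N = sp_fft.rfft(neg, nfft, axis=1)
    spp = np.sum(np.abs(P) ** 2, axis=0)
    snn = np.sum(np.abs(N) ** 2, axis=0)
    spn = np.sum(np.conj(P) * N, axis=0)
    spy = np.sum(np.conj(P) * Y, axis=0)
    sny = np.sum(np.conj(N) * Y, axis=0)
    det = spp * snn - np.abs(spn) ** 2
    good = det > 1e-12 * np.max(det)
    hp = np.zeros_like(spy)
    hn = np.zeros_like(sny)
    hp[good] = (snn[good] * spy[good] - spn[good] * sny[good]) / det[good]
    hn[good] = (spp[good] * sny[good] - np.conj(spn[good]) * spy[good]) / det[good]
    return 0.5 * (sp_fft.irfft(hp, nfft) + sp_fft.irfft(hn, nfft))


def cumulative_deconvolve(
    epochs: EegEpochs,
    regressor: Regressor,
    lags_ms: tuple[float, float] = DEFAULT_LAGS_MS,
    prefixes: list[int] | None = None,
    lowpass: float | None = None,
    lowpass_direction: str = "causal",
) -> list[ResponseWaveform]:
    """Responses from the first k epochs, for each k in ``prefixes``.

    Spectra are accumulated in a single streaming pass, so the cost of the
    whole curve is close to that of one full deconvolution.  Unusable epochs
    still advance the prefix counter but contribute nothing.
    """
    if regressor.fs != epochs.fs or regressor.n_epochs != epochs.n_epochs:
        raise ValueError("regressor and epochs must match")
    n_ep = epochs.n_epochs
    if prefixes is None:
        prefixes = list(range(1, n_ep + 1))
    if any(p < 1 or p > n_ep for p in prefixes):
        raise ValueError("prefixes must lie in 1..n_epochs")
    fs = epochs.fs
    n_pre, n_post = _lag_counts(lags_ms, fs)
    nfft = sp_fft.next_fast_len(epochs.n_samples + n_pre + n_post, real=True)
    same = np.array_equal(regressor.pos, regressor.neg)
    branches = [regressor.pos] if same else [regressor.pos, regressor.neg]
    n_b = len(branches)
    sxy = [np.zeros(nfft // 2 + 1, dtype=complex) for _ in range(n_b)]
    sxx = [np.zeros(nfft // 2 + 1) for _ in range(n_b)]
    energy = [0.0] * n_b
    out: list[ResponseWaveform] = []
    targets = sorted(set(prefixes))
    ti = 0
    for e in range(n_ep):
        if epochs.usable[e]:
            Ye = sp_fft.rfft(epochs.data[e] * epochs.g_r[e], nfft)
            for b, xb in enumerate(branches):
                Xe = sp_fft.rfft(xb[e], nfft)
                sxy[b] += np.conj(Xe) * Ye
                sxx[b] += np.abs(Xe) ** 2
                energy[b] += float(np.sum(xb[e] ** 2))
        while ti < len(targets) and targets[ti] == e + 1:
            hs = []
            for b in range(n_b):
                if regressor.kind == "impulse_train":
                    if energy[b] <= 0:
                        raise ValueError("degenerate regressor prefix")
                    hs.append(sp_fft.irfft(sxy[b], nfft) / energy[b])
                else:
                    good = sxx[b] > 1e-12 * sxx[b].max()
                    quot = np.zeros_like(sxy[b])
                    quot[good] = sxy[b][good] / sxx[b][good]
                    hs.append(sp_fft.irfft(quot, nfft))
            h = np.mean(hs, axis=0)
            amp = np.concatenate([h[nfft - n_pre :], h[: n_post + 1]])
            resp = ResponseWaveform(
                amp,
                fs,
                n_pre,
                {
                    "regressor_kind": regressor.kind,
                    "lags_ms": tuple(lags_ms),
                    "n_epochs": e + 1,
                    "filters": [],
                },
            )
            if lowpass is not None:
                resp = postfilter_response(resp, lowpass, direction=lowpass_direction)
            out.append(resp)
            ti += 1
    # restore requested order (prefixes may repeat)
    by_n = {r.provenance["n_epochs"]: r for r in out}
    return [by_n[p] for p in prefixes]


def postfilter_response(
    resp: ResponseWaveform,
    lowpass: float | None = 2000.0,
    order: int = 1,
    direction: str = "causal",
) -> ResponseWaveform:
    """Low-pass the response waveform (default 2 kHz, first-order Butterworth).

    Lower cutoffs (200 Hz, 20 Hz) turn the same waveform into middle- and
    late-latency views.  ``lowpass=None`` is the identity.
    """
    if lowpass is None:
        return resp.replace()
    y = butter_filter(resp.amplitude, resp.fs, lowpass, "lowpass", order, direction)
    prov = dict(resp.provenance)
    prov["filters"] = list(prov.get("filters", [])) + [
        {"type": "lowpass", "cutoff_hz": lowpass, "order": order, "direction": direction}
    ]
    return resp.replace(amplitude=y, provenance=prov)


def combine_conditions(
    responses: list[ResponseWaveform], weights=None
) -> ResponseWaveform:
    """Pointwise (weighted) mean of responses on identical lag grids.

    Used to average the per-narrator responses into one speech-derived
    response per subject.
    """
    if not responses:
        raise ValueError("no responses to combine")
    r0 = responses[0]
    for r in responses[1:]:
        if r.fs != r0.fs or r.n_pre != r0.n_pre or r.n_samples != r0.n_samples:
            raise ValueError("responses must share an identical lag grid")
    w = np.ones(len(responses)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    amp = np.tensordot(w, np.vstack([r.amplitude for r in responses]), axes=1)
    prov = {
        "combined_from": [r.provenance for r in responses],
        "weights": w.tolist(),
        "filters": list(r0.provenance.get("filters", [])),
    }
    return ResponseWaveform(amp, r0.fs, r0.n_pre, prov, r0.normalized)


def compute_gn(
    click_responses: list[ResponseWaveform],
    speech_responses: list[ResponseWaveform],
    window_ms: tuple[float, float] = (0.0, 20.0),
) -> NormalizationFactor:
    """Cohort normalization g_n = mean_i(sigma_click,i) / mean_i(sigma_speech,i)."""
    if len(click_responses) != len(speech_responses) or not click_responses:
        raise ValueError("need one click and one speech response per subject")
    sc = np.array([np.std(r.window_values(window_ms)) for r in click_responses])
    ss = np.array([np.std(r.window_values(window_ms)) for r in speech_responses])
    if np.mean(ss) == 0:
        raise ValueError("speech responses have zero SD in the window")
    return NormalizationFactor(float(np.mean(sc) / np.mean(ss)), sc, ss, tuple(window_ms))


def apply_gn(resp: ResponseWaveform, factor: NormalizationFactor | float) -> ResponseWaveform:
    """Scale a speech-derived response onto the microvolt scale of clicks."""
    g = factor.g_n if isinstance(factor, NormalizationFactor) else float(factor)
    prov = dict(resp.provenance)
    prov["g_n"] = g
    return resp.replace(amplitude=resp.amplitude * g, provenance=prov, normalized=True)


def click_triggered_average(
    epochs: EegEpochs,
    trains: ClickTrain | list[ClickTrain],
    lags_ms: tuple[float, float] = DEFAULT_LAGS_MS,
) -> ResponseWaveform:
    """Time-domain average of EEG sweeps around each click (zero-filled at
    record edges).  Serves as the independent reference for the deconvolution
    path; for unit-impulse regressors the two are mathematically identical."""
    tr_list = trains if isinstance(trains, (list, tuple)) else [trains] * epochs.n_epochs
    fs = epochs.fs
    n_pre, n_post = _lag_counts(lags_ms, fs)
    total = np.zeros(n_pre + n_post + 1)
    count = 0
    n = epochs.n_samples
    for e in range(epochs.n_epochs):
        if not epochs.usable[e]:
            continue
        y = epochs.data[e] * epochs.g_r[e]
        idx = np.round(np.asarray(tr_list[e].click_times) * fs).astype(int)
        idx = np.unique(idx[(idx >= 0) & (idx < int(round(tr_list[e].duration * fs)))])
        for i in idx:
            lo, hi = i - n_pre, i + n_post + 1
            sweep = np.zeros(n_pre + n_post + 1)
            src_lo, src_hi = max(0, lo), min(n, hi)
            sweep[src_lo - lo : src_lo - lo + (src_hi - src_lo)] = y[src_lo:src_hi]
            total += sweep
            count += 1
    if count == 0:
        raise ValueError("no clicks to average")
    return ResponseWaveform(
        total / count,
        fs,
        n_pre,
        {"regressor_kind": "impulse_train", "method": "triggered_average", "n_sweeps": count},
    )


def average_abr_traditional(
    epochs: EegEpochs,
    trains: ClickTrain | list[ClickTrain],
    hp: float = 150.0,
    hp_order: int = 2,
    lowpass: float = 2000.0,
    notches: tuple[float, ...] = (60.0, 180.0, 300.0),
    window_ms: tuple[float, float | None] = (-3.0, None),
    reject_pp: float = 100.0,
) -> ResponseWaveform:
    """Standard averaged ABR from periodic click trains.

    Each epoch is notch filtered, low-passed at 2 kHz and high-passed with a
    causal second-order Butterworth at 150 Hz (the canonical display filter).
    Sweeps are cut per click from -3 ms to -3 ms + 1/rate (the longest window
    that avoids temporal wrapping at the periodic rate), rejected when their
    peak-to-peak amplitude exceeds ``reject_pp`` uV, and averaged.
    """
    tr_list = trains if isinstance(trains, (list, tuple)) else [trains] * epochs.n_epochs
    fs = epochs.fs
    rate = tr_list[0].rate
    start_ms, end_ms = window_ms
    if end_ms is None:
        end_ms = start_ms + 1000.0 / rate
    n_pre = int(round(-start_ms / 1000.0 * fs))
    n_post = int(round(end_ms / 1000.0 * fs))
    filt = np.empty_like(epochs.data)
    for e in range(epochs.n_epochs):
        y = epochs.data[e]
        if notches:
            y = notch_cascade(y, fs, tuple(notches), 5.0, "causal")
        if lowpass is not None:
            y = butter_filter(y, fs, lowpass, "lowpass", 1, "causal")
        y = butter_filter(y, fs, hp, "highpass", hp_order, "causal")
        filt[e] = y
    total = np.zeros(n_pre + n_post + 1)
    n_kept = 0
    n_rejected = 0
    n = epochs.n_samples
    for e in range(epochs.n_epochs):
        if not epochs.usable[e]:
            continue
        idx = np.round(np.asarray(tr_list[e].click_times) * fs).astype(int)
        for i in idx:
            lo, hi = i - n_pre, i + n_post + 1
            if lo < 0 or hi > n:
                continue
            sweep = filt[e, lo:hi]
            if np.ptp(sweep) > reject_pp:
                n_rejected += 1
                continue
            total += sweep
            n_kept += 1
    if n_kept == 0:
        raise ValueError("all sweeps rejected")
    prov = {
        "method": "triggered_average",
        "highpass_hz": hp,
        "window_ms": (start_ms, end_ms),
        "n_sweeps": n_kept,
        "n_rejected": n_rejected,
        "filters": [{"type": "highpass", "cutoff_hz": hp, "order": hp_order, "direction": "causal"}],
    }
    return ResponseWaveform(total / n_kept, fs, n_pre, prov, normalized=True)
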