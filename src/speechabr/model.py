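"""Model/Results front-end over the deconvolution pipeline.

`BrainstemResponseModel` holds conditioned EEG epochs and the stimulus
regressor; `fit()` runs the frequency-domain least-squares deconvolution and
returns a `BrainstemResponseResults` carrying the response waveform together
with its standard measurements (Wave V latency/amplitude, evoked SNR, SNR
growth curve, split-half stability) and a text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import leakage as _leakage
from . import metrics as _metrics
from . import response as _response
from .eeg import EegEpochs, EegRecording, epoch_recording, filter_eeg, zero_excursions
from .response import ResponseWaveform
from .stimuli import Regressor


class BrainstemResponseModel:
    """Linear encoding model of the EEG as regressor convolved with a kernel.

    Parameters
    ----------
    epochs : EegEpochs
        Conditioned (filtered, excursion-zeroed) EEG epochs in microvolts.
    regressor : Regressor
        Rectified-speech or impulse-train drive at the EEG rate, one row per
        epoch.
    lags_ms : tuple
        Lag window of the estimated response; the default -150..350 ms covers
        a pre-stimulus noise floor through late cortical components.
    raw_audio_epochs : ndarray, optional
        Signed stimulus audio at the EEG rate (one row per epoch); required
        when ``remove_leakage`` is enabled.
    """

    def __init__(
        self,
        epochs: EegEpochs,
        regressor: Regressor,
        lags_ms: tuple[float, float] = _response.DEFAULT_LAGS_MS,
        raw_audio_epochs: np.ndarray | None = None,
        remove_leakage: bool = False,
    ) -> None:
        self.epochs = epochs
        self.regressor = regressor
        self.lags_ms = tuple(lags_ms)
        self.raw_audio_epochs = raw_audio_epochs
        self.remove_leakage = remove_leakage
        self.leakage_kernel_: _leakage.LeakageKernel | None = None

    @classmethod
    def from_recording(
        cls,
        recording: EegRecording,
        regressor: Regressor,
        stim_duration: float,
        lags_ms: tuple[float, float] = _response.DEFAULT_LAGS_MS,
        reject_threshold_uv: float = 100.0,
        raw_audio_epochs: np.ndarray | None = None,
        remove_leakage: bool = False,
    ) -> "BrainstemResponseModel":
        """Full preprocessing chain from a continuous recording.

        Causal 1-Hz high-pass and line notches, epoching (stimulus duration
        plus 100 ms), then +/-100 uV excursion zeroing with corrective gains.
        """
        rec = filter_eeg(recording)
        epochs = epoch_recording(rec, stim_duration)
        epochs = zero_excursions(epochs, threshold=reject_threshold_uv)
        return cls(epochs, regressor, lags_ms, raw_audio_epochs, remove_leakage)

    def _working_epochs(self) -> EegEpochs:
        epochs = self.epochs
        if self.remove_leakage:
            if self.raw_audio_epochs is None:
                raise ValueError("remove_leakage requires raw_audio_epochs")
            self.leakage_kernel_ = _leakage.estimate_leakage(epochs, self.raw_audio_epochs)
            epochs = _leakage.subtract_leakage(epochs, self.leakage_kernel_, self.raw_audio_epochs)
        return epochs

    def fit(
        self,
        lowpass: float | None = 2000.0,
        lowpass_direction: str = "causal",
        polarity_mode: str = "average",
    ) -> "BrainstemResponseResults":
        """Estimate the response and package it with its measurements."""
        epochs = self._working_epochs()
        resp = _response.deconvolve(epochs, self.regressor, self.lags_ms, polarity_mode)
        resp = _response.postfilter_response(resp, lowpass, direction=lowpass_direction)
        return BrainstemResponseResults(
            self, resp, epochs, lowpass, lowpass_direction, polarity_mode
        )


@dataclass
class BrainstemResponseResults:
    """Fitted response waveform plus the standard derived measures."""

    model: BrainstemResponseModel
    response: ResponseWaveform
    _epochs: EegEpochs = field(repr=False)
    lowpass: float | None = 2000.0
    lowpass_direction: str = "causal"
    polarity_mode: str = "average"

    def wave_v(self, window_ms=(5.0, 7.0)) -> _metrics.WaveVMeasurement:
        return _metrics.find_wave_v(self.response, window_ms)

    def snr(self) -> _metrics.SnrMeasurement:
        return _metrics.snr(self.response)

    def snr_curve(self, prefixes=None) -> list[_metrics.SnrMeasurement]:
        """Evoked SNR of the cumulative response after each epoch count."""
        resps = _response.cumulative_deconvolve(
            self._epochs,
            self.model.regressor,
            self.model.lags_ms,
            prefixes,
            self.lowpass,
            self.lowpass_direction,
        )
        return _metrics.snr_curve(resps)

    def split_responses(self, idx_a, idx_b) -> tuple[ResponseWaveform, ResponseWaveform]:
        """Responses derived from two disjoint epoch subsets (same pipeline)."""
        out = []
        for idx in (idx_a, idx_b):
            resp = _response.deconvolve(
                self._epochs.select(idx),
                self.model.regressor.select(idx),
                self.model.lags_ms,
                self.polarity_mode,
            )
            out.append(_response.postfilter_response(resp, self.lowpass,
                                                     direction=self.lowpass_direction))
        return out[0], out[1]

    def split_half_r(self, mode: str = "even_odd") -> float:
        """Correlation (0-20 ms) between even/odd or first/second-half splits."""
        n = self._epochs.n_epochs
        if mode == "even_odd":
            idx_a, idx_b = _metrics.even_odd_split(n)
        elif mode == "session_half":
            idx_a, idx_b = _metrics.session_half_split(n)
        else:
            raise ValueError("mode must be 'even_odd' or 'session_half'")
        a, b = self.split_responses(idx_a, idx_b)
        return _metrics.correlate_window(a, b)

    def correlate(self, other: "BrainstemResponseResults | ResponseWaveform",
                  window_ms=(0.0, 20.0)) -> float:
        resp = other.response if isinstance(other, BrainstemResponseResults) else other
        return _metrics.correlate_window(self.response, resp, window_ms)

    def summary(self) -> str:
        wv = self.wave_v()
        sn = self.snr()
        prov = self.response.provenance
        lines = [
            "Brainstem response (frequency-domain deconvolution)",
            "=" * 53,
            f"regressor kind      : {prov.get('regressor_kind')}",
            f"epochs used         : {prov.get('n_epochs')}",
            f"lag window (ms)     : {prov.get('lags_ms')}",
            f"response low-pass   : {self.lowpass} Hz ({self.lowpass_direction})",
            f"Wave V latency (ms) : {wv.latency_ms:.2f}",
            f"Wave V amplitude    : {wv.amplitude_uv:.4g} "
            + ("µV" if self.response.normalized else "a.u."),
            f"evoked SNR (dB)     : "
            + (f"{sn.snr_db:.2f}" if sn.defined else "undefined (signal <= noise)"),
            f"  signal window (ms): {sn.signal_window_ms}",
            f"  noise window (ms) : {sn.noise_window_ms}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, window_ms=None, **kwargs):
        return self.response.plot(ax=ax, window_ms=window_ms, **kwargs)
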