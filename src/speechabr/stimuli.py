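"""Stimulus preparation: calibrated speech audio, click trains, and regressors.

The acoustic chain mirrors a typical brainstem-EEG experiment.  Continuous
speech is silence-truncated, gently high-passed at 1 kHz (the brainstem
response is dominated by high stimulus frequencies), RMS-normalized to a
calibrated digital level, and sectioned into long overlapping epochs with
raised-cosine fades.  Click stimuli are Poisson (or periodic) trains of brief
two-sample pulses at a matched peak-to-peak-equivalent level.

The regressor — the input of the linear encoding model — is either the
half-wave rectified audio (split into a positive-peaks branch and an
inverted-negative-peaks branch, each resampled to the EEG rate) or, for
clicks, a train of unit-height single-sample impulses placed at the nearest
EEG-rate sample.  Impulse trains deliberately bypass anti-alias resampling:
low-passing an ideal impulse train would only introduce Gibbs ringing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from ._filters import butter_filter, raised_cosine_fade

logger = logging.getLogger(__name__)

#: digital RMS that corresponds to the SPL reference (a 1-kHz tone at 75 dB SPL)
DEFAULT_RMS_TARGET = 0.01
DEFAULT_SPL_REFERENCE = 75.0


@dataclass
class AudioStimulus:
    """A calibrated mono stimulus waveform.

    ``samples`` are unitless digital pressure on a full-scale +/-1 range; the
    calibration convention is that a waveform of RMS ``rms_target`` plays back
    at ``spl_reference`` dB SPL.
    """

    samples: np.ndarray
    fs: float
    rms_target: float = DEFAULT_RMS_TARGET
    spl_reference: float = DEFAULT_SPL_REFERENCE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("AudioStimulus is mono: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def replace(self, samples: np.ndarray) -> "AudioStimulus":
        return AudioStimulus(samples, self.fs, self.rms_target, self.spl_reference)


@dataclass
class EpochedStimulus:
    """Equal-length stimulus epochs with shared overlap and raised-cosine fades.

    ``epochs`` carry the fades as presented; ``raw_epochs`` are the same
    segments before fading (consecutive raw epochs share ``overlap_dur``
    seconds of content exactly).
    """

    raw_epochs: list[AudioStimulus]
    epoch_dur: float = 64.0
    fade_dur: float = 1.0
    overlap_dur: float = 4.0
    epochs: list[AudioStimulus] = field(init=False)

    def __post_init__(self) -> None:
        counts = {e.n_samples for e in self.raw_epochs}
        if len(counts) > 1:
            raise ValueError("epochs must all have the same sample count")
        faded = []
        for e in self.raw_epochs:
            n_fade = int(round(self.fade_dur * e.fs))
            faded.append(e.replace(e.samples * raised_cosine_fade(e.n_samples, n_fade)))
        self.epochs = faded

    @property
    def n_epochs(self) -> int:
        return len(self.raw_epochs)


@dataclass
class ClickTrain:
    """Click times of a Poisson or periodic train at a fixed average rate."""

    click_times: np.ndarray
    rate: float = 44.1
    duration: float = 30.0
    click_width_samples: int = 2
    fs_audio: float = 24414.0
    polarity: str = "rarefaction"
    timing: str = "poisson"

    def __post_init__(self) -> None:
        self.click_times = np.asarray(self.click_times, dtype=float)
        if np.any(np.diff(self.click_times) < 0):
            raise ValueError("click times must be sorted")
        if self.click_times.size and (
            self.click_times[0] < 0 or self.click_times[-1] >= self.duration
        ):
            raise ValueError("click times must lie in [0, duration)")
        if self.polarity not in ("rarefaction", "condensation"):
            raise ValueError("polarity must be 'rarefaction' or 'condensation'")
        if self.timing not in ("poisson", "periodic"):
            raise ValueError("timing must be 'poisson' or 'periodic'")

    @property
    def n_clicks(self) -> int:
        return self.click_times.size


@dataclass
class Regressor:
    """Dual-polarity, non-negative drive signal(s) at the EEG sampling rate.

    ``pos``/``neg`` are (n_epochs, n_samples) arrays.  For rectified speech,
    ``pos - neg`` reconstructs the signed (downsampled) audio; for impulse
    trains the two branches are identical 0/1 impulse sequences.
    """

    pos: np.ndarray
    neg: np.ndarray
    fs: float
    kind: str

    def __post_init__(self) -> None:
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        self.neg = np.atleast_2d(np.asarray(self.neg, dtype=float))
        if self.pos.shape != self.neg.shape:
            raise ValueError("pos and neg must have matching shapes")
        if self.kind not in ("rectified_speech", "impulse_train"):
            raise ValueError("kind must be 'rectified_speech' or 'impulse_train'")
        if np.any(self.pos < 0) or np.any(self.neg < 0):
            raise ValueError("regressor branches must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.pos.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pos.shape[1]

    @property
    def drive(self) -> np.ndarray:
        """Mean of the two rectified branches (the model's effective input)."""
        return 0.5 * (self.pos + self.neg)

    def select(self, idx) -> "Regressor":
        return Regressor(self.pos[idx], self.neg[idx], self.fs, self.kind)

    @classmethod
    def concatenate(cls, regs: list["Regressor"]) -> "Regressor":
        kinds = {r.kind for r in regs}
        fss = {r.fs for r in regs}
        if len(kinds) > 1 or len(fss) > 1:
            raise ValueError("regressors must share kind and sampling rate")
        return cls(
            np.concatenate([r.pos for r in regs], axis=0),
            np.concatenate([r.neg for r in regs], axis=0),
            regs[0].fs,
            regs[0].kind,
        )


# ---------------------------------------------------------------------------
# speech processing


def truncate_silences(
    audio: AudioStimulus,
    max_pause: float = 0.5,
    frame_dur: float = 0.010,
    threshold_db: float = -40.0,
) -> AudioStimulus:
    """Shorten every silent pause longer than ``max_pause`` s to ``max_pause``.

    Silence is detected on non-overlapping ``frame_dur`` frames whose RMS falls
    below ``threshold_db`` relative to the whole-signal RMS; a silent run is a
    maximal sequence of such frames.  Non-silent content is kept unchanged and
    in order.
    """
    if audio.n_samples == 0:
        raise ValueError("cannot truncate silences of empty audio")
    if max_pause <= 0:
        raise ValueError("max_pause must be positive")
    x = audio.samples
    frame = max(1, int(round(frame_dur * audio.fs)))
    n_frames = x.size // frame
    if n_frames == 0:
        return audio.replace(x.copy())
    ref = audio.rms
    if ref == 0:
        # all-silent audio: one run covering everything
        frame_rms = np.zeros(n_frames)
        thresh = 1.0
    else:
        frames = x[: n_frames * frame].reshape(n_frames, frame)
        frame_rms = np.sqrt(np.mean(frames**2, axis=1))
        thresh = ref * 10.0 ** (threshold_db / 20.0)
    silent = frame_rms < thresh

    keep = np.ones(x.size, dtype=bool)
    max_run = int(round(max_pause * audio.fs))
    i = 0
    n_truncated = 0
    while i < n_frames:
        if silent[i]:
            j = i
            while j < n_frames and silent[j]:
                j += 1
            start, stop = i * frame, j * frame
            if j == n_frames:
                stop = x.size  # trailing partial frame joins a final silent run
            if stop - start > max_run:
                keep[start + max_run : stop] = False
                n_truncated += 1
            i = j
        else:
            i += 1
    if n_truncated:
        logger.info(
            "truncated %d silent pause(s) > %.3g s (removed %.3f s)",
            n_truncated,
            max_pause,
            (x.size - keep.sum()) / audio.fs,
        )
    return audio.replace(x[keep])


def highpass_speech(
    audio: AudioStimulus,
    cutoff: float = 1000.0,
    order: int = 1,
    direction: str = "anticausal",
) -> AudioStimulus:
    """Gentle Butterworth high-pass of the stimulus (anti-causal by default).

    Stimulus-side filtering is anti-causal so that it cannot delay the
    regressor relative to the EEG, which would masquerade as shorter neural
    latencies.
    """
    y = butter_filter(audio.samples, audio.fs, cutoff, "highpass", order, direction)
    return audio.replace(y)


def normalize_rms(audio: AudioStimulus, rms_target: float | None = None) -> AudioStimulus:
    """Scale the waveform to the calibrated digital RMS (default 0.01)."""
    target = audio.rms_target if rms_target is None else rms_target
    current = audio.rms
    if current == 0:
        raise ValueError("cannot RMS-normalize all-zero audio")
    return audio.replace(audio.samples * (target / current))


def section_epochs(
    audio: AudioStimulus,
    epoch_dur: float = 64.0,
    fade_dur: float = 1.0,
    overlap_dur: float = 4.0,
) -> EpochedStimulus:
    """Cut audio into epochs of ``epoch_dur`` s that overlap by ``overlap_dur`` s.

    Each epoch advances the source by ``epoch_dur - overlap_dur`` seconds of
    novel material; raised-cosine fades of ``fade_dur`` s are applied to each
    epoch as presented.
    """
    if 2 * fade_dur > epoch_dur:
        raise ValueError("fades longer than the epoch")
    if overlap_dur >= epoch_dur:
        raise ValueError("overlap must be shorter than the epoch")
    n_epoch = int(round(epoch_dur * audio.fs))
    n_step = int(round((epoch_dur - overlap_dur) * audio.fs))
    if audio.n_samples < n_epoch:
        raise ValueError("audio shorter than one epoch")
    starts = range(0, audio.n_samples - n_epoch + 1, n_step)
    raw = [audio.replace(audio.samples[s : s + n_epoch].copy()) for s in starts]
    return EpochedStimulus(raw, epoch_dur, fade_dur, overlap_dur)


# ---------------------------------------------------------------------------
# click trains


def make_click_train(
    rate: float = 44.1,
    duration: float = 30.0,
    timing: str = "poisson",
    seed: int | np.random.Generator | None = None,
    fs_audio: float = 24414.0,
    click_width_samples: int = 2,
    polarity: str = "rarefaction",
) -> ClickTrain:
    """Draw a Poisson click train (exponential inter-click intervals) or build
    a periodic one with clicks at k/rate, k = 0..floor(rate*duration)-1."""
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if timing == "poisson":
        rng = np.random.default_rng(seed)
        # draw gaps in blocks until past the end; expected count = rate*duration
        times: list[np.ndarray] = []
        t = 0.0
        block = max(16, int(rate * duration * 1.2) + 32)
        while t < duration:
            gaps = rng.exponential(1.0 / rate, size=block)
            chunk = t + np.cumsum(gaps)
            times.append(chunk)
            t = chunk[-1]
        click_times = np.concatenate(times)
        click_times = click_times[click_times < duration]
    elif timing == "periodic":
        n = int(np.floor(rate * duration))
        click_times = np.arange(n) / rate
    else:
        raise ValueError("timing must be 'poisson' or 'periodic'")
    return ClickTrain(
        click_times, rate, duration, click_width_samples, fs_audio, polarity, timing
    )


def render_click_audio(
    train: ClickTrain,
    rms_target: float = DEFAULT_RMS_TARGET,
    spl_reference: float = DEFAULT_SPL_REFERENCE,
) -> AudioStimulus:
    """Render the train as audio of brief rectangular pulses.

    The pulse amplitude is sqrt(2) * ``rms_target`` — the peak of the 1-kHz
    calibration sinusoid — so clicks play at ``spl_reference`` dB
    peak-to-peak-equivalent SPL.  Overlapping clicks merge (amplitudes
    saturate rather than add).
    """
    if train.click_width_samples < 1:
        raise ValueError("click width must be at least one sample")
    n = int(round(train.duration * train.fs_audio))
    x = np.zeros(n)
    amp = np.sqrt(2.0) * rms_target
    if train.polarity == "rarefaction":
        amp = -amp
    idx = np.round(train.click_times * train.fs_audio).astype(int)
    for i in idx:
        x[i : i + train.click_width_samples] = amp
    return AudioStimulus(x, train.fs_audio, rms_target, spl_reference)


# ---------------------------------------------------------------------------
# regressors


def resample_audio(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling (identity when rates match)."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(100000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def _as_audio_list(audio) -> list[AudioStimulus]:
    if isinstance(audio, AudioStimulus):
        return [audio]
    if isinstance(audio, EpochedStimulus):
        return list(audio.epochs)
    return list(audio)


def make_regressor_speech(audio, fs_eeg: float = 10000.0) -> Regressor:
    """Half-wave rectify speech into dual-polarity branches at the EEG rate.

    Rectification happens at the audio rate; each branch is then anti-alias
    filtered and polyphase-resampled to ``fs_eeg``.  Resampling ripple can
    leave tiny negative values, which are clipped to zero (the regression
    assumes non-negative branches); the largest clipped magnitude is logged.
    """
    epochs = _as_audio_list(audio)
    if any(e.fs < fs_eeg for e in epochs):
        raise ValueError("fs_eeg must not exceed the audio sampling rate")
    pos_rows, neg_rows = [], []
    max_clip = 0.0
    for e in epochs:
        pos = np.maximum(e.samples, 0.0)
        neg = np.maximum(-e.samples, 0.0)
        pos_r = resample_audio(pos, e.fs, fs_eeg)
        neg_r = resample_audio(neg, e.fs, fs_eeg)
        max_clip = max(max_clip, float(-min(pos_r.min(), neg_r.min(), 0.0)))
        pos_rows.append(np.maximum(pos_r, 0.0))
        neg_rows.append(np.maximum(neg_r, 0.0))
    if max_clip > 0:
        logger.debug("clipped resampling ripple up to %.3g", max_clip)
    return Regressor(np.vstack(pos_rows), np.vstack(neg_rows), fs_eeg, "rectified_speech")


def downsample_signed_audio(audio, fs_eeg: float = 10000.0) -> np.ndarray:
    """Resample the signed (un-rectified) audio to the EEG rate.

    Used as the reference signal when estimating the electromagnetic
    leakage artifact.  Returns an (n_epochs, n_samples) array.
    """
    epochs = _as_audio_list(audio)
    rows = [resample_audio(e.samples, e.fs, fs_eeg) for e in epochs]
    return np.vstack(rows)


def make_regressor_clicks(
    train: ClickTrain | list[ClickTrain], fs_eeg: float = 10000.0
) -> Regressor:
    """Unit-height single-sample impulses at round(click_time * fs_eeg).

    No anti-alias filtering is applied (it would turn ideal impulses into
    ringing).  Rounding follows numpy's round-half-even rule; clicks that
    collide on one sample keep a single unit impulse (with a warning).
    """
    trains = train if isinstance(train, (list, tuple)) else [train]
    if fs_eeg <= 0:
        raise ValueError("fs_eeg must be positive")
    rows = []
    for tr in trains:
        n = int(round(tr.duration * fs_eeg))
        idx = np.round(tr.click_times * fs_eeg).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        uniq = np.unique(idx)
        if uniq.size < idx.size:
            logger.warning(
                "%d click(s) collided on the same EEG sample; kept unit impulses",
                idx.size - uniq.size,
            )
        row = np.zeros(n)
        row[uniq] = 1.0
        rows.append(row)
    return Regressor(np.vstack(rows), np.vstack(rows), fs_eeg, "impulse_train")
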