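"""File I/O: WAV audio, EEG recordings, regressors/epochs (HDF5), responses.

EEG loading accepts a BrainVision header/marker/binary triplet (read through
:mod:`mne`) or a plain fallback: a JSON sidecar naming the sampling rate,
amplitude unit and epoch-onset markers next to either a float32 binary or a
one-column TSV of potentials.  Amplitudes are converted to microvolts on
load; NaN anywhere is a hard error (artifact handling in this pipeline is the
excursion-zeroing step, never missing data).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .eeg import EegRecording
from .response import ResponseWaveform
from .stimuli import AudioStimulus, Regressor


def read_wav(path, rms_target: float = 0.01, spl_reference: float = 75.0) -> AudioStimulus:
    """Read a mono WAV file (PCM16/PCM32/float) to full-scale +/-1 floats."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(float)
    return AudioStimulus(data, float(fs), rms_target, spl_reference)


def write_wav(path, audio: AudioStimulus, dtype: str = "float32") -> None:
    """Write audio as float32 (sample-exact round trip) or PCM16."""
    if dtype == "float32":
        wavfile.write(path, int(round(audio.fs)), audio.samples.astype(np.float32))
    elif dtype == "int16":
        scaled = np.clip(audio.samples, -1.0, 1.0 - 1.0 / 32768) * 32768
        wavfile.write(path, int(round(audio.fs)), scaled.astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")


def load_eeg(path, unit_scale_to_uv: float | None = None) -> EegRecording:
    """Load a single-channel EEG recording with epoch-onset markers.

    ``.vhdr`` files go through mne; anything else must have a ``.json``
    sidecar (same stem) with keys ``fs``, ``markers`` and optionally
    ``unit_scale_to_uv`` (default 1.0), pointing at a float32 ``.dat`` binary
    or a one-column ``.tsv`` text file.
    """
    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        return _load_brainvision(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"no JSON sidecar {sidecar} for fallback EEG format")
    meta = json.loads(sidecar.read_text())
    scale = unit_scale_to_uv if unit_scale_to_uv is not None else meta.get("unit_scale_to_uv", 1.0)
    if path.suffix.lower() == ".tsv":
        potential = np.loadtxt(path)
    else:
        potential = np.fromfile(path, dtype=np.float32).astype(float)
    return EegRecording(
        potential * scale,
        float(meta["fs"]),
        np.asarray(meta.get("markers", []), dtype=int),
        meta.get("channel_label", "EEG"),
    )


def _load_brainvision(path: Path) -> EegRecording:
    import mne

    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data = raw.get_data()
    if data.shape[0] != 1:
        raise ValueError("expected a single-channel recording")
    potential = data[0] * 1e6  # mne loads volts
    markers = (raw.annotations.onset * raw.info["sfreq"]).round().astype(int)
    keep = [
        i for i, d in enumerate(raw.annotations.description)
        if d.startswith("Stimulus") or d.startswith("stim")
    ]
    markers = markers[keep] if keep else markers
    markers = markers[(markers >= 0) & (markers < potential.size)]
    return EegRecording(potential, float(raw.info["sfreq"]), np.sort(markers),
                        raw.ch_names[0])


def save_eeg_fallback(path, rec: EegRecording) -> None:
    """Write the plain fallback pair (.dat float32 + .json sidecar)."""
    path = Path(path)
    rec.potential.astype(np.float32).tofile(path)
    sidecar = {
        "fs": rec.fs,
        "markers": rec.markers.tolist(),
        "unit_scale_to_uv": 1.0,
        "channel_label": rec.channel_label,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def save_regressor(path, reg: Regressor) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("pos", data=reg.pos, compression="gzip")
        f.create_dataset("neg", data=reg.neg, compression="gzip")
        f.attrs["fs"] = reg.fs
        f.attrs["kind"] = reg.kind


def load_regressor(path) -> Regressor:
    import h5py

    with h5py.File(path, "r") as f:
        return Regressor(f["pos"][()], f["neg"][()], float(f.attrs["fs"]), str(f.attrs["kind"]))


def save_epochs(path, epochs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("rejection_mask", data=epochs.rejection_mask, compression="gzip")
        f.create_dataset("n_rejected", data=epochs.n_rejected)
        f.create_dataset("g_r", data=epochs.g_r)
        f.create_dataset("usable", data=epochs.usable)
        if epochs.onsets is not None:
            f.create_dataset("onsets", data=epochs.onsets)
        f.attrs["fs"] = epochs.fs


def load_epochs(path):
    import h5py

    from .eeg import EegEpochs

    with h5py.File(path, "r") as f:
        return EegEpochs(
            f["data"][()],
            float(f.attrs["fs"]),
            f["onsets"][()] if "onsets" in f else None,
            f["rejection_mask"][()].astype(bool),
            f["n_rejected"][()],
            f["g_r"][()],
            f["usable"][()].astype(bool),
        )


def write_response(path, resp: ResponseWaveform) -> None:
    """Two-column text (lag_ms, amplitude) plus a JSON provenance sidecar."""
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([resp.lags_ms, resp.amplitude]),
        delimiter="\t",
        header="lag_ms\tamplitude",
        comments="",
    )
    sidecar = {
        "fs": resp.fs,
        "n_pre": resp.n_pre,
        "normalized": resp.normalized,
        "provenance": _jsonable(resp.provenance),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_response(path) -> ResponseWaveform:
    path = Path(path)
    table = np.loadtxt(path, delimiter="\t", skiprows=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        return ResponseWaveform(
            table[:, 1], float(meta["fs"]), int(meta["n_pre"]),
            meta.get("provenance", {}), bool(meta.get("normalized", False)),
        )
    lags = table[:, 0]
    fs = 1000.0 / float(np.median(np.diff(lags)))
    n_pre = int(np.argmin(np.abs(lags)))
    return ResponseWaveform(table[:, 1], fs, n_pre)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
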