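"""File formats: EDF recordings, per-subject feature JSON, WAV audio, CSV tables.

EDF reading goes through MNE; a minimal 16-bit EDF writer is provided for
round-trip fixtures (the canonical clinical container has no writer in the
runtime stack).  The feature file is a UTF-8 JSON document with exact keys::

    {"subject_id": ..., "acquisition": {"fs", "window_s", "step_s"},
     "timestamps": [...],
     "regions": {"F-L": {"delta": [...], ..., "gamma": [...], "entropy": [...]}, ...}}

Numbers round-trip at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .montage import REGIONS, normalize_channel_name
from .spectral import BAND_NAMES, SubjectFeatures, WindowedFeatures
from .synthesis import AudioBuffer


class Recording:
    """Plain multichannel recording: samples (channels x time, µV), fs, names."""

    def __init__(self, samples, fs, channel_names, subject_id="subject"):
        self.samples = np.asarray(samples, float)
        self.fs = float(fs)
        self.channel_names = tuple(channel_names)
        self.subject_id = subject_id


# ---------------------------------------------------------------- EDF

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording, path) -> None:
    """Write a recording as 16-bit EDF (1-s data records, µV physical units).

    Trailing samples not filling a whole record are dropped.
    """
    x = np.asarray(recording.samples, float)
    fs = int(round(recording.fs))
    names = list(recording.channel_names)
    n_ch, n_samp = x.shape
    n_rec = n_samp // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    pm = max(1.0, float(np.ceil(np.max(np.abs(x)))))
    digital = np.round(x[:, : n_rec * fs] / pm * 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(getattr(recording, "subject_id", "X"), 80))
        fh.write(_pad("synthetic EEG", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for name in names:
            fh.write(_pad(name, 16))
        for _ in names:
            fh.write(_pad("", 80))
        for _ in names:
            fh.write(_pad("uV", 8))
        for _ in names:
            fh.write(_pad(f"{-pm:g}", 8))
        for _ in names:
            fh.write(_pad(f"{pm:g}", 8))
        for _ in names:
            fh.write(_pad("-32768", 8))
        for _ in names:
            fh.write(_pad("32767", 8))
        for _ in names:
            fh.write(_pad("", 80))
        for _ in names:
            fh.write(_pad(str(fs), 8))
        for _ in names:
            fh.write(_pad("", 32))
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def read_edf(path, require_channels: set[str] | None = None) -> Recording:
    """Read an EDF file into a Recording (µV), normalizing 10-20 channel labels."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = []
    keep = []
    for i, raw_name in enumerate(raw.ch_names):
        canonical = normalize_channel_name(raw_name)
        if canonical is not None:
            names.append(canonical)
            keep.append(i)
    if require_channels is not None:
        missing = sorted(require_channels - set(names))
        if missing:
            raise ValueError(f"EDF file is missing montage channels: {missing}")
    data = raw.get_data()[keep] * 1e6  # volts -> µV
    return Recording(data, raw.info["sfreq"], names, subject_id=Path(path).stem)


# ---------------------------------------------------------------- feature JSON

def write_features(features: SubjectFeatures, path) -> None:
    doc = {
        "subject_id": features.subject_id,
        "acquisition": {
            "fs": features.fs,
            "window_s": features.window_s,
            "step_s": features.step_s,
        },
        "timestamps": features.timestamps.tolist(),
        "regions": {
            code: {
                **{b: wf.rel_power[b].tolist() for b in BAND_NAMES},
                "entropy": wf.entropy.tolist(),
            }
            for code, wf in features.regions.items()
        },
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def _require(doc: dict, key: str, context: str = "top level"):
    if key not in doc:
        raise ValueError(f"feature file schema violation: missing key {key!r} at {context}")
    return doc[key]


def read_features(path) -> SubjectFeatures:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    subject_id = _require(doc, "subject_id")
    acq = _require(doc, "acquisition")
    for key in ("fs", "window_s", "step_s"):
        _require(acq, key, "acquisition")
    timestamps = np.asarray(_require(doc, "timestamps"), float)
    regions_doc = _require(doc, "regions")
    regions = {}
    for code in REGIONS:
        rdoc = _require(regions_doc, code, "regions")
        arrays = {}
        for key in (*BAND_NAMES, "entropy"):
            arr = np.asarray(_require(rdoc, key, f"regions.{code}"), float)
            if arr.shape != timestamps.shape:
                raise ValueError(
                    f"feature file schema violation: length mismatch at regions.{code}.{key}"
                )
            arrays[key] = arr
        regions[code] = WindowedFeatures(
            timestamps, {b: arrays[b] for b in BAND_NAMES}, arrays["entropy"]
        )
    return SubjectFeatures(
        subject_id=subject_id, fs=float(acq["fs"]),
        window_s=float(acq["window_s"]), step_s=float(acq["step_s"]),
        regions=regions,
    )


# ---------------------------------------------------------------- WAV

def write_wav(audio: AudioBuffer, path, bit_depth: int = 16) -> None:
    """Write mono WAV (16-bit PCM default, float32 optional); clipped input rejected."""
    x = np.asarray(audio.samples, float)
    if x.size and np.max(np.abs(x)) > 1.0:
        raise ValueError("samples exceed [-1, 1]; normalize before writing")
    if bit_depth == 16:
        wavfile.write(path, int(audio.fs), np.round(x * 32767).astype(np.int16))
    elif bit_depth == 32:
        wavfile.write(path, int(audio.fs), x.astype(np.float32))
    else:
        raise ValueError("bit_depth must be 16 (PCM) or 32 (float)")


def read_wav(path) -> AudioBuffer:
    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    else:
        samples = data.astype(float)
    return AudioBuffer(samples, float(fs))


# ---------------------------------------------------------------- CSV tables

def read_ratings_csv(path):
    """Ratings CSV -> RatingMatrix.

    Expected columns: subject_id, truth, then one column per evaluator; empty
    cells are missing ratings.
    """
    from .ratings import RatingMatrix

    table = pd.read_csv(path, dtype=str)
    for col in ("subject_id", "truth"):
        if col not in table.columns:
            raise ValueError(f"ratings file must have a {col!r} column")
    evaluators = [c for c in table.columns if c not in ("subject_id", "truth")]
    if not evaluators:
        raise ValueError("ratings file has no evaluator columns")
    ratings = table[evaluators].where(~table[evaluators].isna(), other=np.nan)
    ratings.index = table["subject_id"]
    return RatingMatrix(truth=table["truth"].tolist(), ratings=ratings)


def write_ratings_csv(matrix, path) -> None:
    out = matrix.ratings.copy()
    out.insert(0, "truth", matrix.truth)
    out.insert(0, "subject_id", matrix.ratings.index)
    out.to_csv(path, index=False)
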