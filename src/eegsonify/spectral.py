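"""Sliding-window spectral features of multichannel EEG.

For each 2-s window (1-s step) the power spectral density is estimated with
Welch's method and reduced to the five relative band powers P_b(i)
(delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz, normalized over
1-45 Hz) and the normalized spectral entropy H(i).  Channel spectra are
aggregated into 10 topographic regions by weighted averaging of PSDs before
feature reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import DEFAULT_MONTAGE, REGIONS, validate_montage

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi) Hz (upper edge inclusive for gamma)."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band edges {self.f_lo}, {self.f_hi}")


#: Canonical EEG bands.
CANONICAL_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Sliding-window analysis parameters.

    window_s/step_s give a 2-s window with 50% overlap by default.  Welch
    internals: 1-s Hann segments with 50% overlap, i.e. 3 averaged segments
    per window and 1 Hz resolution, which resolves the 1-Hz delta edge.
    """

    window_s: float = 2.0
    step_s: float = 1.0
    total_band: tuple[float, float] = (1.0, 45.0)
    welch_segment_s: float = 1.0
    welch_overlap: float = 0.5

    def __post_init__(self):
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must be in [0, 1)")
        if self.welch_segment_s > self.window_s:
            raise ValueError("welch segment longer than analysis window")


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.psd = np.asarray(self.psd, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")


@dataclass
class WindowedFeatures:
    """Per-window relative band powers and normalized spectral entropy."""

    timestamps: np.ndarray
    rel_power: dict[str, np.ndarray]
    entropy: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.timestamps)

    def frame(self, i: int) -> tuple[dict[str, float], float]:
        """(P_b, H) of window i, as consumed by the synthesis mapping."""
        return {b: float(self.rel_power[b][i]) for b in BAND_NAMES}, float(self.entropy[i])


@dataclass
class SubjectFeatures:
    """Per-region windowed features of one subject (in-memory twin of the feature file)."""

    subject_id: str
    fs: float
    window_s: float
    step_s: float
    regions: dict[str, WindowedFeatures] = field(default_factory=dict)

    @property
    def timestamps(self) -> np.ndarray:
        return next(iter(self.regions.values())).timestamps


def welch_psd(window_samples: np.ndarray, fs: float, cfg: AnalysisConfig = AnalysisConfig()) -> PowerSpectrum:
    """Welch PSD of one analysis window (Hann-tapered averaged periodograms)."""
    x = np.asarray(window_samples, float)
    nperseg = int(round(cfg.welch_segment_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError("window shorter than the Welch segment")
    freqs, psd = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * cfg.welch_overlap)),
    )
    return PowerSpectrum(freqs, psd)


def _band_mask(freqs: np.ndarray, band: BandDefinition, gamma_hi: float) -> np.ndarray:
    # half-open [lo, hi); the top band closes at its upper edge so the bands
    # tile the total range without double counting
    if band.f_hi >= gamma_hi:
        return (freqs >= band.f_lo) & (freqs <= band.f_hi)
    return (freqs >= band.f_lo) & (freqs < band.f_hi)


def relative_band_powers(
    spec: PowerSpectrum,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    total_band: tuple[float, float] = (1.0, 45.0),
) -> dict[str, float]:
    """P_b = power in band / power in total_band; fractions sum to 1."""
    lo, hi = total_band
    total_mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    total = float(spec.psd[total_mask].sum())
    if total <= 0:
        raise ValueError("degenerate window: zero power in the analysis band")
    return {
        b.name: float(spec.psd[_band_mask(spec.freqs, b, hi)].sum()) / total
        for b in bands
    }


def spectral_entropy(spec: PowerSpectrum, total_band: tuple[float, float] = (1.0, 45.0)) -> float:
    """Normalized Shannon entropy of the PSD restricted to total_band.

    H = -sum p_k ln p_k / ln K with p_k the normalized PSD over the K bins in
    the band; 0 for a single spectral line, 1 for a flat spectrum.
    """
    lo, hi = total_band
    mask = (spec.freqs >= lo) & (spec.freqs <= hi)
    p = spec.psd[mask]
    if p.size < 2:
        raise ValueError("need at least 2 bins inside total_band")
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate window: zero power in the analysis band")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


def window_starts(n_samples: int, fs: float, cfg: AnalysisConfig) -> np.ndarray:
    """Sample indices of window starts; trailing partial window dropped."""
    win = int(round(cfg.window_s * fs))
    step = int(round(cfg.step_s * fs))
    if n_samples < win:
        raise ValueError("signal shorter than one analysis window")
    n_win = (n_samples - win) // step + 1
    return np.arange(n_win) * step


def windowed_psds(channel: np.ndarray, fs: float, cfg: AnalysisConfig = AnalysisConfig()) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(timestamps, freqs, psds[n_windows, n_freqs]) for one channel."""
    x = np.asarray(channel, float)
    starts = window_starts(x.shape[-1], fs, cfg)
    win = int(round(cfg.window_s * fs))
    # strided view: all windows at once through scipy.welch's vectorized axis
    frames = np.stack([x[s:s + win] for s in starts])
    nperseg = int(round(cfg.welch_segment_s * fs))
    freqs, psds = signal.welch(
        frames, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * cfg.welch_overlap)), axis=-1,
    )
    return starts / fs, freqs, psds


def _features_from_psds(timestamps, freqs, psds, cfg) -> WindowedFeatures:
    rel = {b: np.empty(len(timestamps)) for b in BAND_NAMES}
    ent = np.empty(len(timestamps))
    for i in range(len(timestamps)):
        spec = PowerSpectrum(freqs, psds[i])
        powers = relative_band_powers(spec, CANONICAL_BANDS, cfg.total_band)
        for b in BAND_NAMES:
            rel[b][i] = powers[b]
        ent[i] = spectral_entropy(spec, cfg.total_band)
    return WindowedFeatures(np.asarray(timestamps, float), rel, ent)


def sliding_features(channel: np.ndarray, fs: float, cfg: AnalysisConfig = AnalysisConfig()) -> WindowedFeatures:
    """Relative band powers and entropy per sliding window of one channel."""
    timestamps, freqs, psds = windowed_psds(channel, fs, cfg)
    return _features_from_psds(timestamps, freqs, psds, cfg)


def aggregate_regions(
    per_channel_psds: dict[str, np.ndarray],
    freqs: np.ndarray,
    timestamps: np.ndarray,
    montage: dict[str, dict[str, float]] = DEFAULT_MONTAGE,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> dict[str, WindowedFeatures]:
    """Regional features from per-channel windowed PSDs.

    The regional spectrum of each window is the weighted mean of its member
    channels' PSDs (midline channels contribute 0.5 to each hemisphere);
    band powers and entropy are then computed from that mean spectrum.
    """
    validate_montage(montage)
    missing = sorted(
        {ch for members in montage.values() for ch in members} - set(per_channel_psds)
    )
    if missing:
        raise ValueError(f"channels missing from input: {missing}")
    out: dict[str, WindowedFeatures] = {}
    for region in REGIONS:
        members = montage[region]
        wsum = sum(members.values())
        mean_psd = sum(w * per_channel_psds[ch] for ch, w in members.items()) / wsum
        out[region] = _features_from_psds(timestamps, freqs, mean_psd, cfg)
    return out


def extract_subject(
    recording,
    cfg: AnalysisConfig = AnalysisConfig(),
    montage: dict[str, dict[str, float]] = DEFAULT_MONTAGE,
) -> SubjectFeatures:
    """Full feature extraction for one recording.

    ``recording`` needs ``samples`` (channels x time, µV), ``fs``,
    ``channel_names`` and optionally ``subject_id``.
    """
    names = list(recording.channel_names)
    needed = {ch for members in montage.values() for ch in members}
    missing = sorted(needed - set(names))
    if missing:
        raise ValueError(f"recording is missing montage channels: {missing}")
    per_channel: dict[str, np.ndarray] = {}
    timestamps = freqs = None
    for ch in sorted(needed):
        x = np.asarray(recording.samples)[names.index(ch)]
        timestamps, freqs, psds = windowed_psds(x, recording.fs, cfg)
        per_channel[ch] = psds
    regions = aggregate_regions(per_channel, freqs, timestamps, montage, cfg)
    return SubjectFeatures(
        subject_id=getattr(recording, "subject_id", "subject"),
        fs=float(recording.fs), window_s=cfg.window_s, step_s=cfg.step_s,
        regions=regions,
    )
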