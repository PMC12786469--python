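"""Seeded synthetic EEG cohorts and evaluator rating matrices.

Recordings emulate 19-channel, 500-Hz resting EEG with an exactly controlled
relative band-power profile: each channel sums five band-limited noise
components (4th-order Butterworth band-pass on white noise) whose variances
solve a measured leakage system, so the powers the feature extractor reads
back match the profile weights.  A fixed topographic template (frontal
delta/theta, posterior alpha, central beta, mild left/right asymmetry)
shapes per-channel profiles around the subject's global one, and organized
rhythms (a concentrated, globally waxing-and-waning posterior alpha in the
control profile) carry the entropy structure of healthy EEG.  The "AD-like"
profile shifts power toward delta/theta and flattens the spectrum, the
spectral-slowing signature the sonification is designed to expose.

Seeding is hierarchical: one global seed expands to per-subject, per-channel,
per-band substreams, so adding or removing subjects does not perturb the
others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import CHANNELS_1020
from .spectral import BAND_NAMES, CANONICAL_BANDS

#: Floor applied when jitter would drive a band weight negative.
WEIGHT_FLOOR = 0.01

#: Directional group profiles: AD-like shows elevated slow-band (delta/theta)
#: power, reduced fast-band power, and a flattened (higher-entropy) spectrum.
#: The control-like group carries a concentrated posterior-alpha rhythm — the
#: sharp ~10 Hz peak of healthy eyes-closed resting EEG — which is what gives
#: controls their lower spectral entropy; in the AD-like profile that rhythm
#: is dissolved into band-flat noise (spectral slowing and disorganization).
#: Magnitudes are plausible stand-ins, not estimates of any real cohort.
AD_PROFILE_WEIGHTS = {"delta": 0.30, "theta": 0.30, "alpha": 0.15, "beta": 0.15, "gamma": 0.10}
CONTROL_PROFILE_WEIGHTS = {"delta": 0.20, "theta": 0.15, "alpha": 0.30, "beta": 0.22, "gamma": 0.13}
CONTROL_ALPHA_CONCENTRATION = 0.9


@dataclass(frozen=True)
class SpectralProfile:
    """Target relative band powers and entropy level of a synthetic group.

    ``band_concentration`` controls how much of a band's power sits in a
    narrow rhythm at the band center instead of spreading flat across the
    band (0 = flat, toward 1 = a sharp spectral peak).  Concentration is how
    the generator shapes spectral entropy: organized rhythms (a healthy
    posterior alpha peak) lower it, band-flat noise raises it.
    """

    band_weights: dict[str, float]
    entropy_level: float
    label: str
    band_concentration: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BAND_NAMES}
    )
    broadband_floor: float = 0.0

    def __post_init__(self):
        if set(self.band_weights) != set(BAND_NAMES):
            raise ValueError(f"band_weights must have exactly the bands {BAND_NAMES}")
        if abs(sum(self.band_weights.values()) - 1.0) > 1e-9:
            raise ValueError("band weights must sum to 1")
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band weights must be non-negative")
        if not 0 <= self.entropy_level <= 1:
            raise ValueError("entropy_level must be in [0, 1]")
        if any(not 0 <= c < 1 for c in self.band_concentration.values()):
            raise ValueError("band_concentration values must be in [0, 1)")
        if not 0 <= self.broadband_floor < 1:
            raise ValueError("broadband_floor must be in [0, 1)")


#: Analysis bins per band at 1-Hz resolution, and each band's center bin.
_BAND_BINS = {"delta": 3, "theta": 4, "alpha": 5, "beta": 17, "gamma": 16}
_CENTER_BIN = {"delta": 2, "theta": 6, "alpha": 10, "beta": 21, "gamma": 37}


def _profile_entropy(
    weights: dict[str, float],
    concentration: dict[str, float] | None = None,
    broadband_floor: float = 0.0,
) -> float:
    """Bin-level spectral entropy implied by a profile at 1 Hz resolution."""
    concentration = concentration or {b: 0.0 for b in BAND_NAMES}
    parts = []
    for b in BAND_NAMES:
        k = _BAND_BINS[b]
        c = concentration.get(b, 0.0)
        bins = np.full(k, (1.0 - c) * weights[b] / k)
        bins[k // 2] += c * weights[b]
        parts.append(bins)
    p = np.concatenate(parts)
    n_bins = p.size
    p = (1.0 - broadband_floor) * p + broadband_floor / n_bins
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n_bins))


def ad_profile() -> SpectralProfile:
    return SpectralProfile(dict(AD_PROFILE_WEIGHTS), _profile_entropy(AD_PROFILE_WEIGHTS), "AD")


def control_profile() -> SpectralProfile:
    conc = {b: 0.0 for b in BAND_NAMES}
    conc["alpha"] = CONTROL_ALPHA_CONCENTRATION
    return SpectralProfile(
        dict(CONTROL_PROFILE_WEIGHTS),
        _profile_entropy(CONTROL_PROFILE_WEIGHTS, conc),
        "control",
        band_concentration=conc,
    )


@dataclass
class SyntheticRecording:
    samples: np.ndarray          # channels x time, µV
    fs: float
    channel_names: tuple[str, ...]
    profile: SpectralProfile
    seed: int
    subject_id: str = "subject"


#: Fixed topographic template: per-band multiplicative deviation of each
#: channel's relative power from the subject's global profile (anterior
#: delta/theta dominance, posterior alpha dominance, central beta — the
#: textbook scalp distribution of resting rhythms).  Deviations are centered
#: so the scalp-mean relative powers still equal the profile weights.
_ANTERIOR = {"Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"}
_POSTERIOR = {"P3", "P4", "Pz", "T5", "T6", "O1", "O2"}

def _topo_pattern() -> dict[str, np.ndarray]:
    raw = {"delta": (0.45, 0.0, -0.45), "theta": (0.35, 0.1, -0.35),
           "alpha": (-0.55, -0.25, 0.8), "beta": (-0.15, 0.3, -0.15),
           "gamma": (0.0, 0.0, 0.0)}
    # mild hemispheric asymmetry (alternating direction across bands so the
    # scalp stays balanced); separates homologous regions' band powers the
    # way real recordings do
    lr = {"delta": 0.15, "theta": -0.18, "alpha": 0.12, "beta": -0.12, "gamma": 0.10}
    # channels are weighted by their total exposure across the 10 regions
    # (posterior channels populate more regions), so that the mean of the 10
    # regional relative-power profiles equals the subject's global profile
    from .montage import DEFAULT_MONTAGE
    expo = {ch: 0.0 for ch in CHANNELS_1020}
    for members in DEFAULT_MONTAGE.values():
        total = sum(members.values())
        for ch, wt in members.items():
            expo[ch] += wt / total
    u = np.array([expo[ch] for ch in CHANNELS_1020])
    u = u / u.sum()
    left = {"Fp1", "F3", "F7", "C3", "P3", "O1", "T3", "T5"}
    right = {"Fp2", "F4", "F8", "C4", "P4", "O2", "T4", "T6"}
    out = {}
    for b, (ant, cen, post) in raw.items():
        d = np.array([
            ant if ch in _ANTERIOR else post if ch in _POSTERIOR else cen
            for ch in CHANNELS_1020
        ])
        d = d + np.array([
            lr[b] if ch in left else -lr[b] if ch in right else 0.0
            for ch in CHANNELS_1020
        ])
        out[b] = d - (u * d).sum()
    return out

_TOPOGRAPHY = _topo_pattern()


def _channel_weight_targets(weights: dict[str, float], spread: float = 1.0) -> np.ndarray:
    """Per-channel relative-power targets (n_channels x n_bands).

    Each channel's targets sum to 1 and the scalp mean equals ``weights``.
    """
    w = np.array([weights[b] for b in BAND_NAMES])
    d = np.stack([_TOPOGRAPHY[b] for b in BAND_NAMES], axis=1)  # ch x band
    c = d @ w  # per-channel weighted mean deviation
    p = w[None, :] * (1.0 + spread * (d - c[:, None]))
    p = np.maximum(p, 0.005)
    return p / p.sum(axis=1, keepdims=True)


#: Spectral-analysis bin width the generator calibrates against (1-s Welch
#: segments -> 1 Hz bins centered on integer frequencies).  Pass-band edges
#: are shifted down by half a bin so that, e.g., delta noise occupies
#: 0.5-3.5 Hz — exactly the support of the analysis bins at 1, 2 and 3 Hz —
#: and band-power recovery is unbiased.
ANALYSIS_BIN_HZ = 1.0


def _bandpass_noise(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _rhythm_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow positive amplitude envelope emulating the waxing and waning of an
    organized cortical rhythm (timescale of seconds), unit RMS."""
    sos = signal.butter(2, [0.05, 0.4], btype="bandpass", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, rng.standard_normal(n))
    # fix the realized modulation depth: every subject's rhythm waxes and
    # wanes fully, only the tempo and phase pattern vary with the seed
    slow = slow / np.sqrt((slow ** 2).mean())
    env = np.maximum(1.0 + 0.95 * slow, 0.02)
    return env / np.sqrt((env ** 2).mean())


def _band_noise(
    n: int,
    band,
    fs: float,
    rng: np.random.Generator,
    concentration: float = 0.0,
    envelope: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-variance noise for one band.

    A fraction (1 - concentration) spreads flat across the band's analysis
    bins; the rest forms a narrow rhythm one bin wide at the band center,
    optionally amplitude-modulated by a shared slow envelope (healthy rhythms
    wax and wane coherently across the scalp).
    """
    half = ANALYSIS_BIN_HZ / 2.0
    lo = max(band.f_lo - half, 0.1)
    hi = band.f_hi - half
    flat = _bandpass_noise(n, lo, hi, fs, rng)
    if concentration <= 0:
        return flat
    center = _CENTER_BIN[band.name]
    narrow = _bandpass_noise(n, center - half, center + half, fs, rng)
    out = np.sqrt(1.0 - concentration) * flat + np.sqrt(concentration) * narrow
    if envelope is not None:
        out = out * envelope
        out = out / out.std()
    return out


def _mix_to_weights(comps: np.ndarray, weights: np.ndarray, fs: float) -> np.ndarray:
    """Scale band components so *measured* relative band powers hit the targets.

    Band-limited noise leaks a few percent of its power into neighbouring
    analysis bins (filter roll-off plus Hann leakage), which would bias naive
    variance scaling.  Each component's band allocation is therefore measured
    with the same Welch analysis the feature extractor uses, and the component
    variances solve the resulting 5x5 leakage system exactly.
    """
    nperseg = int(round(ANALYSIS_BIN_HZ ** -1 * fs))
    freqs, psds = signal.welch(comps, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    alloc = np.stack([
        [psds[bi][(freqs >= b.f_lo) & ((freqs < b.f_hi) if b.f_hi < 45 else (freqs <= b.f_hi))].sum()
         for bi in range(len(CANONICAL_BANDS))]
        for b in CANONICAL_BANDS
    ])  # alloc[target_band, component]: band power per unit component variance
    var = np.linalg.solve(alloc, weights)
    var = np.maximum(var, 0.0)
    return (np.sqrt(var)[:, None] * comps).sum(axis=0)


def generate_recording(
    profile: SpectralProfile,
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
    subject_id: str = "subject",
    _subject_key: int = 0,
) -> SyntheticRecording:
    """One 19-channel recording whose relative band powers match the profile."""
    if duration_s < 4:
        raise ValueError("duration_s must be at least 4 s (two analysis windows)")
    if fs < 200:
        raise ValueError("fs must be at least 200 Hz")
    n = int(round(duration_s * fs))
    targets = _channel_weight_targets(profile.band_weights)
    # one slow envelope per subject: rhythm amplitude co-modulates across the
    # whole scalp, as the posterior dominant rhythm does
    envelope = _rhythm_envelope(n, fs, np.random.default_rng([seed, _subject_key, 30_000]))
    samples = np.empty((len(CHANNELS_1020), n))
    for ci in range(len(CHANNELS_1020)):
        comps = np.stack([
            _band_noise(
                n, band, fs, np.random.default_rng([seed, _subject_key, ci, bi]),
                concentration=profile.band_concentration.get(band.name, 0.0),
                envelope=envelope,
            )
            for bi, band in enumerate(CANONICAL_BANDS)
        ])
        samples[ci] = 10.0 * _mix_to_weights(comps, targets[ci], fs)  # ~10 µV RMS
    return SyntheticRecording(samples, fs, CHANNELS_1020, profile, seed, subject_id)


def _jittered_weights(base: dict[str, float], jitter: float, rng: np.random.Generator) -> dict[str, float]:
    w = np.array([base[b] for b in BAND_NAMES])
    w = w * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=w.size))
    if np.any(w < WEIGHT_FLOOR):
        warnings.warn("jitter drove a band weight below the floor; clipping", stacklevel=3)
        w = np.maximum(w, WEIGHT_FLOOR)
    w = w / w.sum()
    return dict(zip(BAND_NAMES, w.tolist()))


def generate_cohort(
    n_ad: int,
    n_control: int,
    duration_s: float = 60.0,
    fs: float = 500.0,
    seed: int = 0,
    jitter: float = 0.1,
) -> list[SyntheticRecording]:
    """A two-group cohort; per-subject weights are the group profile plus seeded jitter."""
    if n_ad < 1 or n_control < 1:
        raise ValueError("need at least one subject per group")
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must be in [0, 0.5)")
    cohort = []
    groups = [("AD", ad_profile())] * n_ad + [("control", control_profile())] * n_control
    for idx, (label, base) in enumerate(groups):
        rng = np.random.default_rng([seed, idx, 10_000])
        weights = _jittered_weights(base.band_weights, jitter, rng)
        profile = SpectralProfile(
            weights,
            _profile_entropy(weights, base.band_concentration),
            label,
            band_concentration=dict(base.band_concentration),
        )
        sid = f"sub-{idx:03d}-{label}"
        cohort.append(
            generate_recording(profile, duration_s, fs, seed, subject_id=sid, _subject_key=idx)
        )
    return cohort


def cohort_manifest(cohort: list[SyntheticRecording]) -> pd.DataFrame:
    """Tabular summary of a cohort (id, group, seed, band weights)."""
    rows = []
    for rec in cohort:
        row = {"subject_id": rec.subject_id, "group": rec.profile.label, "seed": rec.seed}
        row.update({f"w_{b}": rec.profile.band_weights[b] for b in BAND_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_rating_matrix(
    truth: list[str],
    evaluator_accuracies: list[float],
    seed: int = 0,
    labels: tuple[str, str] = ("AD", "control"),
):
    """Simulated evaluator panel: each rating is correct with the evaluator's accuracy.

    Returns a :class:`eegsonify.ratings.RatingMatrix`.
    """
    from .ratings import RatingMatrix

    if len(truth) == 0:
        raise ValueError("truth must be non-empty")
    if any(not 0 <= a <= 1 for a in evaluator_accuracies):
        raise ValueError("accuracies must be in [0, 1]")
    truth = list(truth)
    flipped = {labels[0]: labels[1], labels[1]: labels[0]}
    cols = {}
    for e, acc in enumerate(evaluator_accuracies):
        rng = np.random.default_rng([seed, e, 20_000])
        correct = rng.random(len(truth)) < acc
        cols[f"evaluator_{e + 1}"] = [
            t if c else flipped[t] for t, c in zip(truth, correct)
        ]
    ratings = pd.DataFrame(cols, index=[f"sub-{i:03d}" for i in range(len(truth))])
    return RatingMatrix(truth=truth, ratings=ratings)
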