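"""Offline parametric synthesis: feature-to-parameter mapping and rendering.

Every window of regional EEG features (five relative band powers P_b and the
normalized spectral entropy H) is mapped to synthesis parameters:

* delta  -> sine oscillator, f = 45 + 50 P_delta Hz
* theta  -> sine oscillator, f = 90 + 80 P_theta Hz
* alpha  -> triangle oscillator, f = 180 + 160 P_alpha Hz, random micro-detune
  drawn uniformly in +-(6 + 14 H) cents per window
* beta   -> pink noise, 600 Hz high-pass, tremolo at 3 + 14 P_beta Hz
* gamma  -> white noise, 2 kHz high-pass, tremolo at 5 + 20 P_gamma Hz
* gains g_b = P_b^0.85 (perceptual compression)
* entropy drives the clean/bit-crushed crossfade (fade = 0.15 + 0.85 H),
  the tremolo depths (d_beta = 0.1 + 0.8 H, d_gamma = 0.15 + 0.8 H) and the
  regional resonance quality factor (Q = 1 + 10 (1 - H), center 1000 Hz),
  realized as a peaking-EQ bell whose prominence and narrowness grow with Q.

Parameters advance once per window (1 s) and are smoothed by 80-ms
exponential-approach ramps so transitions are click-free.  Rendering is
deterministic given a seed and fixed at 48 kHz mono.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .montage import REGIONS
from .spectral import BAND_NAMES, SubjectFeatures, WindowedFeatures

#: RMS of a unit-amplitude sine; the tonal sources' reference level.
_UNIT_LEVEL = 2.0 ** -0.5

#: Noise sources (beta pink, gamma white) enter the mix 6 dB above the tonal
#: reference.  Broadband noise at equal RMS is perceptually much quieter than
#: a pure tone, and the reference energy balance of rendered sonifications
#: (roughly a third of total energy above 2 kHz) implies a noise-forward mix.
_NOISE_MULT = 2.0


@dataclass(frozen=True)
class MappingConstants:
    """All constants of the feature-to-synthesis mapping (reference defaults of the method)."""

    delta_f: tuple[float, float] = (45.0, 50.0)      # base, span (Hz)
    theta_f: tuple[float, float] = (90.0, 80.0)
    alpha_f: tuple[float, float] = (180.0, 160.0)
    alpha_detune: tuple[float, float] = (6.0, 14.0)  # cents
    beta_trem: tuple[float, float] = (3.0, 14.0)     # Hz
    gamma_trem: tuple[float, float] = (5.0, 20.0)
    gain_exponent: float = 0.85
    q: tuple[float, float] = (1.0, 10.0)
    fade: tuple[float, float] = (0.15, 0.85)
    d_beta: tuple[float, float] = (0.1, 0.8)
    d_gamma: tuple[float, float] = (0.15, 0.8)
    beta_hp_cut: float = 600.0                       # Hz
    gamma_hp_cut: float = 2000.0
    region_bp_center: float = 1000.0
    bit_depth: int = 4
    ramp_s: float = 0.08
    focus_gain_db: float = -6.0
    nonfocus_gain_db: float = -24.0


@dataclass
class SynthFrameParams:
    """Mapped synthesis parameters of one analysis window."""

    f_delta: float
    f_theta: float
    f_alpha: float
    detune_alpha: float
    trem_rate_beta: float
    trem_rate_gamma: float
    trem_depth_beta: float
    trem_depth_gamma: float
    gains: dict[str, float]
    q_factor: float
    fade: float


@dataclass
class AudioBuffer:
    """Mono audio samples in [-1, 1] at a fixed sampling rate."""

    samples: np.ndarray
    fs: float = 48000.0

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def map_frame(
    P: dict[str, float],
    H: float,
    consts: MappingConstants = MappingConstants(),
    rng: np.random.Generator | None = None,
) -> SynthFrameParams:
    """Apply the mapping equations to one window's (P_b, H)."""
    for b in BAND_NAMES:
        if not 0.0 <= P[b] <= 1.0:
            raise ValueError(f"relative power {b}={P[b]} outside [0, 1]")
    if not 0.0 <= H <= 1.0:
        raise ValueError(f"entropy {H} outside [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    detune_span = consts.alpha_detune[0] + consts.alpha_detune[1] * H
    return SynthFrameParams(
        f_delta=consts.delta_f[0] + consts.delta_f[1] * P["delta"],
        f_theta=consts.theta_f[0] + consts.theta_f[1] * P["theta"],
        f_alpha=consts.alpha_f[0] + consts.alpha_f[1] * P["alpha"],
        detune_alpha=float(rng.uniform(-detune_span, detune_span)),
        trem_rate_beta=consts.beta_trem[0] + consts.beta_trem[1] * P["beta"],
        trem_rate_gamma=consts.gamma_trem[0] + consts.gamma_trem[1] * P["gamma"],
        trem_depth_beta=consts.d_beta[0] + consts.d_beta[1] * H,
        trem_depth_gamma=consts.d_gamma[0] + consts.d_gamma[1] * H,
        gains={b: P[b] ** consts.gain_exponent for b in BAND_NAMES},
        q_factor=consts.q[0] + consts.q[1] * (1.0 - H),
        fade=consts.fade[0] + consts.fade[1] * H,
    )


def _phase_frac(freq_track: np.ndarray, fs: float) -> np.ndarray:
    """Fractional cycle phase from a frequency track.

    Accumulated in float64 (phase counts tens of thousands of cycles over a
    render) and wrapped to [0, 1) before the cheap float32 waveform math.
    """
    phase = np.cumsum(freq_track, dtype=np.float64)
    phase /= fs
    whole = np.floor(phase)
    np.subtract(phase, whole, out=phase)
    return phase.astype(np.float32)


def osc_sine(freq_track: np.ndarray, fs: float) -> np.ndarray:
    """Phase-continuous unit-amplitude sine following a per-sample frequency track."""
    freq_track = np.asarray(freq_track, float)
    if freq_track.size == 0:
        return np.empty(0, np.float32)
    return np.sin(np.float32(2.0 * np.pi) * _phase_frac(freq_track, fs))


def osc_triangle(freq_track: np.ndarray, detune_cents_track: np.ndarray, fs: float) -> np.ndarray:
    """Phase-continuous triangle; effective frequency f * 2^(cents/1200)."""
    freq_track = np.asarray(freq_track, float)
    if freq_track.size == 0:
        return np.empty(0, np.float32)
    f_eff = freq_track * 2.0 ** (np.asarray(detune_cents_track, float) / 1200.0)
    frac = _phase_frac(f_eff, fs)
    # rising 0->1 over the first half cycle, falling back over the second
    return np.where(
        frac < 0.5,
        np.float32(4.0) * frac - np.float32(1.0),
        np.float32(3.0) - np.float32(4.0) * frac,
    )


def noise_pink(n_samples: int, fs: float, rng: np.random.Generator, n_rows: int = 16) -> np.ndarray:
    """Pink (1/f) noise via the Voss-McCartney multi-rate sum, unit variance."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out = np.zeros(n_samples, np.float32)
    for k in range(n_rows):
        hold = 2 ** k
        m = -(-n_samples // hold)  # ceil
        out += np.repeat(rng.standard_normal(m).astype(np.float32), hold)[:n_samples]
    return out / np.float32(np.sqrt(n_rows))


def apply_tremolo(x: np.ndarray, rate_track: np.ndarray, depth_track: np.ndarray, fs: float) -> np.ndarray:
    """Sinusoidal amplitude modulation; gain oscillates in [1 - d, 1]."""
    depth_track = np.asarray(depth_track)
    if np.any((depth_track < 0) | (depth_track > 1)):
        raise ValueError("tremolo depth must be in [0, 1]")
    lfo = np.sin(np.float32(2.0 * np.pi) * _phase_frac(np.asarray(rate_track, float), fs))
    gain = 1.0 - depth_track * (1.0 + lfo) / 2.0
    return np.asarray(x) * gain


def bitcrush(x: np.ndarray, bits: int = 4) -> np.ndarray:
    """Uniform mid-tread quantization to 2^bits levels over [-1, 1]."""
    if bits < 1:
        raise ValueError("bits must be >= 1")
    x = np.asarray(x)
    scale = x.dtype.type(2.0 ** (bits - 1)) if x.dtype.kind == "f" else 2.0 ** (bits - 1)
    return np.clip(np.round(x * scale) / scale, -1.0, 1.0)


def crossfade(clean: np.ndarray, crushed: np.ndarray, fade_track: np.ndarray) -> np.ndarray:
    """Equal-power crossfade: cos(fade*pi/2)*clean + sin(fade*pi/2)*crushed."""
    clean = np.asarray(clean)
    crushed = np.asarray(crushed)
    if clean.shape != crushed.shape:
        raise ValueError("clean and crushed must have equal length")
    theta = np.asarray(fade_track) * (np.pi / 2.0)
    if clean.dtype == np.float32:
        theta = theta.astype(np.float32)
    return np.cos(theta) * clean + np.sin(theta) * crushed


def ramp_track(
    values_per_window: np.ndarray,
    window_step_s: float,
    ramp_s: float,
    fs: float,
    dtype=np.float64,
) -> np.ndarray:
    """Per-sample parameter track with exponential-approach ramps at window boundaries.

    The track reaches within 1% of each new target by ``ramp_s`` (time constant
    ramp_s / ln 100) and each ramp starts from the current value, so the track
    is continuous.  The first window starts directly at its value.
    """
    if ramp_s <= 0:
        raise ValueError("ramp_s must be positive")
    if ramp_s >= window_step_s:
        raise ValueError("ramp_s must be shorter than the window step")
    values = np.atleast_1d(np.asarray(values_per_window, float))
    step_n = int(round(window_step_s * fs))
    tau = ramp_s / np.log(100.0)
    # the transient is numerically dead after ~30 time constants
    cut = min(step_n, int(np.ceil(fs * tau * 30.0)))
    decay = np.exp(-np.arange(1, cut + 1) / (fs * tau))
    d_end = decay[-1] if cut == step_n else 0.0
    # start-of-block values follow a scalar recurrence; blocks then broadcast
    starts = np.empty(values.size)
    current = values[0]
    for i, target in enumerate(values):
        starts[i] = current
        current = target + (current - target) * d_end
    out = np.repeat(values.astype(dtype), step_n).reshape(values.size, step_n)
    out[:, :cut] += ((starts - values)[:, None] * decay[None, :]).astype(dtype)
    return out.reshape(-1)


def _highpass(x: np.ndarray, cut_hz: float, fs: float) -> np.ndarray:
    sos = signal.butter(2, cut_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfilt(sos, x)


def _peaking_eq(center_hz: float, q: float, gain_db: float, fs: float):
    """RBJ-cookbook peaking-EQ biquad: unity gain far from center, a resonant
    bell of ``gain_db`` at the center whose width narrows with Q."""
    A = 10.0 ** (gain_db / 40.0)
    w0 = 2.0 * np.pi * center_hz / fs
    alpha = np.sin(w0) / (2.0 * q)
    cw = np.cos(w0)
    b = np.array([1.0 + alpha * A, -2.0 * cw, 1.0 - alpha * A])
    a = np.array([1.0 + alpha / A, -2.0 * cw, 1.0 - alpha / A])
    return b / a[0], a / a[0]


def _regional_filter(
    x: np.ndarray,
    q_track: np.ndarray,
    fs: float,
    center_hz: float,
    step_n: int,
    ramp_n: int,
) -> np.ndarray:
    """Entropy-driven resonant coloration at the regional center frequency.

    Realized as a peaking EQ whose boost (in dB) equals the mapped Q, so low
    spectral entropy yields a prominent, narrow 1-kHz resonance and high
    entropy leaves the spectrum nearly untouched.  Coefficients are
    piecewise-constant: refreshed at each window boundary and at
    quarter-points of the 80-ms ramp, tracking the ramped Q; filter state is
    carried across blocks so the output is continuous.
    """
    n = x.size
    sub = max(1, ramp_n // 4)
    edges = []
    start = 0
    while start < n:
        for off in (0, sub, 2 * sub, 3 * sub, 4 * sub):
            if start + off < min(start + step_n, n):
                edges.append(start + off)
        start += step_n
    edges.append(n)
    y = np.empty_like(x)
    zi = np.zeros(2)
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        q = float(q_track[lo])
        b, a = _peaking_eq(center_hz, q, gain_db=q, fs=fs)
        y[lo:hi], zi = signal.lfilter(b, a, x[lo:hi], zi=zi)
    return y


def _infer_step(features: WindowedFeatures, step_s: float | None) -> float:
    if step_s is not None:
        return step_s
    ts = features.timestamps
    return float(ts[1] - ts[0]) if len(ts) > 1 else 1.0


def render_region(
    features: WindowedFeatures,
    consts: MappingConstants = MappingConstants(),
    fs: float = 48000.0,
    seed: int = 0,
    step_s: float | None = None,
) -> AudioBuffer:
    """Render one region's feature time series through the full signal chain."""
    n_win = features.n_windows
    if n_win < 1:
        raise ValueError("need at least one feature window")
    step_s = _infer_step(features, step_s)
    step_n = int(round(step_s * fs))
    n = n_win * step_n
    ramp_n = int(round(consts.ramp_s * fs))

    rng_detune = np.random.default_rng([seed, 0])
    rng_pink = np.random.default_rng([seed, 1])
    rng_white = np.random.default_rng([seed, 2])

    frames = [
        map_frame(*features.frame(i), consts=consts, rng=rng_detune)
        for i in range(n_win)
    ]

    def track(getter):
        return ramp_track(
            [getter(f) for f in frames], step_s, consts.ramp_s, fs, dtype=np.float32
        )

    f_d = track(lambda f: f.f_delta)
    f_t = track(lambda f: f.f_theta)
    f_a = track(lambda f: f.f_alpha)
    det = track(lambda f: f.detune_alpha)
    gains = {b: track(lambda f, b=b: f.gains[b]) for b in BAND_NAMES}
    tr_b = track(lambda f: f.trem_rate_beta)
    tr_g = track(lambda f: f.trem_rate_gamma)
    td_b = track(lambda f: f.trem_depth_beta)
    td_g = track(lambda f: f.trem_depth_gamma)
    fade = track(lambda f: f.fade)
    q_tr = track(lambda f: f.q_factor)

    level = np.float32(_UNIT_LEVEL * _NOISE_MULT)
    sine_d = osc_sine(f_d, fs)
    sine_t = osc_sine(f_t, fs)
    tri_a = osc_triangle(f_a, det, fs)
    # rows slower than ~190 Hz sit >40 dB under the 600-Hz high-pass and
    # are omitted from the render's pink source
    pink = apply_tremolo(
        _highpass(level * noise_pink(n, fs, rng_pink, n_rows=8), consts.beta_hp_cut, fs),
        tr_b, td_b, fs,
    )
    white = apply_tremolo(
        _highpass(level * rng_white.standard_normal(n).astype(np.float32),
                  consts.gamma_hp_cut, fs),
        tr_g, td_g, fs,
    )

    mix = (
        gains["delta"] * sine_d
        + gains["theta"] * sine_t
        + gains["alpha"] * tri_a
        + gains["beta"] * pink
        + gains["gamma"] * white
    )
    # quantize relative to the regional bus's own full scale, as a digital
    # bit-depth reduction does; the distortion level then tracks the signal
    # level instead of exploding for quiet mixes
    peak = float(np.max(np.abs(mix)))
    if peak > 0:
        crushed = bitcrush(mix / np.float32(peak), consts.bit_depth) * np.float32(peak)
    else:
        crushed = mix
    blended = crossfade(mix, crushed, fade)
    out = _regional_filter(
        blended, q_tr, fs, consts.region_bp_center, step_n, ramp_n
    )
    return AudioBuffer(out, fs)


def _region_seed(seed: int, region_index: int) -> int:
    return int(np.random.SeedSequence([seed, region_index]).generate_state(1)[0] % (2 ** 31))


def render_subject(
    subject: SubjectFeatures,
    focus_region: str = "all",
    consts: MappingConstants = MappingConstants(),
    fs: float = 48000.0,
    seed: int = 0,
) -> AudioBuffer:
    """Mix the 10 regional renders with focus gains into the master output.

    The focused region plays at -6 dB, all others at -24 dB; with
    ``focus_region="all"`` every region plays at -6 dB.  The master is peak
    normalized to -1 dBFS only if the mix would clip.
    """
    if focus_region != "all" and focus_region not in REGIONS:
        raise ValueError(f"unknown region {focus_region!r}")
    g_focus = 10.0 ** (consts.focus_gain_db / 20.0)
    g_other = 10.0 ** (consts.nonfocus_gain_db / 20.0)
    total = None
    for ri, region in enumerate(REGIONS):
        buf = render_region(
            subject.regions[region], consts, fs,
            seed=_region_seed(seed, ri), step_s=subject.step_s,
        )
        gain = g_focus if focus_region in ("all", region) else g_other
        total = gain * buf.samples if total is None else total + gain * buf.samples
    peak = np.max(np.abs(total)) if total.size else 0.0
    if peak > 1.0:
        total = total * (10.0 ** (-1.0 / 20.0) / peak)
    return AudioBuffer(total, fs)
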