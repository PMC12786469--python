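import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from eegsonify.spectral import BAND_NAMES
from eegsonify.synthesis import (
    MappingConstants,
    apply_tremolo,
    bitcrush,
    crossfade,
    map_frame,
    noise_pink,
    osc_sine,
    osc_triangle,
    ramp_track,
    render_region,
    render_subject,
)
from .conftest import make_features

CONSTS = MappingConstants()
FS = 48000.0


def P_of(**kwargs):
    p = {b: 0.0 for b in BAND_NAMES}
    p.update(kwargs)
    return p


class TestMapFrame:
    def test_range_endpoints(self):
        rng = np.random.default_rng(0)
        f = map_frame(P_of(delta=1.0), 0.0, CONSTS, rng)
        assert f.f_delta == 95.0
        assert map_frame(P_of(theta=1.0), 0.0, CONSTS, rng).f_theta == 170.0
        assert map_frame(P_of(alpha=1.0), 0.0, CONSTS, rng).f_alpha == 340.0

    def test_entropy_zero_endpoints(self):
        f = map_frame(P_of(), 0.0, CONSTS, np.random.default_rng(0))
        assert f.q_factor == 11.0
        assert f.fade == pytest.approx(0.15)
        assert f.trem_depth_beta == pytest.approx(0.1)
        assert f.trem_depth_gamma == pytest.approx(0.15)

    def test_gain_power_law(self):
        f = map_frame({b: 0.5 for b in BAND_NAMES}, 0.5, CONSTS, np.random.default_rng(0))
        for b in BAND_NAMES:
            assert f.gains[b] == pytest.approx(0.5 ** 0.85, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            map_frame(P_of(delta=1.2), 0.5, CONSTS, np.random.default_rng(0))
        with pytest.raises(ValueError):
            map_frame(P_of(), 1.5, CONSTS, np.random.default_rng(0))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0, 1), min_size=5, max_size=5),
        st.floats(0, 1),
    )
    def test_bounds_over_unit_hypercube(self, ps, h):
        f = map_frame(dict(zip(BAND_NAMES, ps)), h, CONSTS, np.random.default_rng(1))
        assert 45 <= f.f_delta <= 95
        assert 90 <= f.f_theta <= 170
        assert 180 <= f.f_alpha <= 340
        eps = 1e-9
        assert 1 - eps <= f.q_factor <= 11 + eps
        assert 0.15 - eps <= f.fade <= 1 + eps
        assert 0.1 - eps <= f.trem_depth_beta <= 0.9 + eps
        assert 0.15 - eps <= f.trem_depth_gamma <= 0.95 + eps
        assert 3 - eps <= f.trem_rate_beta <= 17 + eps
        assert 5 - eps <= f.trem_rate_gamma <= 25 + eps
        assert abs(f.detune_alpha) <= 6 + 14 * h

    def test_monotonicity(self):
        rng = np.random.default_rng(2)
        lo = map_frame({b: 0.2 for b in BAND_NAMES}, 0.3, CONSTS, rng)
        hi = map_frame({b: 0.7 for b in BAND_NAMES}, 0.8, CONSTS, rng)
        assert hi.f_delta > lo.f_delta
        assert hi.f_theta > lo.f_theta
        assert hi.f_alpha > lo.f_alpha
        assert hi.trem_rate_beta > lo.trem_rate_beta
        assert hi.trem_rate_gamma > lo.trem_rate_gamma
        assert all(hi.gains[b] > lo.gains[b] for b in BAND_NAMES)
        assert hi.q_factor < lo.q_factor          # decreasing in H
        assert hi.fade > lo.fade
        assert hi.trem_depth_beta > lo.trem_depth_beta


class TestOscillators:
    def test_sine_peak_frequency(self):
        x = osc_sine(np.full(48000, 100.0), FS)
        f, p = signal.welch(x, FS, nperseg=16384)
        assert f[np.argmax(p)] == pytest.approx(100.0, abs=3.0)

    def test_sine_no_discontinuity_under_frequency_step(self):
        track = ramp_track([100.0, 400.0], 1.0, 0.08, FS)
        x = osc_sine(track, FS)
        bound = 2 * np.pi * track.max() / FS * 1.1
        assert np.max(np.abs(np.diff(x))) <= bound

    def test_empty_track(self):
        assert osc_sine(np.empty(0), FS).size == 0
        assert osc_triangle(np.empty(0), np.empty(0), FS).size == 0

    def test_triangle_fundamental_and_octave_detune(self):
        n = 96000
        for cents, expected in [(0.0, 250.0), (1200.0, 500.0), (20.0, 252.90)]:
            x = osc_triangle(np.full(n, 250.0), np.full(n, cents), FS)
            f, p = signal.welch(x, FS, nperseg=2 ** 16)
            mask = f < 700
            assert f[mask][np.argmax(p[mask])] == pytest.approx(expected, abs=1.0)


class TestNoisePink:
    def test_spectral_slope(self):
        x = noise_pink(2 ** 19, FS, np.random.default_rng(5))
        f, p = signal.welch(x, FS, nperseg=2 ** 14)
        mask = (f >= 100) & (f <= 8000)
        slope = np.polyfit(np.log(f[mask]), np.log(p[mask]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_seeded(self):
        a = noise_pink(48000, FS, np.random.default_rng(7))
        b = noise_pink(48000, FS, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_unbiased_across_seeds(self):
        # a single 1/f realization can sit far from zero (diverging
        # low-frequency power); the generator is unbiased in expectation
        means = [
            noise_pink(48000, FS, np.random.default_rng(s)).mean() for s in range(12)
        ]
        assert abs(np.mean(means)) < 0.15


class TestTremolo:
    def test_zero_depth_identity(self):
        x = np.random.default_rng(0).standard_normal(1000)
        y = apply_tremolo(x, np.full(1000, 5.0), np.zeros(1000), FS)
        np.testing.assert_allclose(y, x)

    def test_full_depth_gain_range(self):
        n = 48000
        y = apply_tremolo(np.ones(n), np.full(n, 5.0), np.ones(n), FS)
        assert y.min() == pytest.approx(0.0, abs=1e-3)
        assert y.max() == pytest.approx(1.0, abs=1e-3)

    def test_envelope_modulation_at_rate(self):
        n = 5 * 48000
        rng = np.random.default_rng(1)
        y = apply_tremolo(rng.standard_normal(n), np.full(n, 5.0), np.full(n, 1.0), FS)
        env = np.abs(signal.hilbert(y))
        env = signal.decimate(env, 100, ftype="fir")
        f, p = signal.welch(env - env.mean(), FS / 100, nperseg=2048)
        assert f[np.argmax(p)] == pytest.approx(5.0, abs=0.3)


class TestBitcrushAndCrossfade:
    def test_quantizer_values(self):
        assert bitcrush(np.array([0.0]))[0] == 0.0
        assert bitcrush(np.array([0.3]), 4)[0] == pytest.approx(0.25)

    def test_level_count(self):
        x = np.linspace(-1, 1, 10001)
        assert np.unique(bitcrush(x, 4)).size <= 17

    def test_bits_below_one_rejected(self):
        with pytest.raises(ValueError):
            bitcrush(np.zeros(4), 0)

    def test_crossfade_endpoints_and_midpoint(self):
        clean = np.ones(8)
        crushed = np.full(8, -1.0)
        np.testing.assert_allclose(crossfade(clean, crushed, np.zeros(8)), clean)
        np.testing.assert_allclose(crossfade(clean, crushed, np.ones(8)), crushed, atol=1e-7)
        mid = crossfade(clean, crushed, np.full(8, 0.5))
        assert mid[0] == pytest.approx(np.cos(np.pi / 4) - np.sin(np.pi / 4), abs=1e-7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossfade(np.zeros(3), np.zeros(4), np.zeros(3))


class TestRampTrack:
    def test_constant_track(self):
        tr = ramp_track([0.7, 0.7, 0.7], 1.0, 0.08, FS)
        np.testing.assert_allclose(tr, 0.7)

    def test_reaches_99pct_at_ramp_time(self):
        tr = ramp_track([0.0, 1.0], 1.0, 0.08, FS)
        idx = 48000 + int(0.08 * FS) - 1
        assert tr[idx] >= 0.99 - 1e-9

    def test_second_ramp_starts_from_current_value(self):
        tr = ramp_track([0.0, 1.0, 0.0], 1.0, 0.08, FS)
        # continuity at the second boundary: no jump bigger than one ramp step
        assert abs(tr[96000] - tr[95999]) < 0.01

    def test_monotone_during_ramp(self):
        tr = ramp_track([0.0, 1.0], 1.0, 0.08, FS)
        ramp = tr[48000:48000 + int(0.08 * FS)]
        assert np.all(np.diff(ramp) > 0)

    def test_invalid_ramp_rejected(self):
        with pytest.raises(ValueError):
            ramp_track([0.0, 1.0], 1.0, 0.0, FS)
        with pytest.raises(ValueError):
            ramp_track([0.0, 1.0], 1.0, 2.0, FS)


class TestRenderRegion:
    def test_silence_on_zero_powers(self):
        buf = render_region(make_features({}, 0.5), seed=1)
        assert np.max(np.abs(buf.samples)) == 0.0

    def test_duration(self):
        buf = render_region(make_features({"delta": 0.5}, 0.5, n_windows=5), seed=1)
        assert buf.samples.size == 5 * 48000

    def test_deterministic(self):
        a = render_region(make_features({"alpha": 0.6, "beta": 0.4}, 0.5), seed=9)
        b = render_region(make_features({"alpha": 0.6, "beta": 0.4}, 0.5), seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            render_region(make_features({}, 0.5, n_windows=0), seed=1)

    def test_gamma_energy_above_cutoff(self):
        """A gamma-only mix is dominated by the 2-kHz high-passed white noise."""
        buf = render_region(make_features({"gamma": 1.0}, 0.5), seed=2)
        f, p = signal.welch(buf.samples, FS, nperseg=8192)
        frac_hi = p[f > 2000].sum() / p.sum()
        assert frac_hi > 0.9


@pytest.fixture(scope="module")
def tiny_subject():
    from eegsonify.spectral import SubjectFeatures
    from eegsonify.montage import REGIONS

    regions = {
        code: make_features({"theta": 0.5, "alpha": 0.5}, 0.6, n_windows=3)
        for code in REGIONS
    }
    return SubjectFeatures("tiny", 500.0, 2.0, 1.0, regions)


class TestRenderSubject:

    def test_duration_and_peak_bound(self, tiny_subject):
        buf = render_subject(tiny_subject, seed=4)
        assert buf.samples.size == 3 * 48000
        assert np.max(np.abs(buf.samples)) <= 1.0

    def test_focus_gain_ratio(self):
        """Focused region plays 18 dB (7.94x) above a non-focused one."""
        from eegsonify.spectral import SubjectFeatures
        from eegsonify.montage import REGIONS

        regions = {
            code: make_features({"alpha": 0.7} if code == "O-L" else {}, 0.5, n_windows=3)
            for code in REGIONS
        }
        subject = SubjectFeatures("solo", 500.0, 2.0, 1.0, regions)
        focused = render_subject(subject, focus_region="O-L", seed=4)
        unfocused = render_subject(subject, focus_region="F-L", seed=4)
        rms = lambda x: np.sqrt((x ** 2).mean())
        ratio = rms(focused.samples) / rms(unfocused.samples)
        assert ratio == pytest.approx(10 ** (18 / 20), rel=1e-3)

    def test_unknown_region_rejected(self, tiny_subject):
        with pytest.raises(ValueError):
            render_subject(tiny_subject, focus_region="X-9", seed=4)

    def test_deterministic(self, tiny_subject):
        a = render_subject(tiny_subject, seed=8)
        b = render_subject(tiny_subject, seed=8)
        np.testing.assert_array_equal(a.samples, b.samples)
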