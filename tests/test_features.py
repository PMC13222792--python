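"""Acoustic feature extraction: periods, perturbation, HNR, entropy, MFCC,
glottal proxies, tensor assembly."""

import math

import numpy as np
import pytest

from dysarthria_ssm.features import (DEFAULT_CHANNELS, FrameMatrix,
                                     PeriodTrack, assemble_tensor,
                                     bilinear_resize, detect_periods,
                                     glottal_measures, harmonic_noise_ratio,
                                     mfcc_with_deltas, perturbation_measures,
                                     wavelet_entropy)
from dysarthria_ssm.synth import synth_phonation

from conftest import as_segment, params, profile


def track(periods=None, amps=None):
    periods = np.asarray(periods if periods is not None else [])
    amps = np.asarray(amps if amps is not None else np.ones_like(periods))
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    return PeriodTrack(starts, periods, amps, np.ones(10, bool))


class TestDetectPeriods:
    def test_clean_phonation_periods(self):
        """Jitter-free 150 Hz phonation: every period within 1% of 1/150 s."""
        x, fs = synth_phonation(profile(f0=150.0, seed=4), params(), 2.0)
        t = detect_periods(as_segment(x))
        assert t.n_cycles > 100
        np.testing.assert_allclose(t.cycle_periods, 1 / 150.0, rtol=0.01)

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        t = detect_periods(as_segment(rng.standard_normal(32000)))
        assert t.voiced_fraction < 0.2

    def test_silence_empty_track(self):
        t = detect_periods(as_segment(np.zeros(12000), scale="short_0p75s"))
        assert t.n_cycles == 0 and t.voiced_fraction == 0.0


class TestPerturbationMeasures:
    def test_constant_track_all_zero(self):
        m = perturbation_measures(track([0.01] * 30, [1.0] * 30))
        for v in m.as_dict().values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_alternating_periods_local_jitter(self):
        """Periods alternating 9.9/10.1 ms: each |dT| = 0.2 ms on a 10 ms
        mean, so local jitter is exactly 2%."""
        m = perturbation_measures(track([0.0099, 0.0101] * 20))
        assert m.jitter_local == pytest.approx(2.0, rel=1e-9)

    def test_alternating_amplitudes_shimmer_db(self):
        m = perturbation_measures(track([0.01] * 40, [1.0, 1.122] * 20))
        assert m.shimmer_local_db == pytest.approx(20 * math.log10(1.122),
                                                   rel=1e-9)

    def test_quotient_measures_missing_when_too_few_cycles(self):
        m = perturbation_measures(track([0.01] * 6, [1.0] * 6))
        assert math.isnan(m.shimmer_apq11)
        assert not math.isnan(m.jitter_ppq5)

    def test_empty_track_all_missing(self):
        m = perturbation_measures(track())
        assert all(math.isnan(v) for v in m.as_dict().values())


class TestHNR:
    def test_noiseless_phonation_hits_cap(self):
        """Without noise the per-frame autocorrelation saturates, so the
        reported HNR sits at the configured ceiling (up to edge frames)."""
        x, fs = synth_phonation(profile(seed=1), params(), 2.0)
        s = as_segment(x)
        est = harmonic_noise_ratio(s, detect_periods(s), ceiling_db=20.0)
        assert est == pytest.approx(20.0, abs=0.2)

    def test_recovers_generator_hnr(self):
        x, fs = synth_phonation(profile(seed=2),
                                params(jitter=0.1, shimmer=0.1, hnr=10.0), 3.0)
        s = as_segment(x)
        est = harmonic_noise_ratio(s, detect_periods(s))
        assert est == pytest.approx(10.0, abs=3.0)

    def test_unvoiced_missing(self):
        rng = np.random.default_rng(3)
        s = as_segment(rng.standard_normal(32000))
        assert math.isnan(harmonic_noise_ratio(s, detect_periods(s)))


class TestWaveletEntropy:
    def test_uniform_subbands_give_ln5(self):
        # white noise spreads energy over all subbands: entropy near ln 5;
        # a narrowband tone concentrates it: entropy much lower
        rng = np.random.default_rng(4)
        noise_h = wavelet_entropy(as_segment(rng.standard_normal(16000)))
        t = np.arange(16000) / 16000
        tone_h = wavelet_entropy(as_segment(np.sin(2 * np.pi * 3000 * t)))
        assert tone_h < noise_h <= math.log(5) + 1e-9

    def test_range_bounds(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            h = wavelet_entropy(as_segment(rng.standard_normal(12000)))
            assert 0.0 <= h <= math.log(5) + 1e-9


class TestMFCC:
    def test_frame_count_short_window(self):
        """0.75 s at 16 kHz: floor((12000-400)/160)+1 = 73 frames."""
        rng = np.random.default_rng(6)
        fm = mfcc_with_deltas(as_segment(rng.standard_normal(12000),
                                         scale="short_0p75s"))
        assert fm.values.shape == (73, 39)

    def test_reversal_leaves_static_mean(self):
        """Time reversal preserves magnitude spectra, so the mean static
        MFCC vector is (statistically) unchanged."""
        rng = np.random.default_rng(7)
        x = rng.standard_normal(12000)
        a = mfcc_with_deltas(as_segment(x)).values[:, :13].mean(axis=0)
        b = mfcc_with_deltas(as_segment(x[::-1].copy())).values[:, :13].mean(axis=0)
        np.testing.assert_allclose(a, b, atol=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            mfcc_with_deltas(as_segment(np.ones(100)))


class TestGlottal:
    def _pulse_train(self, duty, f0=125.0, fs=16000, dur=1.0):
        n = round(dur * fs)
        t = np.arange(n) / fs
        phase = (t * f0) % 1.0
        return (phase < duty).astype(float)

    def test_open_quotient_of_duty_cycle(self):
        x = self._pulse_train(0.6)
        s = as_segment(x)
        t = detect_periods(s)
        g = glottal_measures(s, t)
        assert g.oq == pytest.approx(0.6, abs=0.1)

    def test_pure_sine_h1h2_at_cap(self):
        tt = np.arange(16000) / 16000
        x = np.sin(2 * np.pi * 150 * tt)
        s = as_segment(x)
        g = glottal_measures(s, detect_periods(s))
        assert g.h1_h2 == pytest.approx(40.0)

    def test_doubling_h2_drops_6db(self):
        tt = np.arange(16000) / 16000
        base = np.sin(2 * np.pi * 150 * tt)

        def h1h2(a2):
            x = base + a2 * np.sin(2 * np.pi * 300 * tt)
            s = as_segment(x)
            return glottal_measures(s, detect_periods(s)).h1_h2

        assert h1h2(0.4) - h1h2(0.8) == pytest.approx(6.02, abs=0.3)

    def test_unvoiced_missing(self):
        rng = np.random.default_rng(8)
        s = as_segment(rng.standard_normal(16000))
        g = glottal_measures(s, detect_periods(s))
        assert math.isnan(g.oq) and math.isnan(g.h1_h2)


class TestAssembleTensor:
    def _scalars(self, value=1.0):
        from dysarthria_ssm.features import SCALAR_CHANNELS
        return {k: value for k in SCALAR_CHANNELS}

    def test_constant_channel_stays_constant(self):
        fm = FrameMatrix(np.zeros((73, 39)))
        t = assemble_tensor(fm, self._scalars(2.5), size=64)
        jit_plane = t.values[:, :, t.channel_names.index("jitter_local")]
        np.testing.assert_allclose(jit_plane, 2.5, atol=1e-12)

    def test_bilinear_preserves_linear_ramp(self):
        ramp = np.linspace(0, 1, 73)[:, None] * np.ones((1, 13))
        out = bilinear_resize(ramp, (128, 128))
        expect = np.linspace(0, 1, 128)[:, None] * np.ones((1, 128))
        np.testing.assert_allclose(out, expect, atol=1e-6)

    def test_corners_preserved(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((73, 39))
        out = bilinear_resize(a, (128, 128))
        assert out[0, 0] == pytest.approx(a[0, 0])
        assert out[-1, -1] == pytest.approx(a[-1, -1])
        assert out[0, -1] == pytest.approx(a[0, -1])

    def test_default_layout(self):
        fm = FrameMatrix(np.random.default_rng(0).standard_normal((73, 39)))
        t = assemble_tensor(fm, self._scalars(), size=32)
        assert t.values.shape == (32, 32, 14)
        assert list(t.channel_names) == DEFAULT_CHANNELS

    def test_missing_scalar_rejected(self):
        fm = FrameMatrix(np.zeros((73, 39)))
        scal = self._scalars()
        scal["hnr_db"] = math.nan
        with pytest.raises(ValueError, match="impute"):
            assemble_tensor(fm, scal)
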