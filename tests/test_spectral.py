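"""Cyclic auto-spectrum and frequency/CV estimation."""

import numpy as np
import pytest

from dropfreq import (
    AliasingWarning,
    CyclicAutoSpectrum,
    DegenerateSpectrumError,
    NoPeakError,
    PeakBand,
    SimilarityVector,
    compute_auto_spectrum,
    detect_fundamentals,
    estimate_clip,
    estimate_frequency,
    find_fundamental_band,
)

from conftest import make_clip


def tone_sv(freq_hz, frame_rate, n, amp=0.05, offset=0.9):
    i = np.arange(n)
    return SimilarityVector(
        similarities=offset + amp * np.cos(2 * np.pi * freq_hz * i / frame_rate),
        reference_index=None,
        frame_rate=frame_rate,
    )


def synthetic_spectrum(frame_rate, n, peak_powers):
    """Spectrum with power concentrated in chosen bins: {bin: power}."""
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    power = np.zeros_like(freqs)
    for b, p in peak_powers.items():
        power[b] = p
    return CyclicAutoSpectrum(
        freqs=freqs, power=power, delta_f=frame_rate / n,
        n_frames=n, frame_rate=frame_rate,
    )


class TestComputeAutoSpectrum:
    def test_pure_tone_lands_in_its_bin(self):
        spec = compute_auto_spectrum(tone_sv(1200.0, 10000.0, 5000))
        assert spec.delta_f == pytest.approx(2.0)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(1200.0)

    def test_constant_vector_is_degenerate(self):
        sv = SimilarityVector(np.full(128, 0.97), None, 1000.0)
        spec = compute_auto_spectrum(sv)
        assert spec.degenerate
        assert np.all(spec.power == 0.0)

    def test_parseval_with_rectangular_window(self, rng):
        x = rng.random(512)
        sv = SimilarityVector(x, None, 1000.0)
        spec = compute_auto_spectrum(sv, window="rectangular")
        assert spec.power.sum() == pytest.approx(
            x.size * np.var(x), rel=1e-6
        )

    def test_dc_bin_is_zero(self, rng):
        sv = SimilarityVector(rng.random(256) + 5.0, None, 100.0)
        spec = compute_auto_spectrum(sv)
        assert spec.power[0] == 0.0

    def test_resolution_law(self, rng):
        x = rng.random(5000)
        full = compute_auto_spectrum(SimilarityVector(x, None, 10000.0))
        short = compute_auto_spectrum(SimilarityVector(x[:1000], None, 10000.0))
        assert short.delta_f == pytest.approx(5 * full.delta_f)
        assert full.delta_f == pytest.approx(2.0)


class TestFundamentalBand:
    def test_pure_tone_band_contains_only_the_tone(self):
        spec = compute_auto_spectrum(tone_sv(1200.0, 10000.0, 5000))
        band = find_fundamental_band(spec)
        assert spec.freqs[band.peak_bin] == pytest.approx(1200.0)
        assert band.hi - band.lo <= 4

    def test_fundamental_beats_stronger_harmonic_rule(self):
        # 400 Hz (power 1.0) with 800 Hz harmonic (0.6): band sits at 400
        spec = synthetic_spectrum(10000.0, 1000, {40: 1.0, 80: 0.6})
        band = find_fundamental_band(spec, prominence_frac=0.5)
        assert spec.freqs[band.peak_bin] == pytest.approx(400.0)

    def test_weak_lowest_peak_requires_prominence(self):
        # the lowest peak below the prominence threshold is skipped
        spec = synthetic_spectrum(10000.0, 1000, {40: 0.2, 77: 1.0})
        band = find_fundamental_band(spec, prominence_frac=0.5)
        assert spec.freqs[band.peak_bin] == pytest.approx(770.0)

    def test_flat_noise_has_no_peak(self, rng):
        sv = SimilarityVector(
            0.9 + 1e-3 * rng.standard_normal(2048), None, 1000.0
        )
        with pytest.raises(NoPeakError):
            find_fundamental_band(compute_auto_spectrum(sv))

    def test_degenerate_raises(self):
        sv = SimilarityVector(np.ones(64), None, 100.0)
        with pytest.raises(DegenerateSpectrumError):
            find_fundamental_band(compute_auto_spectrum(sv))

    def test_equal_power_tie_resolves_to_lower_frequency(self):
        spec = synthetic_spectrum(10000.0, 1000, {50: 1.0, 90: 1.0})
        band = find_fundamental_band(spec, prominence_frac=0.5)
        assert spec.freqs[band.peak_bin] == pytest.approx(500.0)


class TestEstimateFrequency:
    def test_single_bin_peak_has_zero_cv(self):
        spec = synthetic_spectrum(10000.0, 1000, {120: 3.0})
        est = estimate_frequency(spec, PeakBand(lo=119, hi=121, peak_bin=120))
        assert est.mean_freq_hz == pytest.approx(1200.0)
        assert est.cv_percent == 0.0
        assert est.peak_freq_hz == pytest.approx(1200.0)

    def test_two_bin_centroid_and_width(self):
        # equal power at 1198 and 1202 Hz: centroid 1200, sigma 2 Hz
        spec = synthetic_spectrum(10000.0, 5000, {599: 1.0, 601: 1.0})
        est = estimate_frequency(spec, PeakBand(lo=599, hi=601, peak_bin=599))
        assert est.mean_freq_hz == pytest.approx(1200.0)
        assert est.cv_percent == pytest.approx(100 * 2.0 / 1200.0, rel=1e-9)

    def test_band_contains_mean_and_peak(self):
        spec = compute_auto_spectrum(tone_sv(431.7, 3000.0, 2000))
        band = find_fundamental_band(spec)
        est = estimate_frequency(spec, band)
        assert est.band_low_hz <= est.mean_freq_hz <= est.band_high_hz
        assert est.band_low_hz <= est.peak_freq_hz <= est.band_high_hz

    def test_zero_band_power_raises(self):
        spec = synthetic_spectrum(1000.0, 100, {20: 1.0})
        with pytest.raises(NoPeakError):
            estimate_frequency(spec, PeakBand(lo=5, hi=7, peak_bin=6))

    def test_aliasing_warning_near_nyquist(self):
        spec = synthetic_spectrum(1000.0, 1000, {450: 1.0})
        with pytest.warns(AliasingWarning):
            estimate_frequency(spec, PeakBand(lo=449, hi=451, peak_bin=450))

    def test_stable_cv_much_below_stepped_cv(self):
        stable, _ = make_clip(200.0, 2000.0, 1000, seed=21)
        sched = ((0.0, 0.25, 200.0), (0.25, 0.5, 209.0))
        from dropfreq import SyntheticVideoConfig, generate_video
        from conftest import SMALL_GEOMETRY

        cfg = SyntheticVideoConfig(
            frequency_schedule=sched, frame_rate=2000.0, n_frames=1000,
            seed=22, **SMALL_GEOMETRY,
        )
        stepped, _ = generate_video(cfg)
        cv_stable = estimate_clip(stable).cv_percent
        cv_stepped = estimate_clip(stepped, prominence_frac=0.3).cv_percent
        assert cv_stable < 1.0
        assert cv_stepped > 2 * cv_stable


class TestDetectFundamentals:
    def test_harmonic_ladder_collapses_to_one(self):
        spec = synthetic_spectrum(
            10000.0, 1000, {40: 1.0, 80: 0.7, 120: 0.4}
        )
        mc = detect_fundamentals(spec, max_channels=3, prominence_frac=0.1)
        assert mc.n_channels == 1
        assert mc.channels[0].mean_freq_hz == pytest.approx(400.0)

    def test_three_distinct_fundamentals(self):
        spec = synthetic_spectrum(
            10000.0, 1000, {41: 0.3, 158: 1.0, 192: 0.5}
        )
        mc = detect_fundamentals(spec, max_channels=3, prominence_frac=0.1)
        assert [round(ch.mean_freq_hz) for ch in mc.channels] == [410, 1580, 1920]

    def test_single_channel_spectrum_yields_one(self):
        spec = compute_auto_spectrum(tone_sv(300.0, 2000.0, 1000))
        mc = detect_fundamentals(spec, max_channels=4)
        assert mc.n_channels == 1

    def test_no_fundamental_is_multiple_of_another(self):
        spec = synthetic_spectrum(
            10000.0, 1000, {30: 1.0, 60: 0.8, 73: 0.9}
        )
        mc = detect_fundamentals(spec, max_channels=3, prominence_frac=0.1)
        freqs = [ch.mean_freq_hz for ch in mc.channels]
        assert freqs == [pytest.approx(300.0), pytest.approx(730.0)]
        for i, fa in enumerate(freqs):
            for fb in freqs[i + 1:]:
                ratio = fb / fa
                assert abs(ratio - round(ratio)) > 0.02

    def test_max_channels_prunes_weakest(self):
        spec = synthetic_spectrum(
            10000.0, 1000, {41: 0.3, 158: 1.0, 192: 0.5}
        )
        mc = detect_fundamentals(spec, max_channels=2, prominence_frac=0.1)
        assert [round(ch.mean_freq_hz) for ch in mc.channels] == [1580, 1920]


def test_reference_choice_shifts_phase_not_frequency(stable_clip):
    """Estimated frequency moves by less than one bin across references."""
    stack, _ = stable_clip
    estimates = [
        estimate_clip(stack, reference_index=r).mean_freq_hz
        for r in (0, 3, 17, 101, 250)
    ]
    delta_f = stack.frame_rate / stack.n_frames
    assert max(estimates) - min(estimates) < delta_f
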