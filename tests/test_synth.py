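import numpy as np
import pytest

import orcacall as oc
from orcacall.synth import gabor_click


def _spectrum_db(x, fs):
    """One-sided amplitude spectrum in dB, and its frequency axis (Hz)."""
    w = np.hanning(x.size)
    mag = np.abs(np.fft.rfft(x * w))
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    with np.errstate(divide="ignore"):
        return 20 * np.log10(mag / mag.max()), freqs


class TestWhistle:
    def test_pure_tone_length_and_peak(self):
        spec = oc.WhistleSpec(contour=oc.ContourSpec(((0.0, 5.0), (1.0, 5.0)), "linear"))
        rec = oc.synthesize_whistle(spec, sample_rate=96_000)
        assert rec.samples.size == 96_000
        db, freqs = _spectrum_db(rec.samples, 96_000)
        assert abs(freqs[np.argmax(db)] - 5000.0) <= 0.5 * 96_000 / rec.samples.size + 1.0

    def test_harmonic_levels_follow_rolloff(self):
        spec = oc.WhistleSpec(
            contour=oc.ContourSpec(((0.0, 5.0), (1.0, 5.0)), "linear"),
            n_harmonics=2,
            harmonic_rolloff=6.0,
        )
        rec = oc.synthesize_whistle(spec, sample_rate=96_000)
        db, freqs = _spectrum_db(rec.samples, 96_000)

        def level_at(f_hz):
            window = (freqs > f_hz - 100) & (freqs < f_hz + 100)
            return db[window].max()

        fund = level_at(5000)
        assert level_at(10_000) - fund == pytest.approx(-6.0, abs=1.0)
        assert level_at(15_000) - fund == pytest.approx(-12.0, abs=1.0)

    def test_aliasing_precondition(self):
        spec = oc.WhistleSpec(
            contour=oc.ContourSpec(((0.0, 20.0), (0.5, 20.0)), "linear"), n_harmonics=2
        )
        with pytest.raises(ValueError, match="sample_rate"):
            oc.synthesize_whistle(spec, sample_rate=96_000)


class TestBurstPulse:
    def test_sidebands_spaced_by_pulse_rate(self, pulsed_carrier):
        _, rec, _ = pulsed_carrier
        db, freqs = _spectrum_db(rec.samples, 96_000)
        bin_hz = freqs[1] - freqs[0]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(db, height=-30.0, distance=int(200 / bin_hz))
        peak_freqs = freqs[peaks]
        near_carrier = peak_freqs[(peak_freqs > 2000) & (peak_freqs < 6000)]
        spacings = np.diff(near_carrier)
        assert np.median(spacings) == pytest.approx(500.0, abs=bin_hz + 1.0)

    def test_full_duty_cycle_degenerates_to_tone(self):
        spec = oc.BurstPulseSpec(
            contour=oc.ContourSpec(((0.0, 4.0), (1.0, 4.0)), "linear"),
            pulse_rate=500.0,
            duty_cycle=1.0,
        )
        rec = oc.synthesize_burst_pulse(spec)
        db, freqs = _spectrum_db(rec.samples, 96_000)
        sideband = (freqs > 4300) & (freqs < 4700)
        assert db[sideband].max() < -40.0

    def test_pulse_rate_must_be_below_carrier(self):
        with pytest.raises(ValueError, match="pulse_rate"):
            oc.synthesize_burst_pulse(
                oc.BurstPulseSpec(
                    contour=oc.ContourSpec(((0.0, 0.4), (1.0, 0.4)), "linear"),
                    pulse_rate=500.0,
                )
            )


class TestClickTrain:
    def test_gabor_envelope_width_below_200_us(self):
        pulse = gabor_click(18.0, 180e-6, 96_000)
        from scipy.signal import hilbert

        env = np.abs(hilbert(pulse))
        above = env > env.max() * 10 ** (-3 / 20)
        width = above.sum() / 96_000
        assert width < 200e-6

    def test_negative_polarity_at_center(self):
        pulse = gabor_click(18.0, 180e-6, 96_000, polarity=-1)
        assert pulse[pulse.size // 2] < 0

    def test_reflection_appears_at_autocorrelation_lag(self):
        spec = oc.ClickTrainSpec(n_clicks=1, ici=0.01, reflection=(0.5e-3, 10.0))
        rec = oc.synthesize_click_train(spec)
        x = rec.samples
        ac = np.correlate(x, x, mode="full")[x.size - 1 :]
        ac /= ac[0]
        lag = 0.5e-3 * 96_000
        window = ac[int(lag - 5) : int(lag + 6)]
        # -10 dB amplitude reflection -> autocorrelation peak near 0.316
        assert window.max() > 0.2
        assert abs(int(lag - 5) + np.argmax(window) - lag) <= 3

    def test_geometric_ramp_shortens_intervals(self):
        spec = oc.ClickTrainSpec(n_clicks=20, ici=0.05, ici_ramp=0.9)
        rec = oc.synthesize_click_train(spec)
        stats = oc.detect_clicks(rec)
        assert stats.n_clicks == 20
        assert np.all(np.diff(stats.icis) < 0)


class TestAddNoise:
    def test_same_seed_reproducible(self, upsweep_recording):
        a = oc.add_noise(upsweep_recording, 10.0, seed=11)
        b = oc.add_noise(upsweep_recording, 10.0, seed=11)
        assert np.array_equal(a.samples, b.samples)
        c = oc.add_noise(upsweep_recording, 10.0, seed=12)
        assert not np.array_equal(a.samples, c.samples)

    def test_band_integrated_snr_within_half_db(self, upsweep_recording):
        band = (4000.0, 9000.0)
        noisy = oc.add_noise(upsweep_recording, 10.0, seed=5, band=band)
        noise = noisy.samples - upsweep_recording.samples
        psd = np.abs(np.fft.rfft(noise)) ** 2
        freqs = np.fft.rfftfreq(noise.size, 1 / 96_000)
        in_band = (freqs >= band[0]) & (freqs < band[1])
        p_noise_band = np.mean(noise**2) * psd[in_band].sum() / psd.sum()
        p_signal = np.mean(upsweep_recording.samples**2)
        measured = 10 * np.log10(p_signal / p_noise_band)
        assert measured == pytest.approx(10.0, abs=0.5)

    def test_high_snr_leaves_contour_unchanged(self, upsweep_spec, upsweep_spectrogram):
        rec = oc.synthesize_whistle(upsweep_spec)
        noisy = oc.add_noise(rec, 60.0, seed=2)
        trace_clean = oc.extract_contour(upsweep_spectrogram)
        trace_noisy = oc.extract_contour(oc.compute_spectrogram(noisy))
        n = min(trace_clean.n_points, trace_noisy.n_points)
        bin_khz = upsweep_spectrogram.params.bin_width / 1000
        assert abs(trace_clean.n_points - trace_noisy.n_points) <= 2
        assert np.all(np.abs(trace_clean.freqs[:n] - trace_noisy.freqs[:n]) <= bin_khz)


class TestFeatureVectors:
    def test_counts_and_labels(self, catalog):
        df = oc.sample_feature_vectors(catalog, n_per_group=20, spread=0.05, seed=0)
        assert len(df) == 180
        assert (df.groupby("group").size() == 20).all()

    def test_truncation_keeps_samples_in_printed_ranges(self, catalog):
        df = oc.sample_feature_vectors(catalog, n_per_group=50, spread=0.05, seed=1)
        for g in catalog:
            sub = df[df.group == g.group_id]
            for name, (lo, hi) in g.ranges.items():
                assert sub[name].between(lo, hi).all(), (g.group_id, name)

    def test_bc03_durations_in_printed_range(self, catalog):
        df = oc.sample_feature_vectors(catalog, n_per_group=30, spread=0.2, seed=2)
        bc03 = df[df.group == "BC03"]
        assert bc03.duration.between(3.9, 11.3).all()

    def test_whistle_groups_have_absent_sideband(self, catalog):
        df = oc.sample_feature_vectors(catalog, n_per_group=5, spread=0.05, seed=3)
        assert df[df.call_class == "whistle"].sideband_spacing.isna().all()
        assert df[df.call_class != "whistle"].sideband_spacing.notna().all()

    def test_deterministic_given_seed(self, catalog):
        a = oc.sample_feature_vectors(catalog, 10, 0.05, seed=9)
        b = oc.sample_feature_vectors(catalog, 10, 0.05, seed=9)
        assert a.equals(b)
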