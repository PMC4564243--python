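import numpy as np
import pytest

import orcacall as oc
from orcacall.contour import BURST_PULSE, PULSED_MIDDLE, TRANSITION, WHISTLE


class TestExtraction:
    def test_noiseless_upsweep_within_one_bin(self, upsweep_spec, upsweep_spectrogram):
        trace = oc.extract_contour(upsweep_spectrogram)
        assert trace.n_points > 100
        truth = upsweep_spec.contour.frequency_at(trace.times)
        bin_khz = upsweep_spectrogram.params.bin_width / 1000
        assert np.all(np.abs(trace.freqs - truth) <= bin_khz)

    def test_snr10_recovery_95_percent(self, upsweep_spec):
        rec = oc.synthesize_whistle(upsweep_spec)
        noisy = oc.add_noise(rec, 10.0, seed=4, band=(4000.0, 9000.0))
        spec = oc.compute_spectrogram(noisy)
        region = oc.CallAnnotation(0.0, 1.2, 3000.0, 10_000.0)
        trace = oc.extract_contour(spec, region=region)
        truth = upsweep_spec.contour.frequency_at(trace.times)
        bin_khz = spec.params.bin_width / 1000
        frac = np.mean(np.abs(trace.freqs - truth) <= bin_khz)
        assert frac >= 0.95

    def test_pure_noise_yields_empty_trace(self):
        rng = np.random.default_rng(6)
        rec = oc.WaveRecording(rng.normal(0, 0.1, 96_000), 96_000)
        trace = oc.extract_contour(oc.compute_spectrogram(rec))
        assert trace.is_empty

    def test_time_translation_equivariance(self, upsweep_spec):
        """Shifting the call by whole hops shifts the trace times only."""
        rec = oc.synthesize_whistle(upsweep_spec)
        spec1 = oc.compute_spectrogram(rec)
        hop = spec1.params.hop
        n_shift = 20  # frames
        shifted = oc.WaveRecording(
            np.r_[np.zeros(n_shift * hop), rec.samples], rec.sample_rate
        )
        spec2 = oc.compute_spectrogram(shifted)
        t1 = oc.extract_contour(spec1)
        t2 = oc.extract_contour(spec2)
        dt = n_shift * hop / rec.sample_rate
        assert abs(t1.n_points - t2.n_points) <= 2  # edge frames only
        # align on frame index; frequencies must agree on the overlap
        k1 = np.round(t1.times / spec1.params.frame_step).astype(int)
        k2 = np.round((t2.times - dt) / spec1.params.frame_step).astype(int)
        common, i1, i2 = np.intersect1d(k1, k2, return_indices=True)
        assert common.size >= t1.n_points - 2
        assert np.array_equal(t1.freqs[i1], t2.freqs[i2])
        assert np.allclose(t2.times[i2] - t1.times[i1], dt, atol=1e-9)

    def test_region_restricts_search(self, upsweep_spectrogram):
        region = oc.CallAnnotation(0.2, 0.8, 3000.0, 10_000.0)
        trace = oc.extract_contour(upsweep_spectrogram, region=region)
        assert trace.times[0] >= 0.2
        assert trace.times[-1] <= 0.8


class TestHarmonics:
    def test_synthesized_harmonics_found(self):
        spec = oc.WhistleSpec(
            contour=oc.ContourSpec(((0.0, 5.0), (1.0, 5.0)), "linear"), n_harmonics=2
        )
        sg = oc.compute_spectrogram(oc.synthesize_whistle(spec))
        trace = oc.extract_contour(sg)
        report = oc.detect_harmonics(sg, trace)
        assert report.has_harmonics
        assert report.multiples_found == [2, 3]

    def test_fundamental_only_whistle_negative(self, upsweep_spectrogram):
        trace = oc.extract_contour(upsweep_spectrogram)
        report = oc.detect_harmonics(upsweep_spectrogram, trace)
        assert not report.has_harmonics
        assert report.multiples_found == []

    def test_bc02_like_overtone_whistle(self):
        # low-frequency, short, weakly modulated whistle with overtones
        spec = oc.WhistleSpec(
            contour=oc.ContourSpec(((0.0, 2.0), (0.3, 2.6), (0.6, 2.2)), "cubic"),
            n_harmonics=3,
        )
        sg = oc.compute_spectrogram(oc.synthesize_whistle(spec))
        trace = oc.extract_contour(sg)
        assert oc.detect_harmonics(sg, trace).has_harmonics

    def test_empty_trace_rejected(self, upsweep_spectrogram):
        empty = oc.ContourTrace(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            oc.detect_harmonics(upsweep_spectrogram, empty)


class TestSidebands:
    def test_pulsed_carrier_spacing(self, pulsed_carrier):
        spec, _, sg = pulsed_carrier
        trace = oc.extract_contour(sg)
        report = oc.measure_sideband_spacing(sg, trace)
        bin_khz = sg.params.bin_width / 1000
        assert report.spacing == pytest.approx(0.5, abs=bin_khz)
        assert report.n_contours_used >= 3

    def test_plain_whistle_absent(self, upsweep_spectrogram):
        trace = oc.extract_contour(upsweep_spectrogram)
        report = oc.measure_sideband_spacing(upsweep_spectrogram, trace)
        assert report.spacing is None

    def test_amplitude_scaling_invariance(self, pulsed_carrier):
        spec, rec, sg = pulsed_carrier
        scaled = oc.WaveRecording(rec.samples * 0.05, rec.sample_rate)
        sg2 = oc.compute_spectrogram(scaled)
        t1, t2 = oc.extract_contour(sg), oc.extract_contour(sg2)
        r1 = oc.measure_sideband_spacing(sg, t1)
        r2 = oc.measure_sideband_spacing(sg2, t2)
        assert r1.spacing == pytest.approx(r2.spacing, abs=1e-9)

    def test_pulsed_middle_region_only(self):
        spec = oc.BurstPulseSpec(
            contour=oc.ContourSpec(((0.0, 4.0), (1.2, 4.0)), "linear"),
            pulse_rate=800.0,
            pulsed_window=(0.4, 0.8),
        )
        sg = oc.compute_spectrogram(oc.synthesize_burst_pulse(spec))
        trace = oc.extract_contour(sg)
        mid = oc.measure_sideband_spacing(sg, trace, region=(0.4, 0.8))
        ends = oc.measure_sideband_spacing(sg, trace, region=(0.0, 0.35))
        bin_khz = sg.params.bin_width / 1000
        assert mid.spacing == pytest.approx(0.8, abs=bin_khz)
        assert ends.spacing is None

    def test_bc05_like_spacing_in_printed_range(self):
        """Low burst-pulse: 0.9 kHz carrier pulsed at 500 Hz."""
        spec = oc.BurstPulseSpec(
            contour=oc.ContourSpec(((0.0, 0.9), (0.8, 0.9)), "linear"), pulse_rate=500.0
        )
        sg = oc.compute_spectrogram(oc.synthesize_burst_pulse(spec))
        region = oc.CallAnnotation(0.0, 0.8, 600.0, 6000.0)
        trace = oc.extract_contour(sg, region=region)
        report = oc.measure_sideband_spacing(sg, trace)
        assert 0.3 <= report.spacing <= 0.7


class TestClassification:
    def test_whistle_with_harmonics_is_whistle(self):
        spec = oc.WhistleSpec(
            contour=oc.ContourSpec(((0.0, 5.0), (1.0, 6.0)), "linear"), n_harmonics=2
        )
        sg = oc.compute_spectrogram(oc.synthesize_whistle(spec))
        assert oc.classify_call(sg, oc.extract_contour(sg)) == WHISTLE

    def test_fully_pulsed_carrier_is_burst_pulse(self, pulsed_carrier):
        _, _, sg = pulsed_carrier
        assert oc.classify_call(sg, oc.extract_contour(sg)) == BURST_PULSE

    def test_half_pulsed_call_is_transition(self):
        spec = oc.BurstPulseSpec(
            contour=oc.ContourSpec(((0.0, 4.0), (1.0, 4.0)), "linear"),
            pulse_rate=500.0,
            pulsed_window=(0.0, 0.5),
        )
        sg = oc.compute_spectrogram(oc.synthesize_burst_pulse(spec))
        assert oc.classify_call(sg, oc.extract_contour(sg)) == TRANSITION

    def test_middle_pulsed_call_is_pulsed_middle(self):
        spec = oc.BurstPulseSpec(
            contour=oc.ContourSpec(((0.0, 4.0), (1.2, 4.0)), "linear"),
            pulse_rate=800.0,
            pulsed_window=(0.4, 0.8),
        )
        sg = oc.compute_spectrogram(oc.synthesize_burst_pulse(spec))
        assert oc.classify_call(sg, oc.extract_contour(sg)) == PULSED_MIDDLE
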