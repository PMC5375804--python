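"""Waveform and pulse-phase feature extraction."""

import numpy as np
import pytest

from pulsetherm import (
    AcquisitionProtocol,
    MaterialThermalParams,
    SampleMask,
    TemperatureTrace,
    amplitude_subset,
    mean_trace,
    pixelwise_spectra,
    protocol_frame_indices,
    simulate_trace,
    spectral_features,
    split_trace,
    trim_buffers,
    waveform_features,
)

from conftest import make_video


def trace_of(values, protocol, trimmed=False):
    return TemperatureTrace(
        values=np.asarray(values, dtype=float), fps=protocol.fps,
        protocol=protocol, trimmed=trimmed,
    )


class TestMeanTrace:
    def test_single_pixel_mask_is_identity(self, default_protocol):
        frames = np.arange(510 * 4 * 4, dtype=float).reshape(510, 4, 4) / 100.0
        video = make_video(frames, default_protocol)
        mask = np.zeros((4, 4), bool)
        mask[2, 3] = True
        trace = mean_trace(video, SampleMask(mask, "manual_threshold"))
        assert np.allclose(trace.values, frames[:, 2, 3], atol=1e-4)

    def test_uniform_frames_independent_of_mask(self, default_protocol):
        frames = np.repeat(np.linspace(20, 30, 510)[:, None, None], 16, axis=1)
        frames = np.repeat(frames, 16, axis=2)
        video = make_video(frames, default_protocol)
        m1 = np.zeros((16, 16), bool); m1[0, 0] = True
        m2 = np.ones((16, 16), bool)
        t1 = mean_trace(video, SampleMask(m1, "manual_threshold"))
        t2 = mean_trace(video, SampleMask(m2, "manual_threshold"))
        assert np.allclose(t1.values, t2.values, atol=1e-4)

    def test_checkerboard_averages_to_midpoint(self, default_protocol):
        frame = np.indices((6, 6)).sum(axis=0) % 2 * 10.0 + 20.0  # 20/30 checkers
        frames = np.repeat(frame[None], 510, axis=0)
        video = make_video(frames, default_protocol)
        trace = mean_trace(video, SampleMask(np.ones((6, 6), bool), "manual_threshold"))
        assert np.allclose(trace.values, 25.0, atol=1e-4)


class TestTrimAndSplit:
    def test_default_protocol_trims_to_450(self, default_protocol):
        trace = trace_of(np.zeros(510), default_protocol)
        assert len(trim_buffers(trace).values) == 450

    def test_zero_buffer_protocol_is_identity(self):
        protocol = AcquisitionProtocol(0, 5, 10, 0, 30)
        trace = trace_of(np.arange(450.0), protocol)
        assert np.array_equal(trim_buffers(trace).values, trace.values)

    def test_10fps_protocol_trims_to_150(self):
        protocol = AcquisitionProtocol(1, 5, 10, 1, 10)
        trace = trace_of(np.zeros(170), protocol)
        assert len(trim_buffers(trace).values) == 150

    def test_split_lengths_and_concatenation(self, default_protocol):
        values = np.sin(np.arange(450) / 7.0)
        trimmed = trace_of(values, default_protocol, trimmed=True)
        rising, falling = split_trace(trimmed)
        assert (len(rising), len(falling)) == (150, 300)
        assert np.array_equal(np.concatenate([rising, falling]), values)

    def test_toy_split(self):
        protocol = AcquisitionProtocol(1, 5, 10, 1, 1)
        trimmed = trace_of(np.arange(15.0), protocol, trimmed=True)
        rising, falling = split_trace(trimmed)
        assert (len(rising), len(falling)) == (5, 10)

    def test_length_mismatch_rejected(self, default_protocol):
        with pytest.raises(ValueError, match="length"):
            trace_of(np.zeros(100), default_protocol)


class TestWaveformFeatures:
    def test_constant_trace_gives_zero_gains(self, default_protocol):
        wf = waveform_features(trace_of(np.full(510, 24.0), default_protocol))
        assert wf.peak_minus_rest == 0.0
        assert wf.final_minus_rest == 0.0

    def test_lumped_model_closed_form(self, default_protocol, quiet_params):
        # T_amb=25, g=50, tau_h=2 s, tau_c=4 s
        trace = trace_of(simulate_trace(quiet_params, default_protocol), default_protocol)
        wf = waveform_features(trace)
        peak_expected = 50.0 * (1 - np.exp(-2.5))
        final_expected = peak_expected * np.exp(-10.0 / 4.0)
        assert wf.peak_minus_rest == pytest.approx(peak_expected, abs=1e-9)
        assert wf.final_minus_rest == pytest.approx(final_expected, abs=1e-9)
        assert peak_expected == pytest.approx(45.896, abs=5e-4)
        assert final_expected == pytest.approx(3.7674, abs=5e-4)

    def test_return_to_rest_gives_zero_final(self, default_protocol):
        values = np.full(510, 25.0)
        values[30:480] = 25.0 + np.sin(np.linspace(0, np.pi, 450)) * 10
        wf = waveform_features(trace_of(values, default_protocol))
        assert wf.final_minus_rest == pytest.approx(0.0, abs=1e-9)

    def test_smoothing_window_averages_around_landmarks(self, default_protocol):
        rng = np.random.default_rng(14)
        values = np.full(510, 25.0) + rng.normal(0, 0.5, 510)
        trace = trace_of(values, default_protocol)
        wf = waveform_features(trace, smooth_window=2)
        expected_rest = values[28:33].mean()
        expected_peak = values[178:183].mean()
        assert wf.peak_minus_rest == pytest.approx(expected_peak - expected_rest)

    def test_zero_front_buffer_reads_first_frame_as_rest(self):
        protocol = AcquisitionProtocol(0, 5, 10, 1, 30)
        values = np.linspace(25, 30, 480)
        wf = waveform_features(trace_of(values, protocol))
        assert wf.peak_minus_rest == pytest.approx(values[150] - values[0])


class TestSpectralFeatures:
    def test_retained_counts_whole_and_split(self, default_protocol):
        trimmed = trace_of(np.random.default_rng(0).normal(30, 2, 450),
                           default_protocol, trimmed=True)
        whole = spectral_features(trimmed, "whole")
        rising = spectral_features(trimmed, "rising")
        falling = spectral_features(trimmed, "falling")
        assert (len(whole.amplitudes), len(whole.phases)) == (225, 224)
        assert (len(rising.amplitudes), len(rising.phases)) == (75, 74)
        assert (len(falling.amplitudes), len(falling.phases)) == (150, 149)

    def test_frequency_grid(self, default_protocol):
        trimmed = trace_of(np.zeros(450) + 1, default_protocol, trimmed=True)
        spec = spectral_features(trimmed, "whole")
        assert spec.frequencies[0] == 0.0
        assert spec.frequencies[1] == pytest.approx(30.0 / 450)
        assert spec.frequencies[-1] < 15.0  # Nyquist bin itself is discarded

    def test_constant_trace_energy_in_dc_bin(self, default_protocol):
        c = 27.5
        trimmed = trace_of(np.full(450, c), default_protocol, trimmed=True)
        spec = spectral_features(trimmed, "whole")
        assert spec.amplitudes[0] == pytest.approx(450 * c, rel=1e-12)
        assert np.all(spec.amplitudes[1:] <= 1e-9 * 450 * c)

    def test_parseval_before_discarding(self, default_protocol):
        rng = np.random.default_rng(2)
        values = rng.normal(25, 3, 450)
        full = np.fft.fft(values)
        assert np.sum(values**2) == pytest.approx(
            np.sum(np.abs(full) ** 2) / 450, rel=1e-12
        )

    def test_conjugate_symmetry_of_real_traces(self, default_protocol):
        rng = np.random.default_rng(3)
        values = rng.normal(25, 3, 450)
        full = np.abs(np.fft.fft(values))
        assert np.allclose(full[1:], full[1:][::-1], rtol=1e-10)

    def test_pure_cosine_lands_in_its_bin(self, default_protocol):
        n, k = 450, 7
        t = np.arange(n)
        values = np.cos(2 * np.pi * k * t / n)
        spec = spectral_features(
            trace_of(values, default_protocol, trimmed=True), "whole"
        )
        assert spec.amplitudes[k] == pytest.approx(n / 2, rel=1e-9)
        others = np.delete(spec.amplitudes, k)
        assert np.all(others < 1e-6 * n)

    @pytest.mark.parametrize("n,fps", [(150, 30.0), (300, 30.0), (450, 30.0)])
    def test_retained_count_formula(self, n, fps):
        # whole-signal protocols with the right trimmed length
        protocol = AcquisitionProtocol(0, n / (3 * fps), 2 * n / (3 * fps), 0, fps)
        spec = spectral_features(
            trace_of(np.zeros(n) + 20, protocol, trimmed=True), "whole"
        )
        assert len(spec.amplitudes) == n // 2
        assert len(spec.phases) == n // 2 - 1

    def test_odd_length_rejected(self):
        protocol = AcquisitionProtocol(0, 5, 10, 0, 1)
        with pytest.raises(ValueError, match="even"):
            spectral_features(trace_of(np.zeros(15), protocol, trimmed=True), "whole")

    def test_untrimmed_trace_rejected(self, default_protocol):
        with pytest.raises(ValueError, match="trimmed"):
            spectral_features(trace_of(np.zeros(510), default_protocol), "whole")


class TestPixelwiseSpectra:
    def test_ampligram_matches_single_pixel_spectrum(self, default_protocol):
        rng = np.random.default_rng(4)
        frames = rng.normal(25, 2, size=(450, 5, 5))
        video = make_video(frames, default_protocol)
        mask = SampleMask(np.ones((5, 5), bool), "manual_threshold")
        phase, amp = pixelwise_spectra(video, mask, component_index=3)
        pix = np.fft.fft(video.frames[:, 2, 2].astype(float))[3]
        assert amp[2, 2] == pytest.approx(np.abs(pix), rel=1e-6)
        assert phase[2, 2] == pytest.approx(np.angle(pix), abs=1e-6)

    def test_constant_background_has_zero_amplitude(self, default_protocol):
        frames = np.full((450, 4, 4), 25.0)
        frames[:, 1, 1] += np.sin(np.arange(450) / 5.0)
        video = make_video(frames, default_protocol)
        mask = SampleMask(np.ones((4, 4), bool), "manual_threshold")
        _, amp = pixelwise_spectra(video, mask, component_index=5)
        assert amp[0, 0] == pytest.approx(0.0, abs=1e-2)

    def test_masked_pixels_are_nan_and_bad_index_rejected(self, default_protocol):
        frames = np.zeros((450, 3, 3)) + 20
        video = make_video(frames, default_protocol)
        m = np.zeros((3, 3), bool); m[1, 1] = True
        phase, amp = pixelwise_spectra(video, SampleMask(m, "manual_threshold"), 1)
        assert np.isnan(amp[0, 0]) and not np.isnan(amp[1, 1])
        with pytest.raises(ValueError, match="retained range"):
            pixelwise_spectra(video, SampleMask(m, "manual_threshold"), 225)

    def test_edge_cooling_separates_boundary_phase(self, toy_protocol):
        """Edge-accelerated cooling shows up as a boundary/interior phase contrast."""
        from dataclasses import replace
        from scipy.ndimage import binary_erosion

        from pulsetherm import ClassSpec, DatasetConfig, render_video

        params = MaterialThermalParams(
            equilibrium_gain=40.0, tau_heat=1.5, tau_cool=4.0,
            edge_cooling_factor=3.0,
        )
        spec = ClassSpec("hulls", "blob", (12, 12), params)
        config = DatasetConfig(
            class_specs=(spec,), samples_per_class=1,
            protocol=AcquisitionProtocol(fps=2.0),
            frame_height=24, frame_width=24, noise_sd=0.0, seed=5,
        )
        video, gt = render_video(spec, config, (0, 0))
        lamp_on, _, cutoff, _ = protocol_frame_indices(config.protocol)
        trimmed = make_video(video.frames[lamp_on:cutoff], config.protocol)
        mask = SampleMask(gt, "manual_threshold")
        phase, _ = pixelwise_spectra(trimmed, mask, component_index=1)
        interior = binary_erosion(gt)
        boundary = gt & ~interior
        assert abs(np.nanmean(phase[boundary]) - np.nanmean(phase[interior])) > 1e-3


class TestAmplitudeSubset:
    def test_subset_selection(self, default_protocol):
        trimmed = trace_of(np.random.default_rng(1).normal(25, 2, 450),
                           default_protocol, trimmed=True)
        spec = spectral_features(trimmed, "whole")
        assert amplitude_subset(spec, 1).tolist() == [spec.amplitudes[0]]
        assert len(amplitude_subset(spec, 10)) == 10
        assert np.array_equal(amplitude_subset(spec, 225), spec.amplitudes)
        with pytest.raises(ValueError):
            amplitude_subset(spec, 226)
        with pytest.raises(ValueError):
            amplitude_subset(spec, 0)
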