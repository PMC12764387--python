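"""Trace metrics: ΔF/F0, peaks, FWHM, τ, TPA-MAD."""

import math

import numpy as np
import pytest

from stimwave.datatypes import Movie, TraceSet
from stimwave.synthetic import TransientKernel, generate_trace_set, generate_wave_movie
from stimwave.transients import (
    compute_fwhm,
    detect_peaks,
    extract_traces,
    fit_decay_tau,
    normalize_dff,
    tpa_mad,
    transient_metrics,
)


def make_traces(dff: np.ndarray, dt_ms: float = 50.0) -> TraceSet:
    dff = np.atleast_2d(dff)
    t = np.arange(dff.shape[1]) * dt_ms
    return TraceSet([f"roi_{i}" for i in range(dff.shape[0])], t, dff)


class TestNormalize:
    def test_constant_series_maps_to_zero(self):
        assert np.allclose(normalize_dff(np.full(50, 7.0)), 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        raw = 100.0 + 20.0 * rng.random(200)
        np.testing.assert_allclose(normalize_dff(raw), normalize_dff(3.7 * raw))

    def test_peak_amplitude_recovered(self, kernel):
        t = np.arange(0, 4000, 50.0)
        raw = 100.0 * (1.0 + 0.5 * np.asarray(kernel(t - 500.0)) / kernel.amplitude)
        dff = normalize_dff(raw)
        assert dff.max() == pytest.approx(0.5, rel=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            normalize_dff(np.ones(5))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_dff(np.linspace(-100.0, -1.0, 60))


class TestExtractTraces:
    def test_constant_movie_gives_zero_traces(self, constant_movie):
        traces = extract_traces(constant_movie, (2, 2))
        assert traces.n_rois == 4
        np.testing.assert_allclose(traces.dff, 0.0)

    def test_single_roi_equals_frame_means(self, constant_movie):
        frames = constant_movie.frames.copy()
        frames[5:] += 30.0
        movie = Movie(frames, constant_movie.frame_rate, constant_movie.pixel_size)
        traces = extract_traces(movie, (1, 1))
        np.testing.assert_allclose(traces.raw[0], frames.mean(axis=(1, 2)))

    def test_synchronous_movie_peaks_at_truth(self, kernel):
        movie, truth = generate_wave_movie(32, 32, 2.0, 20.0, 60, "synchronous",
                                           period_ms=2000.0, kernel=kernel, seed=4)
        traces = extract_traces(movie, (4, 4))
        truth_frame = movie.frames.mean(axis=(1, 2)).argmax()
        for row in traces.dff:
            assert row.argmax() == truth_frame

    def test_oversized_grid_rejected(self, constant_movie):
        with pytest.raises(ValueError, match="does not tile"):
            extract_traces(constant_movie, (100, 1))


class TestDetectPeaks:
    def test_flat_trace_has_no_peaks(self):
        peaks = detect_peaks(make_traces(np.zeros(100)), 0.2, 250.0)
        assert peaks.total_peaks == 0

    def test_noiseless_train_counts_beats(self, clean_traces):
        traces, truth = clean_traces
        peaks = detect_peaks(traces, 0.5, 250.0)
        for roi in peaks.roi_ids:
            assert peaks.n_peaks(roi) == truth.peak_times_ms.shape[1]
            np.testing.assert_allclose(peaks.times_ms[roi],
                                       truth.peak_times_ms[0], atol=50.0)

    def test_noise_preserves_count(self, kernel):
        noisy, truth = generate_trace_set(4, 4, 2000.0, kernel, 0.0,
                                          noise_sd=0.05, frame_rate=20.0, seed=8)
        peaks = detect_peaks(noisy, 0.5 * kernel.amplitude, 250.0)
        for roi in peaks.roi_ids:
            assert peaks.n_peaks(roi) == 4

    def test_separation_floor(self):
        with pytest.raises(ValueError, match="two frame intervals"):
            detect_peaks(make_traces(np.zeros(50)), 0.2, 60.0)


class TestFWHM:
    def test_triangular_pulse_half_base(self):
        # symmetric triangle of base 2w has FWHM w
        w = 20  # samples
        y = np.concatenate([np.linspace(0, 1, w + 1), np.linspace(1, 0, w + 1)[1:]])
        traces = make_traces(y, dt_ms=10.0)
        fwhm = compute_fwhm(traces.time_ms, traces.dff[0], int(y.argmax()))
        assert fwhm == pytest.approx(w * 10.0, rel=0.01)

    def test_dense_kernel_matches_closed_form(self, kernel):
        t = np.arange(0.0, 3000.0, 1.0)
        y = np.asarray(kernel(t))
        fwhm = compute_fwhm(t, y, int(y.argmax()))
        assert fwhm == pytest.approx(kernel.fwhm_ms, rel=1e-3)

    def test_frame_rate_sampling_within_one_frame(self, kernel):
        t = np.arange(0.0, 3000.0, 50.0)  # 20 frames/s
        y = np.asarray(kernel(t))
        fwhm = compute_fwhm(t, y, int(y.argmax()))
        assert abs(fwhm - kernel.fwhm_ms) < 50.0

    def test_clipped_transient_flagged(self, kernel):
        t = np.arange(0.0, 300.0, 10.0)
        y = np.asarray(kernel(t))  # decay never reaches half-max inside trace
        assert math.isnan(compute_fwhm(t, y, int(y.argmax())))


class TestTau:
    def test_exact_exponential_recovered(self):
        t = np.arange(0.0, 2000.0, 50.0)
        tau, r2, _ = fit_decay_tau(t, np.exp(-t / 400.0), 0)
        assert tau == pytest.approx(400.0, rel=0.01)
        assert r2 == pytest.approx(1.0)

    def test_amplitude_invariance(self):
        t = np.arange(0.0, 2000.0, 50.0)
        y = np.exp(-t / 400.0)
        tau_1 = fit_decay_tau(t, y, 0)[0]
        tau_k = fit_decay_tau(t, 5.0 * y, 0)[0]
        assert tau_k == pytest.approx(tau_1)

    def test_rising_window_flagged(self):
        t = np.arange(0.0, 1000.0, 50.0)
        tau, _, _ = fit_decay_tau(t, np.linspace(0.1, 1.0, t.size), 0)
        assert math.isnan(tau)

    def test_noisy_train_mean_within_five_percent(self, kernel):
        taus = []
        for seed in range(10):
            traces, _ = generate_trace_set(16, 8, 2000.0, kernel, 0.0, 0.02,
                                           20.0, seed=seed)
            peaks = detect_peaks(traces, 0.5, 250.0)
            m = transient_metrics(traces, peaks)
            taus.append(m["tau_ms"].mean())
        assert abs(np.mean(taus) - kernel.tau_ms) / kernel.tau_ms < 0.05


class TestScaleInvariance:
    def test_metrics_unchanged_by_raw_scaling(self, kernel):
        traces, _ = generate_trace_set(4, 4, 2000.0, kernel, 20.0, 0.02, 20.0,
                                       seed=3)
        scaled = TraceSet(traces.roi_ids, traces.time_ms,
                          np.vstack([normalize_dff(r) for r in traces.raw * 2.5]))
        m_orig = transient_metrics(traces, detect_peaks(traces, 0.5, 250.0))
        m_scaled = transient_metrics(scaled, detect_peaks(scaled, 0.5, 250.0))
        np.testing.assert_allclose(m_orig["fwhm_ms"], m_scaled["fwhm_ms"])
        # tau comes from an iterative fit: invariant to optimizer tolerance
        np.testing.assert_allclose(m_orig["tau_ms"], m_scaled["tau_ms"],
                                   rtol=1e-4)


class TestTpaMad:
    def test_identical_rois_give_zero(self, clean_traces):
        traces, _ = clean_traces
        result = tpa_mad(traces, detect_peaks(traces, 0.5, 250.0))
        assert result.tpa_mad_ms == 0.0
        assert result.n_rois_used == traces.n_rois

    def test_constructed_offsets_give_exact_mad(self, kernel):
        """Three ROIs offset by {-50, 0, +50} ms every beat -> MAD 50 ms."""
        base, _ = generate_trace_set(1, 4, 2000.0, kernel, 0.0, 0.0, 1000.0,
                                     seed=0)
        dt = base.frame_interval_ms
        shift = int(round(50.0 / dt))
        rows = [np.roll(base.dff[0], s) for s in (-shift, 0, shift)]
        traces = TraceSet(["a", "b", "c"], base.time_ms, np.vstack(rows))
        result = tpa_mad(traces, detect_peaks(traces, 0.5, 250.0))
        assert result.tpa_mad_ms == pytest.approx(50.0)

    def test_global_shift_invariance(self, kernel):
        traces, _ = generate_trace_set(6, 4, 2000.0, kernel, 30.0, 0.0, 20.0,
                                       seed=5)
        peaks = detect_peaks(traces, 0.5, 250.0)
        shifted_peaks = detect_peaks(
            TraceSet(traces.roi_ids, traces.time_ms,
                     np.roll(traces.dff, 3, axis=1)), 0.5, 250.0)
        a = tpa_mad(traces, peaks)
        b = tpa_mad(TraceSet(traces.roi_ids, traces.time_ms,
                             np.roll(traces.dff, 3, axis=1)), shifted_peaks)
        assert a.tpa_mad_ms == pytest.approx(b.tpa_mad_ms)

    def test_roi_permutation_invariance(self, kernel):
        traces, _ = generate_trace_set(6, 4, 2000.0, kernel, 30.0, 0.0, 20.0,
                                       seed=6)
        perm = np.random.default_rng(1).permutation(traces.n_rois)
        permuted = TraceSet([traces.roi_ids[i] for i in perm], traces.time_ms,
                            traces.dff[perm])
        a = tpa_mad(traces, detect_peaks(traces, 0.5, 250.0))
        b = tpa_mad(permuted, detect_peaks(permuted, 0.5, 250.0))
        assert a.tpa_mad_ms == b.tpa_mad_ms

    def test_single_roi_rejected(self, kernel):
        traces, _ = generate_trace_set(1, 4, 2000.0, kernel, 0.0, 0.0, 20.0,
                                       seed=0)
        with pytest.raises(ValueError, match="two ROIs"):
            tpa_mad(traces, detect_peaks(traces, 0.5, 250.0))

    def test_monotone_in_jitter(self, kernel):
        means = []
        for jitter in (0.0, 50.0, 100.0):
            vals = [
                tpa_mad(t, detect_peaks(t, 0.5, 250.0)).tpa_mad_ms
                for t, _ in (generate_trace_set(16, 8, 2000.0, kernel, jitter,
                                                0.02, 20.0, seed=s)
                             for s in range(1, 9))
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]
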