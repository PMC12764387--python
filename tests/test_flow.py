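"""Optical flow: preprocessing, Horn–Schunck, circular statistics, roses."""

import math

import numpy as np
import pytest
from scipy import stats

from stimwave.datatypes import Movie
from stimwave.flow import (
    FlowField,
    circular_mean,
    circular_variance,
    compute_flow_sequence,
    flow_summary,
    horn_schunck,
    preprocess_movie,
    rose_histogram,
)
from stimwave.synthetic import generate_wave_movie


def gaussian_blob(h, w, cy, cx, sigma=4.0):
    y, x = np.mgrid[0:h, 0:w]
    return 100.0 * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * sigma ** 2))


class TestPreprocess:
    def test_constant_movie_unchanged(self, constant_movie):
        out = preprocess_movie(constant_movie)
        np.testing.assert_allclose(out.frames, constant_movie.frames, atol=1e-9)

    def test_impulse_removed_by_median(self, constant_movie):
        frames = constant_movie.frames.copy()
        frames[10, 8, 8] += 500.0
        out = preprocess_movie(Movie(frames, 20.0, 2.0))
        assert abs(out.frames[10, 8, 8] - 100.0) < 1.0

    def test_lowpass_attenuates_fast_oscillation(self):
        t = np.arange(120) / 20.0
        fast = np.sin(2 * np.pi * 5.0 * t)
        slow = np.sin(2 * np.pi * 0.25 * t)
        frames = 100.0 + fast[:, None, None] * np.ones((1, 16, 16)) \
            + slow[:, None, None] * np.ones((1, 16, 16))
        out = preprocess_movie(Movie(frames, 20.0, 2.0), spatial_median_px=1)
        px = out.frames[:, 8, 8] - out.frames[:, 8, 8].mean()
        spec = np.abs(np.fft.rfft(px))
        freqs = np.fft.rfftfreq(px.size, 1 / 20.0)
        amp_fast = spec[np.argmin(np.abs(freqs - 5.0))]
        amp_slow = spec[np.argmin(np.abs(freqs - 0.25))]
        assert amp_fast / amp_slow < 0.1

    def test_cutoff_must_be_below_nyquist(self, constant_movie):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_movie(constant_movie, temporal_cutoff_hz=10.0)


class TestHornSchunck:
    def test_identical_frames_give_zero_flow(self):
        a = gaussian_blob(32, 32, 16, 16)
        f = horn_schunck(a, a)
        assert np.allclose(f.u, 0.0) and np.allclose(f.v, 0.0)

    def test_intensity_offset_invariance(self):
        a = gaussian_blob(32, 32, 16, 14)
        b = gaussian_blob(32, 32, 16, 15)
        f1 = horn_schunck(a, b)
        f2 = horn_schunck(a + 50.0, b + 50.0)
        np.testing.assert_allclose(f1.u, f2.u, atol=1e-10)
        np.testing.assert_allclose(f1.v, f2.v, atol=1e-10)

    def test_translated_blob_recovered(self):
        a = gaussian_blob(48, 48, 24, 23)
        b = gaussian_blob(48, 48, 24, 24)  # shifted +1 px in x
        f = horn_schunck(a, b, alpha=1.0, n_iter=400)
        support = a > 0.1 * a.max()
        assert f.u[support].mean() == pytest.approx(1.0, rel=0.2)
        assert abs(f.v[support].mean()) < 0.2

    def test_subpixel_ramp_shift_oracle(self):
        """Linear ramp translated by s px: closed-form HS solution is uniform
        flow of exactly s."""
        x = np.arange(64, dtype=float)
        ramp = np.tile(x, (64, 1))
        s = 0.4
        f = horn_schunck(ramp, ramp - s, n_iter=300)
        interior = f.u[8:-8, 8:-8]
        assert interior.mean() == pytest.approx(s, rel=0.05)

    def test_nonfinite_input_rejected(self):
        a = gaussian_blob(16, 16, 8, 8)
        b = a.copy()
        b[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            horn_schunck(a, b)


class TestFlowSequence:
    def test_static_movie_all_zero(self, constant_movie):
        fields = compute_flow_sequence(constant_movie)
        for f in fields:
            assert np.allclose(f.u, 0.0) and np.allclose(f.v, 0.0)

    def test_time_reversal_flips_direction(self, small_plane_wave):
        movie, _ = small_plane_wave
        pre = preprocess_movie(movie)
        fwd = compute_flow_sequence(pre)
        rev_movie = Movie(pre.frames[::-1].copy(), pre.frame_rate, pre.pixel_size)
        rev = compute_flow_sequence(rev_movie)
        s_fwd = flow_summary(fwd, movie.pixel_size, movie.frame_rate)
        s_rev = flow_summary(rev, movie.pixel_size, movie.frame_rate)
        diff = abs(s_fwd.mean_direction_rad - s_rev.mean_direction_rad)
        assert min(diff, 2 * math.pi - diff) == pytest.approx(math.pi, abs=0.3)


class TestSummaries:
    def make_field(self, u, v):
        return FlowField(u=np.asarray(u, float), v=np.asarray(v, float))

    def test_aligned_vectors_zero_circular_variance(self):
        f = self.make_field(np.ones((8, 8)), np.zeros((8, 8)))
        s = flow_summary([f], pixel_size=1.0, frame_rate=1.0, magnitude_floor=0.0)
        assert s.circular_variance == pytest.approx(0.0, abs=1e-12)

    def test_balanced_cross_gives_unit_circular_variance(self):
        phases = np.array([0.0, math.pi / 2, math.pi, 3 * math.pi / 2])
        assert circular_variance(phases) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_circvar(self):
        rng = np.random.default_rng(0)
        phases = rng.vonmises(0.5, 2.0, size=500)
        assert circular_variance(phases) == pytest.approx(
            stats.circvar(phases), abs=1e-12)
        assert circular_mean(phases) == pytest.approx(
            stats.circmean(phases, high=np.pi, low=-np.pi), abs=1e-9)

    def test_pixel_size_scales_magnitude_not_phase(self):
        rng = np.random.default_rng(2)
        f = self.make_field(rng.normal(1, 0.1, (8, 8)), rng.normal(0, 0.1, (8, 8)))
        s1 = flow_summary([f], pixel_size=1.0, frame_rate=20.0)
        s2 = flow_summary([f], pixel_size=2.0, frame_rate=20.0)
        assert s2.mean_magnitude_um_s == pytest.approx(2 * s1.mean_magnitude_um_s)
        assert s2.circular_variance == pytest.approx(s1.circular_variance)

    def test_empty_above_floor_is_error(self):
        f = self.make_field(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="floor"):
            flow_summary([f], 1.0, 1.0, magnitude_floor=1.0)


class TestRose:
    def test_counts_partition_vectors(self):
        rng = np.random.default_rng(3)
        f = FlowField(u=rng.normal(size=(32, 32)), v=rng.normal(size=(32, 32)))
        counts, edges = rose_histogram([f], n_bins=16, magnitude_floor=0.0)
        assert counts.sum() == 32 * 32
        assert edges[0] == pytest.approx(-math.pi)
        assert edges[-1] == pytest.approx(math.pi)

    def test_unidirectional_mass_concentrated(self):
        f = FlowField(u=np.ones((32, 32)), v=0.05 * np.ones((32, 32)))
        counts, _ = rose_histogram([f], n_bins=16, magnitude_floor=0.0)
        top = np.argmax(counts)
        neighbors = counts[[top - 1, top, (top + 1) % 16]].sum()
        assert neighbors / counts.sum() >= 0.9

    def test_uniform_phases_spread_evenly(self):
        rng = np.random.default_rng(4)
        theta = rng.uniform(-math.pi, math.pi, 10_000)
        f = FlowField(u=np.cos(theta), v=np.sin(theta))
        counts, _ = rose_histogram([f], n_bins=16, magnitude_floor=0.0)
        assert counts.max() <= 2 * counts.min()

    def test_minimum_bins(self):
        f = FlowField(u=np.ones((4, 4)), v=np.ones((4, 4)))
        with pytest.raises(ValueError, match="4 bins"):
            rose_histogram([f], n_bins=2)


class TestRotationEquivariance:
    def test_rot90_rotates_direction_only(self, small_plane_wave):
        """Rotating the movie 90 degrees rotates the circular mean by 90
        degrees and preserves magnitude and circular variance within the
        asymmetry of the staggered derivative stencils (a few percent)."""
        movie, _ = small_plane_wave
        pre = preprocess_movie(movie)
        base = flow_summary(compute_flow_sequence(pre), movie.pixel_size,
                            movie.frame_rate)
        rot = Movie(np.rot90(pre.frames, k=1, axes=(1, 2)).copy(),
                    pre.frame_rate, pre.pixel_size)
        rs = flow_summary(compute_flow_sequence(rot), movie.pixel_size,
                          movie.frame_rate)
        assert rs.mean_magnitude_um_s == pytest.approx(base.mean_magnitude_um_s,
                                                       rel=0.05)
        assert rs.circular_variance == pytest.approx(base.circular_variance,
                                                     abs=0.02)
        diff = (rs.mean_direction_rad - base.mean_direction_rad) % (2 * math.pi)
        assert diff == pytest.approx(3 * math.pi / 2, abs=math.radians(3.0))
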