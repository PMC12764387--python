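"""Seeded generators of GCaMP-like calcium movies, ROI trace sets, and
phase-contrast-like motion movies, each paired with ground truth.

Every generator is deterministic given its arguments and seed, and returns a
:class:`GroundTruth` recording the injected parameters (peak times, delay
fields, per-frame speeds) so downstream metrics can be tested for parameter
recovery rather than against hand-picked constants.

The calcium transient is modelled as a linear rise to peak followed by an
exponential decay — the minimal shape with a closed-form full width at half
maximum (``rise/2 + tau * ln 2``) and an exact decay constant, i.e. exactly
the two quantities the trace metrics estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .datatypes import Movie, TraceSet
from .transients import normalize_dff

__all__ = [
    "TransientKernel",
    "GroundTruth",
    "transient_kernel_eval",
    "generate_trace_set",
    "generate_wave_movie",
    "generate_motion_movie",
]

#: Baseline fluorescence F0 in camera intensity units.  Signals and noise are
#: specified in ΔF/F0 units and scaled by F0, so normalization is testable.
DEFAULT_F0 = 100.0

Pattern = Literal["synchronous", "plane_wave", "source", "sink", "motion"]


@dataclass(frozen=True)
class TransientKernel:
    """Calcium transient: linear rise over ``rise_ms``, then exponential
    decay with constant ``tau_ms``, peaking at ``amplitude`` (ΔF/F0 units)."""

    rise_ms: float = 100.0
    tau_ms: float = 400.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_ms <= 0 or self.tau_ms <= 0 or self.amplitude <= 0:
            raise ValueError("rise_ms, tau_ms and amplitude must all be positive")

    def __call__(self, t_ms: np.ndarray | float) -> np.ndarray | float:
        return transient_kernel_eval(self, t_ms)

    @property
    def fwhm_ms(self) -> float:
        """Closed-form full width at half max: rise/2 + tau * ln 2."""
        return self.rise_ms / 2.0 + self.tau_ms * math.log(2.0)

    def support_ms(self, fraction: float = 0.01) -> float:
        """Time until the decay falls below ``fraction`` of the amplitude."""
        return self.rise_ms + self.tau_ms * math.log(1.0 / fraction)


def transient_kernel_eval(kernel: TransientKernel,
                          t_ms: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the kernel at time(s) ``t_ms`` (ms since transient onset).

    Zero for t <= 0, linear up to ``amplitude`` at ``rise_ms``, then
    ``amplitude * exp(-(t - rise_ms) / tau_ms)``.
    """
    t = np.asarray(t_ms, dtype=float)
    rising = kernel.amplitude * t / kernel.rise_ms
    decaying = kernel.amplitude * np.exp(-(t - kernel.rise_ms) / kernel.tau_ms)
    out = np.where(t <= kernel.rise_ms, rising, decaying)
    out = np.where(t <= 0.0, 0.0, out)
    return float(out) if np.isscalar(t_ms) else out


@dataclass
class GroundTruth:
    """Injected parameters of a generated object, for recovery tests.

    Only the fields meaningful for the pattern are populated:
    ``peak_times_ms`` (n_rois, n_beats) for trace sets, ``delay_ms`` (H, W)
    activation-delay field for wave movies, ``mean_speed_um_s``
    (n_frames - 1,) per-frame-pair mean pixel speed for motion movies.
    """

    pattern: Pattern
    period_ms: float
    kernel: TransientKernel | None
    seed: int
    speed_um_s: float | None = None
    direction_rad: float | None = None
    jitter_sd_ms: float | None = None
    noise_sd: float | None = None
    peak_times_ms: np.ndarray | None = None
    delay_ms: np.ndarray | None = None
    mean_speed_um_s: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def generate_trace_set(
    n_rois: int,
    n_beats: int,
    period_ms: float,
    kernel: TransientKernel = TransientKernel(),
    jitter_sd_ms: float = 0.0,
    noise_sd: float = 0.0,
    frame_rate: float = 20.0,
    seed: int = 0,
    f0: float = DEFAULT_F0,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate per-ROI calcium traces: a periodic beat train with per-ROI,
    per-beat Gaussian peak-time jitter and white Gaussian intensity noise.

    Beat k onsets at ``(k + 0.25) * period_ms`` (quarter-period lead-in so the
    first transient is not clipped).  ``noise_sd`` is in ΔF/F0 units; the
    intensity-domain noise standard deviation is ``noise_sd * f0``.  Ground
    truth records the exact jittered peak time of every beat in every ROI.
    """
    if n_beats < 1 or n_rois < 1:
        raise ValueError("need at least one ROI and one beat")
    if period_ms <= kernel.rise_ms + 3.0 * kernel.tau_ms:
        raise ValueError(
            f"period {period_ms} ms too short for kernel "
            f"(need > rise + 3*tau = {kernel.rise_ms + 3 * kernel.tau_ms} ms)"
        )
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / frame_rate
    total_ms = (n_beats + 0.5) * period_ms
    n_samples = int(round(total_ms / dt_ms))
    t = np.arange(n_samples) * dt_ms

    onsets = (np.arange(n_beats) + 0.25) * period_ms
    jitter = rng.normal(0.0, jitter_sd_ms, size=(n_rois, n_beats)) if jitter_sd_ms > 0 \
        else np.zeros((n_rois, n_beats))
    signal = np.zeros((n_rois, n_samples))
    for k in range(n_beats):
        signal += kernel(t[None, :] - onsets[k] - jitter[:, [k]])
    raw = f0 * (1.0 + signal)
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd * f0, size=raw.shape)

    dff = np.vstack([normalize_dff(row) for row in raw])
    traces = TraceSet(
        roi_ids=[f"roi_{i}" for i in range(n_rois)],
        time_ms=t, dff=dff, raw=raw,
    )
    truth = GroundTruth(
        pattern="synchronous", period_ms=period_ms, kernel=kernel, seed=seed,
        jitter_sd_ms=jitter_sd_ms, noise_sd=noise_sd,
        peak_times_ms=onsets[None, :] + jitter + kernel.rise_ms,
        extras={"onsets_ms": onsets, "jitter_ms": jitter, "f0": f0,
                "frame_rate": frame_rate},
    )
    return traces, truth


def _delay_field(pattern: Pattern, h: int, w: int, pixel_size: float,
                 speed: float, direction: float) -> np.ndarray:
    """Per-pixel activation delay (ms), minimum shifted to zero."""
    y, x = np.mgrid[0:h, 0:w]
    if pattern == "synchronous":
        return np.zeros((h, w))
    if speed <= 0:
        raise ValueError("propagating patterns need a positive speed")
    if pattern == "plane_wave":
        proj = (x * math.cos(direction) + y * math.sin(direction)) * pixel_size
        delay = proj / speed * 1000.0
    elif pattern in ("source", "sink"):
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r = np.hypot((x - cx) * pixel_size, (y - cy) * pixel_size)
        delay = r / speed * 1000.0
        if pattern == "sink":
            delay = delay.max() - delay  # wave converges onto the centre
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return delay - delay.min()


def generate_wave_movie(
    h: int = 128,
    w: int = 128,
    pixel_size: float = 2.0,
    frame_rate: float = 20.0,
    n_frames: int = 120,
    pattern: Pattern = "plane_wave",
    speed: float = 10.0,
    direction: float = 0.0,
    period_ms: float = 1000.0,
    kernel: TransientKernel = TransientKernel(),
    noise_sd: float = 0.0,
    seed: int = 0,
    f0: float = DEFAULT_F0,
) -> tuple[Movie, GroundTruth]:
    """Simulate a GCaMP movie of periodic calcium activity.

    Each pixel replays the transient kernel with period ``period_ms``,
    delayed by its activation delay: zero everywhere for ``synchronous``,
    ``position . direction / speed`` for ``plane_wave``, radial distance
    from the centre over speed for ``source`` (reversed for ``sink``).
    ``speed`` is in μm/s, ``direction`` in radians (image x toward +columns,
    y toward +rows), ``noise_sd`` in ΔF/F0 units.
    """
    duration_ms = n_frames * 1000.0 / frame_rate
    if duration_ms < period_ms:
        raise ValueError("movie shorter than one beat period; no full wave crossing")
    delay = _delay_field(pattern, h, w, pixel_size, speed, direction)
    rng = np.random.default_rng(seed)
    t_ms = np.arange(n_frames) * 1000.0 / frame_rate
    # phase within the beat cycle for every (frame, pixel)
    phase = np.mod(t_ms[:, None, None] - delay[None, :, :], period_ms)
    frames = f0 * (1.0 + np.asarray(kernel(phase)))
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd * f0, size=frames.shape)
    frames = np.clip(frames, 0.0, None)
    movie = Movie(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)
    truth = GroundTruth(
        pattern=pattern, period_ms=period_ms, kernel=kernel, seed=seed,
        speed_um_s=None if pattern == "synchronous" else speed,
        direction_rad=direction if pattern == "plane_wave" else None,
        noise_sd=noise_sd, delay_ms=delay,
        extras={"f0": f0},
    )
    return movie, truth


def _stroke_displacement(phase_ms: np.ndarray, period_ms: float,
                         peak_px: float, contraction_fraction: float) -> np.ndarray:
    """Radial displacement amplitude over one beat: raised-cosine in, then out."""
    t_c = contraction_fraction * period_ms
    t_r = period_ms - t_c
    contracting = 0.5 * peak_px * (1.0 - np.cos(np.pi * phase_ms / t_c))
    relaxing = 0.5 * peak_px * (1.0 + np.cos(np.pi * (phase_ms - t_c) / t_r))
    return np.where(phase_ms < t_c, contracting, relaxing)


def generate_motion_movie(
    texture_seed: int = 0,
    h: int = 96,
    w: int = 96,
    pixel_size: float = 2.0,
    frame_rate: float = 20.0,
    n_frames: int = 120,
    beat_period_ms: float = 1000.0,
    peak_displacement_px: float = 2.0,
    contraction_fraction: float = 0.5,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[Movie, GroundTruth]:
    """Simulate a phase-contrast-like movie of a radially beating monolayer.

    A static random texture is warped toward the image centre by a radial
    displacement field whose amplitude follows a raised-cosine stroke:
    contraction over ``contraction_fraction`` of the beat, relaxation over
    the remainder.  The displacement of the farthest pixel peaks at
    ``peak_displacement_px``; displacement scales linearly with radius, so
    the warp is affine and inverted exactly when rendering.

    Ground truth records the per-frame-pair mean pixel speed (μm/s), the
    quantity the contractility velocimetry estimates.
    """
    if peak_displacement_px < 0:
        raise ValueError("peak_displacement_px must be non-negative")
    if not (0.0 < contraction_fraction < 1.0):
        raise ValueError("contraction_fraction must be in (0, 1)")
    y, x = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(x - cx, y - cy)
    r_max = float(r.max())
    if peak_displacement_px >= min(h, w) / 2.0:
        raise ValueError("peak displacement exceeds half the image size")

    tex_rng = np.random.default_rng(texture_seed)
    texture = ndimage.gaussian_filter(tex_rng.uniform(0.0, 1.0, size=(h, w)), sigma=2.0)
    texture = 50.0 + 100.0 * (texture - texture.min()) / np.ptp(texture)

    t_ms = np.arange(n_frames) * 1000.0 / frame_rate
    phase = np.mod(t_ms, beat_period_ms)
    d = _stroke_displacement(phase, beat_period_ms, peak_displacement_px,
                             contraction_fraction)

    frames = np.empty((n_frames, h, w))
    for i in range(n_frames):
        # material point x0 maps to x = x0 - d*(x0-c)/r_max; exact inverse:
        scale = 1.0 - d[i] / r_max
        src_y = cy + (y - cy) / scale
        src_x = cx + (x - cx) / scale
        frames[i] = ndimage.map_coordinates(texture, [src_y, src_x], order=3,
                                            mode="reflect")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd * np.ptp(texture), size=frames.shape)
    frames = np.clip(frames, 0.0, None)
    movie = Movie(frames=frames, frame_rate=frame_rate, pixel_size=pixel_size)

    # mean material speed between frames: |Δd| * mean(r)/r_max, converted to μm/s
    mean_speed = np.abs(np.diff(d)) * float(r.mean()) / r_max * pixel_size * frame_rate
    truth = GroundTruth(
        pattern="motion", period_ms=beat_period_ms, kernel=None, seed=seed,
        noise_sd=noise_sd, mean_speed_um_s=mean_speed,
        extras={
            "peak_displacement_px": peak_displacement_px,
            "contraction_fraction": contraction_fraction,
            "displacement_px": d,
            "texture_seed": texture_seed,
        },
    )
    return movie, truth
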