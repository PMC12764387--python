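"""Shared in-memory containers for movies and ROI trace sets.

These are deliberately thin: a :class:`Movie` is an intensity stack with the
two pieces of acquisition metadata every downstream computation needs (frame
rate and pixel size), and a :class:`TraceSet` is a set of uniformly sampled
per-ROI ΔF/F0 series.  Both round-trip through plain-text/TIFF formats via
:mod:`stimwave.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Movie", "TraceSet"]


@dataclass
class Movie:
    """A time-lapse image stack.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative intensities; T >= 2.
    frame_rate : float
        Acquisition rate in frames per second.
    pixel_size : float
        Physical pixel pitch in micrometres per pixel.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a (T, H, W) stack with T >= 2")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def times_ms(self) -> np.ndarray:
        """Acquisition time of each frame, in ms from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval_ms


@dataclass
class TraceSet:
    """Uniformly sampled per-ROI ΔF/F0 traces.

    ``dff`` has shape (n_rois, n_samples); ``time_ms`` is the shared time
    axis.  ``raw`` optionally keeps the un-normalized intensities the traces
    were derived from (generators fill it; file round-trips may drop it).
    """

    roi_ids: list[str]
    time_ms: np.ndarray
    dff: np.ndarray
    raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if self.dff.shape != (len(self.roi_ids), self.time_ms.size):
            raise ValueError("dff must be (n_rois, n_samples) matching roi_ids and time_ms")
        dt = np.diff(self.time_ms)
        if self.time_ms.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("time axis must be uniformly sampled")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def frame_interval_ms(self) -> float:
        if self.time_ms.size < 2:
            raise ValueError("need at least two samples to define a frame interval")
        return float(self.time_ms[1] - self.time_ms[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-to-wide table: one column per ROI, indexed by time_ms."""
        return pd.DataFrame(self.dff.T, index=pd.Index(self.time_ms, name="time_ms"),
                            columns=self.roi_ids)
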