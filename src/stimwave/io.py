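"""File I/O: TIFF movies with JSON sidecars, trace/waveform/schedule CSVs.

Movies travel as multi-page TIFF plus a ``<name>.json`` sidecar holding
``frame_rate`` (frames/s) and ``pixel_size_um``; tabular data are plain CSV
so every artifact is diffable and readable outside this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import Movie, TraceSet
from .regimen import RegimenSchedule, SampledWaveform, param_at

__all__ = [
    "save_movie",
    "load_movie",
    "save_traces",
    "load_traces",
    "save_waveform",
    "load_waveform",
    "schedule_log",
    "save_schedule_log",
]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def save_movie(movie: Movie, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    _sidecar_path(path).write_text(json.dumps({
        "frame_rate": movie.frame_rate,
        "pixel_size_um": movie.pixel_size,
    }, indent=2))
    return path


def load_movie(path: str | Path) -> Movie:
    """Read a TIFF movie; frame rate and pixel size come from the sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie not found: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    return Movie(frames=tifffile.imread(path).astype(float),
                 frame_rate=float(meta["frame_rate"]),
                 pixel_size=float(meta["pixel_size_um"]))


def save_traces(traces: TraceSet, path: str | Path) -> Path:
    """CSV with a ``time_ms`` column followed by one ΔF/F0 column per ROI."""
    path = Path(path)
    traces.to_frame().to_csv(path)
    return path


def load_traces(path: str | Path) -> TraceSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace CSV not found: {path}")
    df = pd.read_csv(path, index_col="time_ms")
    return TraceSet(roi_ids=list(df.columns), time_ms=df.index.to_numpy(),
                    dff=df.to_numpy().T)


def save_waveform(waveform: SampledWaveform, path: str | Path) -> Path:
    """Oscilloscope-style CSV with columns ``time_s, voltage_V``."""
    path = Path(path)
    pd.DataFrame({"time_s": waveform.times,
                  "voltage_V": waveform.voltages}).to_csv(path, index=False)
    return path


def load_waveform(path: str | Path) -> SampledWaveform:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"waveform CSV not found: {path}")
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError("waveform needs at least two samples")
    sample_rate = 1.0 / float(np.median(np.diff(t)))
    return SampledWaveform(times=t, voltages=df["voltage_V"].to_numpy(),
                           sample_rate=sample_rate)


def schedule_log(schedule: RegimenSchedule, step_minutes: float) -> pd.DataFrame:
    """Table of (t_min, frequency_Hz, phase_duration_ms) along a schedule.

    The first and last rows are exactly the schedule endpoints; with daily
    steps a 10-day ramp therefore logs 11 rows.  A step longer than the
    schedule yields the two endpoint rows.
    """
    if step_minutes <= 0:
        raise ValueError("step_minutes must be positive")
    total = schedule.duration_minutes
    times = list(np.arange(0.0, total, step_minutes))
    if not times or times[-1] < total:
        times.append(total)
    rows = []
    for t in times:
        spec = param_at(schedule, t)
        rows.append({"t_min": t, "frequency_Hz": spec.frequency_hz,
                     "phase_duration_ms": spec.phase_duration_ms})
    return pd.DataFrame(rows)


def save_schedule_log(schedule: RegimenSchedule, step_minutes: float,
                      path: str | Path) -> Path:
    path = Path(path)
    schedule_log(schedule, step_minutes).to_csv(path, index=False)
    return path
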