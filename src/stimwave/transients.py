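"""Per-ROI calcium-trace analysis.

ΔF/F0 normalization, peak detection, per-peak full width at half maximum
(FWHM, a proxy for calcium cycle duration), exponential decay-constant (τ)
fitting (a proxy for sarcoplasmic-reticulum reuptake rate), and the
time-of-peak-arrival median absolute deviation (TPA-MAD) synchronicity
statistic: in a well-coupled syncytium every region's calcium peak arrives
at nearly the same time, so the MAD of arrival times across regions is low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import Movie, TraceSet

__all__ = [
    "PeakSet",
    "SynchronicityResult",
    "extract_traces",
    "normalize_dff",
    "detect_peaks",
    "compute_fwhm",
    "fit_decay_tau",
    "transient_metrics",
    "tpa_mad",
]


@dataclass
class PeakSet:
    """Detected calcium peaks: per ROI, arrays of peak times (ms) and
    ΔF/F0 peak heights, plus the sample index of each peak."""

    roi_ids: list[str]
    times_ms: dict[str, np.ndarray]
    heights: dict[str, np.ndarray]
    indices: dict[str, np.ndarray]

    def n_peaks(self, roi_id: str) -> int:
        return self.times_ms[roi_id].size

    @property
    def total_peaks(self) -> int:
        return sum(v.size for v in self.times_ms.values())


@dataclass
class SynchronicityResult:
    """TPA-MAD of peak-arrival times across ROIs (ms), with the number of
    beats and ROIs that contributed."""

    tpa_mad_ms: float
    n_beats_used: int
    n_rois_used: int


def extract_traces(movie: Movie, grid: tuple[int, int] = (8, 8)) -> TraceSet:
    """Tile the frame into a ``rows x cols`` ROI grid and return the ΔF/F0
    trace of each tile (spatial mean per frame, then :func:`normalize_dff`).

    Tiles are near-equal integer partitions of the frame, so any grid that
    fits the image works; every tile must be non-empty.
    """
    rows, cols = grid
    T, H, W = movie.shape
    if rows < 1 or cols < 1 or rows > H or cols > W:
        raise ValueError(f"grid {grid} does not tile a {H}x{W} frame")
    y_edges = np.linspace(0, H, rows + 1, dtype=int)
    x_edges = np.linspace(0, W, cols + 1, dtype=int)
    roi_ids, raw = [], []
    for i in range(rows):
        for j in range(cols):
            block = movie.frames[:, y_edges[i]:y_edges[i + 1], x_edges[j]:x_edges[j + 1]]
            if block.shape[1] == 0 or block.shape[2] == 0:
                raise ValueError(f"empty ROI at grid cell ({i}, {j})")
            roi_ids.append(f"r{i}c{j}")
            raw.append(block.mean(axis=(1, 2)))
    raw = np.vstack(raw)
    dff = np.vstack([normalize_dff(row) for row in raw])
    return TraceSet(roi_ids=roi_ids, time_ms=movie.times_ms, dff=dff, raw=raw)


def normalize_dff(raw: np.ndarray, baseline_percentile: float = 10.0,
                  baseline_smooth: int = 9) -> np.ndarray:
    """ΔF/F0 = (F - F0) / F0 with F0 the ``baseline_percentile`` of the
    series (default 10th), a baseline estimate robust to transients
    occupying a minority of frames.

    The percentile is taken over a median-filtered copy of the series
    (``baseline_smooth`` samples): on noisy traces a low percentile of the
    raw samples sits systematically below the true baseline, which would
    leave a positive offset in every ΔF/F0 trace and bias decay fits.
    Scale-invariant: scaling the raw intensities leaves the output
    unchanged."""
    raw = np.asarray(raw, dtype=float)
    if raw.size <= 10:
        raise ValueError("need more than 10 samples to estimate a baseline")
    k = min(baseline_smooth, raw.size)
    if k % 2 == 0:
        k -= 1
    f0 = float(np.percentile(sps.medfilt(raw, k) if k >= 3 else raw,
                             baseline_percentile))
    if f0 <= 0:
        raise ValueError("non-positive baseline F0; cannot normalize")
    return (raw - f0) / f0


def detect_peaks(traces: TraceSet, min_prominence_dff: float = 0.2,
                 min_separation_ms: float = 250.0) -> PeakSet:
    """Locate calcium peaks in every ROI trace.

    Local maxima with prominence >= ``min_prominence_dff`` and pairwise
    separation >= ``min_separation_ms``; peak times are at frame resolution
    (no sub-frame refinement).  Empty peak lists are allowed.
    """
    dt = traces.frame_interval_ms
    if min_separation_ms < 2 * dt:
        raise ValueError("min_separation_ms must be at least two frame intervals")
    distance = max(1, int(round(min_separation_ms / dt)))
    times, heights, indices = {}, {}, {}
    for roi, trace in zip(traces.roi_ids, traces.dff):
        idx, _ = sps.find_peaks(trace, prominence=min_prominence_dff,
                                distance=distance)
        indices[roi] = idx
        times[roi] = traces.time_ms[idx]
        heights[roi] = trace[idx]
    return PeakSet(roi_ids=list(traces.roi_ids), times_ms=times,
                   heights=heights, indices=indices)


def _interp_crossing(t0: float, y0: float, t1: float, y1: float, level: float) -> float:
    """Time where the segment (t0,y0)-(t1,y1) crosses ``level``."""
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def compute_fwhm(time_ms: np.ndarray, dff: np.ndarray, peak_index: int) -> float:
    """Full width at half maximum of the peak at ``peak_index`` (ms).

    Half-height crossings nearest the peak are located by linear
    interpolation between the bracketing samples.  A crossing counts only
    when confirmed by a second consecutive sub-half sample (or the trace
    edge), so an isolated noise dip near half height cannot narrow the
    width; on monotone flanks the rule is exact.  Returns ``nan`` when a
    crossing is missing on either side (clipped transient); callers should
    omit such peaks.
    """
    y = np.asarray(dff, dtype=float)
    t = np.asarray(time_ms, dtype=float)
    half = y[peak_index] / 2.0
    if y[peak_index] <= 0:
        return float("nan")

    left = float("nan")
    for i in range(peak_index - 1, -1, -1):
        if y[i] < half and (i == 0 or y[i - 1] < half):
            left = _interp_crossing(t[i], y[i], t[i + 1], y[i + 1], half)
            break
    right = float("nan")
    for i in range(peak_index + 1, y.size):
        if y[i] < half and (i == y.size - 1 or y[i + 1] < half):
            right = _interp_crossing(t[i - 1], y[i - 1], t[i], y[i], half)
            break
    return right - left  # nan if either side is clipped


def fit_decay_tau(time_ms: np.ndarray, dff: np.ndarray, peak_index: int,
                  next_peak_index: int | None = None,
                  guard_ms: float = 200.0) -> tuple[float, float, tuple[int, int]]:
    """Decay constant τ (ms) of the transient at ``peak_index``.

    The fit window runs from one sample after the peak (at frame resolution
    the peak sample can precede the true maximum and lie on the rising
    limb) to ``guard_ms`` before the next peak — the guard excludes the
    next transient's rising limb — or to the end of the trace for the last
    beat.  On that window a least-squares fit of ``A * exp(-t/τ) + c`` is
    performed (initialized from a log-linear fit of the window's early
    samples); the offset ``c`` absorbs the small residual baseline left by
    percentile ΔF/F0 normalization, which would otherwise bias the slope.
    Including the inter-beat baseline samples is what makes the offset
    identifiable.

    Returns ``(tau_ms, r_squared, (start, stop))`` with R² in the linear
    domain; ``tau_ms`` is ``nan`` (metric omitted) for non-decaying windows
    or fewer than 5 usable samples.
    """
    from scipy.optimize import curve_fit

    y = np.asarray(dff, dtype=float)
    t = np.asarray(time_ms, dtype=float)
    if y.size > 1:
        guard = int(np.ceil(guard_ms / (t[1] - t[0])))
    else:
        guard = 0
    stop = (next_peak_index - guard) if next_peak_index is not None else y.size
    start = peak_index + 1
    if stop - start < 5:
        return float("nan"), float("nan"), (start, stop)
    tt, yy = t[start:stop], y[start:stop]
    pos = yy > 0
    if pos.sum() < 5:
        return float("nan"), float("nan"), (start, stop)

    # initialize from the early, high-SNR part of the decay
    n_init = max(5, int(pos.sum()) // 2)
    slope, intercept = np.polyfit(tt[pos][:n_init], np.log(yy[pos][:n_init]), 1)
    if slope >= 0:
        return float("nan"), float("nan"), (start, stop)

    def model(x, a, tau, c):
        return a * np.exp(-(x - tt[0]) / tau) + c

    try:
        params, _ = curve_fit(model, tt, yy, p0=(yy[0], -1.0 / slope, 0.0),
                              maxfev=5000)
    except RuntimeError:
        return float("nan"), float("nan"), (start, stop)
    a, tau, c = params
    if not (0.0 < tau < 100.0 * (tt[-1] - tt[0])) or a <= 0:
        return float("nan"), float("nan"), (start, stop)
    fitted = model(tt, *params)
    ss_res = float(np.sum((yy - fitted) ** 2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(tau), r2, (start, stop)


def transient_metrics(traces: TraceSet, peaks: PeakSet) -> pd.DataFrame:
    """Per-peak FWHM and τ for every ROI.

    Returns a tidy table with columns ``roi_id, beat_index, peak_time_ms,
    peak_height_dff, fwhm_ms, tau_ms, tau_r2``; peaks whose FWHM or τ could
    not be measured carry ``NaN`` in that column.
    """
    records = []
    for roi, trace in zip(traces.roi_ids, traces.dff):
        idx = peaks.indices[roi]
        for b, pk in enumerate(idx):
            nxt = int(idx[b + 1]) if b + 1 < idx.size else None
            fwhm = compute_fwhm(traces.time_ms, trace, int(pk))
            tau, r2, _ = fit_decay_tau(traces.time_ms, trace, int(pk), nxt)
            records.append({
                "roi_id": roi,
                "beat_index": b,
                "peak_time_ms": float(traces.time_ms[pk]),
                "peak_height_dff": float(trace[pk]),
                "fwhm_ms": fwhm,
                "tau_ms": tau,
                "tau_r2": r2,
            })
    return pd.DataFrame.from_records(
        records, columns=["roi_id", "beat_index", "peak_time_ms",
                          "peak_height_dff", "fwhm_ms", "tau_ms", "tau_r2"])


def _cluster_beats(peaks: PeakSet) -> tuple[list[dict[str, float]], float]:
    """Group pooled peak times into beats.

    Pooled times are split wherever the gap exceeds half the median
    inter-beat interval; within a beat each ROI contributes the peak
    nearest the beat median (spurious doubles are dropped).
    """
    pooled = sorted(
        (t, roi) for roi in peaks.roi_ids for t in peaks.times_ms[roi])
    if len(pooled) < 2:
        raise ValueError("too few peaks to match beats across ROIs")
    intervals = np.concatenate([
        np.diff(peaks.times_ms[roi]) for roi in peaks.roi_ids
        if peaks.times_ms[roi].size > 1]) if any(
            peaks.times_ms[r].size > 1 for r in peaks.roi_ids) else np.array([])
    if intervals.size:
        gap = float(np.median(intervals)) / 2.0
    else:
        gap = float(pooled[-1][0] - pooled[0][0]) + 1.0  # single beat overall

    beats: list[list[tuple[float, str]]] = [[pooled[0]]]
    for prev, cur in zip(pooled, pooled[1:]):
        if cur[0] - prev[0] > gap:
            beats.append([])
        beats[-1].append(cur)

    matched = []
    for beat in beats:
        med = float(np.median([t for t, _ in beat]))
        per_roi: dict[str, float] = {}
        for t, roi in beat:
            if roi not in per_roi or abs(t - med) < abs(per_roi[roi] - med):
                per_roi[roi] = t
        matched.append(per_roi)
    return matched, gap


def tpa_mad(traces: TraceSet, peaks: PeakSet) -> SynchronicityResult:
    """Time-of-peak-arrival median absolute deviation across ROIs.

    Beats are matched across ROIs by clustering pooled peak times with a
    tolerance of half the median inter-beat interval.  For each beat seen
    by at least two ROIs, the raw MAD (no Gaussian consistency factor) of
    arrival times is computed; the result is the median over beats, in ms.
    Invariant under global time shifts and ROI permutations.
    """
    if traces.n_rois < 2:
        raise ValueError("synchronicity needs at least two ROIs")
    beats, _ = _cluster_beats(peaks)
    mads, rois_seen = [], set()
    for per_roi in beats:
        if len(per_roi) < 2:
            continue
        times = np.array(list(per_roi.values()))
        mads.append(float(np.median(np.abs(times - np.median(times)))))
        rois_seen.update(per_roi)
    if not mads:
        raise ValueError("no beat matched across at least two ROIs")
    return SynchronicityResult(
        tpa_mad_ms=float(np.median(mads)),
        n_beats_used=len(mads),
        n_rois_used=len(rois_seen),
    )
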