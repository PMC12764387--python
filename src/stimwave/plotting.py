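"""Plot helpers: polar rose of flow phases, trace and velocity plots.

Matplotlib is imported lazily so headless analysis runs never touch a
display backend.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_rose", "plot_traces", "plot_velocity_trace"]


def _axes(ax=None, polar: bool = False):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is not None:
        return ax
    _, ax = plt.subplots(subplot_kw={"projection": "polar"} if polar else None)
    return ax


def plot_rose(counts: np.ndarray, bin_edges_rad: np.ndarray, ax=None):
    """Polar rose histogram of flow-vector phases."""
    ax = _axes(ax, polar=True)
    centers = (bin_edges_rad[:-1] + bin_edges_rad[1:]) / 2
    widths = np.diff(bin_edges_rad)
    ax.bar(centers, counts, width=widths, bottom=0.0, alpha=0.7,
           edgecolor="black", linewidth=0.5)
    ax.set_title("Flow-vector phase")
    return ax


def plot_traces(traces, max_rois: int = 8, ax=None):
    """Overlay ΔF/F0 traces of up to ``max_rois`` ROIs."""
    ax = _axes(ax)
    for roi, trace in list(zip(traces.roi_ids, traces.dff))[:max_rois]:
        ax.plot(traces.time_ms / 1000.0, trace, label=roi, linewidth=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(r"$\Delta F / F_0$")
    ax.legend(fontsize="x-small", ncol=2)
    return ax


def plot_velocity_trace(trace, ax=None):
    """Pixel-velocity trace of a motion movie."""
    ax = _axes(ax)
    ax.plot(trace.time_ms / 1000.0, trace.speed_um_s, color="tab:red")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("mean pixel speed (μm/s)")
    return ax
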