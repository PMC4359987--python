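"""Figure export: auditory ROI and lateralized motor time courses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_timecourses"]


def plot_timecourses(report, path) -> None:
    """Two-panel figure: left-auditory ROI effect window (shaded) over the
    lateralized motor traces of both conditions, with mean response-time bars."""
    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    time = report.time_axis
    styles = {"compatible": "-", "incompatible": ":"}

    ax = axes[1]
    for cond, trace in report.lrp_traces.items():
        ax.plot(trace.time, trace.values, styles[cond], color="k", label=cond)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("time after prime onset (s)")
    ax.set_ylabel("motor lateralization (a.u.)")
    ax.legend(frameon=False)

    for cond, tc in report.roi_timecourses.items():
        axes[0].plot(time, tc, styles[cond], color="k", label=cond)
    axes[0].set_ylabel("left-auditory ROI (a.u.)")
    axes[0].axhline(0.0, color="gray", lw=0.5)
    axes[0].legend(frameon=False)
    if report.roi_cluster_extent is not None:
        for ax in axes:
            ax.axvspan(*report.roi_cluster_extent, color="0.85", zorder=0)
    lo = time[report.interest_slice][0]
    hi = max(v for v in report.lrp_landmarks["compatible"].values() if v) if any(
        report.lrp_landmarks["compatible"].values()
    ) else time[-1]
    axes[1].set_xlim(time[0], min(time[-1], hi + 0.5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
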