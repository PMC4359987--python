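"""Epoching, artifact rejection, notch filtering and planar gradients.

Artifact rejection replaces an interactive visual step with a deterministic
rule: a trial is rejected when the mean (across sensors) of its per-sensor
temporal variance exceeds a multiple of the median of that summary across
trials.  Condition labels are never consulted — rejection is blind to
condition by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic import SensorEpochs, SensorLayout

__all__ = [
    "Topography",
    "epoch",
    "reject_by_variance",
    "notch_filter",
    "planar_gradient",
]


@dataclass
class Topography:
    """One scalar per sensor (signal or t units) tied to a layout."""

    values: np.ndarray
    layout: SensorLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.layout.n_sensors:
            raise ValueError("topography length must equal the number of sensors")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("topography values must be finite")


def epoch(
    continuous: np.ndarray,
    fs: float,
    event_samples,
    tmin: float,
    tmax: float,
    layout: SensorLayout = None,
    trial_index=None,
) -> SensorEpochs:
    """Cut sensors x time continuous data into event-locked epochs.

    Each epoch starts at ``event + round(tmin * fs)`` and ends at
    ``event + round(tmax * fs)`` (inclusive).  Events whose window leaves the
    recording raise an error naming them.
    """
    continuous = np.asarray(continuous)
    if continuous.ndim != 2:
        raise ValueError("continuous data must be sensors x time")
    event_samples = np.asarray(event_samples, dtype=int)
    n_time = continuous.shape[1]
    off_lo = int(round(tmin * fs))
    off_hi = int(round(tmax * fs))
    starts = event_samples + off_lo
    stops = event_samples + off_hi
    bad = (starts < 0) | (stops >= n_time)
    if bad.any():
        raise ValueError(
            f"epoch window exceeds recording bounds for events "
            f"{event_samples[bad].tolist()}"
        )
    data = np.stack([continuous[:, a : b + 1] for a, b in zip(starts, stops)])
    time = (off_lo + np.arange(off_hi - off_lo + 1)) / fs
    if layout is None:
        # positions are irrelevant for epoching-only use; chain sensors
        n_sens = continuous.shape[0]
        adj = np.zeros((n_sens, n_sens), dtype=bool)
        for i in range(n_sens - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        layout = SensorLayout(
            positions=np.column_stack(
                [np.arange(n_sens), np.zeros(n_sens), np.zeros(n_sens)]
            ).astype(float),
            adjacency=adj,
        )
    if trial_index is None:
        trial_index = np.arange(len(event_samples))
    return SensorEpochs(
        data=data,
        time=time,
        fs=fs,
        layout=layout,
        trial_index=np.asarray(trial_index),
    )


def reject_by_variance(
    epochs: SensorEpochs, threshold_multiple: float = 5.0
) -> SensorEpochs:
    """Flag high-variance trials (amplitude-artifact proxy), blind to condition.

    The per-trial summary is the mean across sensors of the per-sensor
    temporal variance; trials whose summary exceeds
    ``threshold_multiple x median(summary)`` are marked rejected.
    """
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    summary = epochs.data.var(axis=2, ddof=0).mean(axis=1)
    cutoff = threshold_multiple * np.median(summary)
    rejected = summary > cutoff
    if rejected.all():
        raise ValueError("variance rule rejected every trial")
    out = epochs.copy()
    out.rejected = epochs.rejected | rejected
    return out


def notch_filter(
    epochs: SensorEpochs,
    band: tuple[float, float] = (48.5, 51.5),
    order: int = 4,
) -> SensorEpochs:
    """Zero-phase Butterworth band-stop filter (forward-backward).

    Epochs are padded internally by reflection (via ``filtfilt``'s odd
    padding), standing in for the long context segments a continuous
    recording would provide.
    """
    lo, hi = band
    nyq = epochs.fs / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} invalid for fs = {epochs.fs}")
    b, a = sps.butter(order, [lo / nyq, hi / nyq], btype="bandstop")
    out = epochs.copy()
    out.data = sps.filtfilt(b, a, epochs.data, axis=2)
    return out


def planar_gradient(topo: Topography, layout: SensorLayout = None) -> Topography:
    """Magnitude of the locally estimated spatial derivative of a topography.

    For every sensor, the topography over the sensor and its neighbors is fit
    with a linear model in local tangent-plane coordinates (the plane normal
    to the sensor's radial direction); the output is the Euclidean norm of
    the fitted slope.  This mimics the planar-gradient representation of
    axial gradiometer maps used for visualization: activity appears as a
    non-negative peak directly above its generator.
    """
    layout = layout if layout is not None else topo.layout
    pos = layout.positions
    center = pos.mean(axis=0)
    values = topo.values
    out = np.empty(layout.n_sensors)
    for i in range(layout.n_sensors):
        nbr = np.flatnonzero(layout.adjacency[i])
        if len(nbr) < 2:
            raise ValueError(f"sensor {i} has fewer than 2 neighbors")
        radial = pos[i] - center
        radial = radial / np.linalg.norm(radial)
        # tangent basis
        ref = np.array([0.0, 0.0, 1.0])
        if abs(radial @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(radial, ref)
        u /= np.linalg.norm(u)
        v = np.cross(radial, u)
        pts = np.concatenate([[i], nbr])
        rel = pos[pts] - pos[i]
        design = np.column_stack([np.ones(len(pts)), rel @ u, rel @ v])
        coef, *_ = np.linalg.lstsq(design, values[pts], rcond=None)
        out[i] = np.hypot(coef[1], coef[2])
    return Topography(values=out, layout=layout)
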