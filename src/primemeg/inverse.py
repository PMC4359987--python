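"""Minimum-norm source estimation, localizer statistics and ROI definition.

The inverse operator is the classical minimum-norm solution with an identity
source prior, ``W = L' (L L' + lambda I)^{-1}``: applied to sensor data it
returns the Tikhonov-regularized least-squares source estimate.  Auditory
regions of interest are defined from an independent localizer contrast by a
radius / top-N / largest-contiguous-cluster rule, and ROI time courses are
averaged after flipping each member by the sign of its localizer t-statistic
(a stand-in for opposite dipole orientations on facing gyral walls).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic import LeadField, adjacency_from_positions

__all__ = [
    "InverseOperator",
    "ROIDefinition",
    "minimum_norm_operator",
    "apply_inverse",
    "localizer_stats",
    "define_roi",
    "roi_timecourse",
    "default_lambda",
]

#: Sources are contiguous when closer than this multiple of the median
#: nearest-neighbor distance of the grid.
SOURCE_ADJACENCY_FACTOR = 1.5


@dataclass
class InverseOperator:
    weights: np.ndarray  # (n_sources, n_sensors)
    lambda_: float


@dataclass
class ROIDefinition:
    member_indices: np.ndarray  # indices into the source grid
    sign_flips: np.ndarray  # +/-1 per member
    peak_position: np.ndarray  # mm
    radius: float
    top_n: int


def default_lambda(leadfield: LeadField, snr: float = 3.0) -> float:
    """Regularization heuristic: trace(L L') / (n_sensors * snr^2)."""
    L = leadfield.gain
    return float(np.einsum("ij,ij->", L, L) / (L.shape[0] * snr**2))


def minimum_norm_operator(leadfield: LeadField, lambda_: float) -> InverseOperator:
    """W = L' (L L' + lambda I)^{-1}; lambda = 0 requires an invertible Gram."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    L = leadfield.gain
    gram = L @ L.T + lambda_ * np.eye(L.shape[0])
    try:
        np.linalg.cholesky(gram)  # fails on a singular/indefinite Gram
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "sensor-space Gram matrix is singular; use lambda_ > 0"
        ) from None
    inv = np.linalg.solve(gram, np.eye(L.shape[0]))
    return InverseOperator(weights=L.T @ inv, lambda_=float(lambda_))


def apply_inverse(op: InverseOperator, sensor_data: np.ndarray) -> np.ndarray:
    """Project sensor data (…, n_sensors, n_time) onto the source grid."""
    sensor_data = np.asarray(sensor_data)
    if sensor_data.shape[-2] != op.weights.shape[1]:
        raise ValueError(
            f"sensor dimension {sensor_data.shape[-2]} does not match the "
            f"operator ({op.weights.shape[1]} sensors)"
        )
    return np.einsum("qs,...st->...qt", op.weights, sensor_data)


def localizer_stats(
    window_values: np.ndarray, baseline_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t (and F = t^2) across subjects of baseline-corrected means.

    ``window_values`` and ``baseline_values`` are subjects x sources arrays of
    mean source amplitudes inside the localizer window and the baseline
    interval.  Sources with zero across-subject variance get t = 0 (with a
    warning) rather than an infinite statistic.
    """
    window_values = np.atleast_2d(np.asarray(window_values, dtype=float))
    baseline_values = np.atleast_2d(np.asarray(baseline_values, dtype=float))
    if window_values.shape != baseline_values.shape:
        raise ValueError("window and baseline arrays must have equal shapes")
    n = window_values.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    diff = window_values - baseline_values
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    zero = sd == 0.0
    if zero.any() and np.any(mean[zero] != 0.0):
        warnings.warn("zero across-subject variance at some sources; t set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    return t, t**2


def _connected_components(indices: np.ndarray, adjacency: np.ndarray) -> list:
    """Connected components of the sub-graph induced by ``indices``."""
    index_set = set(indices.tolist())
    seen = set()
    comps = []
    for start in indices:
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            comp.append(node)
            for nbr in np.flatnonzero(adjacency[node]):
                if nbr in index_set and nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        comps.append(np.array(sorted(comp)))
    return comps


def define_roi(
    F_map: np.ndarray,
    t_map: np.ndarray,
    source_positions: np.ndarray,
    radius: float = 25.0,
    top_n: int = 150,
    mask: np.ndarray = None,
    adjacency: np.ndarray = None,
) -> ROIDefinition:
    """Localizer-defined ROI: radius around the F peak, top-N by F, largest
    contiguous cluster, with per-member sign flips from the t map.

    ``mask`` restricts peak search and membership (e.g. one hemisphere).
    Ties with the N-th largest F are all included, keeping the rule
    order-independent.  If several contiguous components tie in size, the one
    containing the peak (else the one with the largest summed F) wins.
    """
    F_map = np.asarray(F_map, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    source_positions = np.asarray(source_positions, dtype=float)
    n = len(F_map)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    if not mask.any():
        raise ValueError("empty source mask")
    if adjacency is None:
        adjacency = adjacency_from_positions(
            source_positions, factor=SOURCE_ADJACENCY_FACTOR
        )
    masked_F = np.where(mask, F_map, -np.inf)
    peak = int(np.argmax(masked_F))
    dist = np.linalg.norm(source_positions - source_positions[peak], axis=1)
    in_radius = np.flatnonzero((dist <= radius) & mask)
    if len(in_radius) == 0:
        raise ValueError("no sources within radius of the localizer peak")
    if len(in_radius) > top_n:
        order = in_radius[np.argsort(F_map[in_radius])[::-1]]
        threshold_F = F_map[order[top_n - 1]]
        candidates = in_radius[F_map[in_radius] >= threshold_F]
    else:
        candidates = in_radius
    comps = _connected_components(candidates, adjacency)
    max_size = max(len(c) for c in comps)
    best = [c for c in comps if len(c) == max_size]
    if len(best) > 1:
        with_peak = [c for c in best if peak in c]
        chosen = with_peak[0] if with_peak else max(best, key=lambda c: F_map[c].sum())
    else:
        chosen = best[0]
    flips = np.where(t_map[chosen] >= 0.0, 1.0, -1.0)
    return ROIDefinition(
        member_indices=chosen,
        sign_flips=flips,
        peak_position=source_positions[peak],
        radius=float(radius),
        top_n=int(top_n),
    )


def roi_timecourse(source_data: np.ndarray, roi: ROIDefinition) -> np.ndarray:
    """Mean over ROI members of sign-flipped source time courses.

    ``source_data`` has sources on its second-to-last axis
    (…, n_sources, n_time).
    """
    if len(roi.member_indices) == 0:
        raise ValueError("empty ROI")
    picked = np.take(source_data, roi.member_indices, axis=-2)
    flips = roi.sign_flips.reshape((-1, 1))
    return np.mean(picked * flips, axis=-2)
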