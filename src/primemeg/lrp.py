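"""Lateralized motor time courses by the double-subtraction method.

Per hemisphere, the mean hand-knob source signal over right-hand trials is
subtracted from the mean over left-hand trials; the hemispheric difference of
those two lateralized signals is the motor analogue of the lateralized
readiness potential (LRP).  The raw subtraction order is arbitrary, so the
trace is plotted/analyzed under an explicit sign convention: lateralization
in favor of the executed response is negative near the time of the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LateralizedTimecourse",
    "lateralized_timecourse",
    "smooth_boxcar",
    "phase_landmarks",
    "compare_latencies",
]


@dataclass
class LateralizedTimecourse:
    condition: str  # "compatible" | "incompatible"
    values: np.ndarray
    time: np.ndarray
    sign_convention: str = "executed-negative"


def lateralized_timecourse(
    left_hemi_left_hand: np.ndarray,
    left_hemi_right_hand: np.ndarray,
    right_hemi_left_hand: np.ndarray,
    right_hemi_right_hand: np.ndarray,
    time: np.ndarray,
    condition: str,
    response_time: float = None,
) -> LateralizedTimecourse:
    """Double-subtracted motor lateralization from four trial-mean traces.

    Inputs are the trial-averaged hand-knob source signals, split by
    hemisphere and by executed hand.  Per hemisphere the right-hand mean is
    subtracted from the left-hand mean; the final trace is the left- minus
    right-hemispheric difference.  If ``response_time`` (s, same clock as
    ``time``) is given, the trace is sign-flipped, if needed, so that its
    mean within +/-50 ms of the response is negative — the executed-response
    lateralization convention.
    """
    traces = [
        np.asarray(x, dtype=float)
        for x in (
            left_hemi_left_hand,
            left_hemi_right_hand,
            right_hemi_left_hand,
            right_hemi_right_hand,
        )
    ]
    if any(tr.shape != traces[0].shape for tr in traces):
        raise ValueError("all four traces must have identical shapes")
    if any(tr.size == 0 for tr in traces):
        raise ValueError("a hand/hemisphere cell has no data")
    lh = traces[0] - traces[1]
    rh = traces[2] - traces[3]
    values = lh - rh
    if response_time is not None:
        time = np.asarray(time)
        near = (time >= response_time - 0.05) & (time <= response_time + 0.05)
        if near.any() and values[near].mean() > 0:
            values = -values
    return LateralizedTimecourse(
        condition=condition, values=values, time=np.asarray(time)
    )


def smooth_boxcar(values: np.ndarray, fs: float, kernel_ms: float = 20.0) -> np.ndarray:
    """Centered moving average with a square kernel.

    Even-width kernels use the classic centered form (half-weight end taps
    over width + 1 samples), which keeps the filter symmetric — a linear
    trend passes through unchanged.  Edges are normalized by the truncated
    window weight.
    """
    values = np.asarray(values, dtype=float)
    width = max(int(round(kernel_ms * fs / 1000.0)), 1)
    if width > values.shape[-1]:
        raise ValueError("kernel longer than the trace")
    if width % 2:
        kernel = np.ones(width)
    else:
        kernel = np.ones(width + 1)
        kernel[0] = kernel[-1] = 0.5
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def _zero_crossings(values: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Times of true sign changes; zero runs between opposite signs count
    once (at their midpoint), flat segments do not."""
    s = np.sign(values)
    nz = np.flatnonzero(s != 0)
    crossings = []
    for i, j in zip(nz[:-1], nz[1:]):
        if s[i] == s[j]:
            continue
        if j == i + 1:  # interpolate between adjacent samples
            frac = values[i] / (values[i] - values[j])
            crossings.append(time[i] + frac * (time[j] - time[i]))
        else:  # a run of exact zeros separates the signs
            crossings.append(0.5 * (time[i + 1] + time[j - 1]))
    return np.sort(np.asarray(crossings))


def phase_landmarks(
    trace: LateralizedTimecourse,
    target_onset: float,
    response_time: float,
    rel_threshold: float = 0.2,
) -> dict:
    """Landmark latencies of a (smoothed) lateralization trace.

    * ``phase1_peak_t`` — first local extremum after target onset whose sign
      matches the prime-driven initial lateralization (negative for the
      compatible condition, positive for the incompatible one, under the
      executed-negative convention);
    * ``reversal_t`` — the zero crossing following that extremum;
    * ``final_convergence_t`` — the last zero crossing before the response.

    Peaks smaller than ``rel_threshold`` times the trace's absolute maximum
    are ignored.  Missing landmarks are reported as ``None``, never raised.
    """
    v = np.asarray(trace.values, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    expected_sign = -1.0 if trace.condition == "compatible" else 1.0
    floor = rel_threshold * np.max(np.abs(v)) if np.any(v) else np.inf

    landmarks = {"phase1_peak_t": None, "reversal_t": None, "final_convergence_t": None}
    dv = np.diff(v)
    extrema = np.flatnonzero(np.sign(dv[:-1]) * np.sign(dv[1:]) < 0) + 1
    for i in extrema:
        if t[i] <= target_onset or t[i] >= response_time:
            continue
        if expected_sign * v[i] > floor:
            landmarks["phase1_peak_t"] = float(t[i])
            crossings = _zero_crossings(v, t)
            after = crossings[crossings > t[i]]
            if len(after):
                landmarks["reversal_t"] = float(after[0])
            break
    crossings = _zero_crossings(v, t)
    before_rt = crossings[(crossings < response_time) & (crossings > target_onset)]
    if len(before_rt):
        landmarks["final_convergence_t"] = float(before_rt[-1])
    return landmarks


def compare_latencies(
    auditory_cluster_extent: tuple, compatible_landmarks: dict
) -> dict:
    """Order the auditory-effect onset against the final motor reversal.

    ``auditory_cluster_extent`` is (t_start, t_end) of the significant
    auditory cluster (or None when absent).  Returns the two latencies in ms
    and whether the auditory effect onset *strictly* precedes the compatible
    trace's final reversal toward the executed response; "undetermined" when
    either landmark is missing.
    """
    out = {
        "auditory_onset_ms": None,
        "final_reversal_ms": None,
        "auditory_precedes_final_reversal": "undetermined",
    }
    if auditory_cluster_extent is not None:
        out["auditory_onset_ms"] = 1000.0 * float(auditory_cluster_extent[0])
    conv = compatible_landmarks.get("final_convergence_t")
    if conv is not None:
        out["final_reversal_ms"] = 1000.0 * float(conv)
    if out["auditory_onset_ms"] is not None and out["final_reversal_ms"] is not None:
        out["auditory_precedes_final_reversal"] = bool(
            out["auditory_onset_ms"] < out["final_reversal_ms"]
        )
    return out
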