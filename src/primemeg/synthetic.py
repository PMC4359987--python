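"""Synthetic data generator for a motor-priming / sensory-attenuation MEG study.

This module produces seeded behavioral trial tables, sensor layouts, toy lead
fields and sensor epochs that embody the statistical structure the analysis
pipeline assumes:

* a negative compatibility effect (NCE): responses to compatibly primed
  targets are slower and more error prone than to incompatibly primed ones;
* a condition-dependent criterion shift in a two-interval loudness judgment
  (stronger bias to call the first tone softer after compatible priming),
  with discriminability (d') equal across conditions;
* tone-evoked biphasic responses (M100-like) in bilateral auditory sources
  at both tone onsets;
* a prime-locked transient in the *left* auditory source, present only on
  compatible trials, inside a configurable latency window;
* two-phase, prime-driven lateralization of motor hand-area sources that
  converges on the executed response at movement time;
* spatially correlated Gaussian sensor noise and an optional 50-Hz line
  component.

Everything is deterministic given a :class:`SimConfig` (including its seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimConfig",
    "SensorLayout",
    "LeadField",
    "SensorEpochs",
    "generate_behavior",
    "generate_prime_recognition",
    "generate_layout",
    "default_source_grid",
    "generate_lead_field",
    "generate_epochs",
    "trial_event_times",
    "write_trials_tsv",
    "read_trials_tsv",
    "save_dataset",
    "load_dataset",
]

CONDITIONS = ("compatible", "incompatible")

#: Trial-table columns, in the order they are written to TSV.
TRIAL_COLUMNS = [
    "subject_id",
    "condition",
    "prime_direction",
    "target_direction",
    "response_hand",
    "rt",
    "target_response_correct",
    "tone2_class",
    "loudness_response",
]


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Design constants and effect sizes of the simulated experiment.

    Timing defaults follow the modeled paradigm: a 200-ms prime-target SOA,
    tones 50 ms and 1,150 ms after the button press (100 ms duration), and a
    600-Hz sampling rate.  Behavioral effect sizes default to a 46-ms RT
    slowing on compatible trials, d' = 2.25 in the loudness judgment and a
    criterion of 0.2 (compatible) vs 0.0 (incompatible).  The prime-locked
    auditory effect is injected 387-477 ms after prime onset.
    """

    n_subjects: int = 15
    n_trials_per_condition: int = 192
    fs: float = 600.0
    prime_target_soa: float = 0.2
    tone1_delay_after_press: float = 0.05
    tone2_delay_after_press: float = 1.15
    tone_duration: float = 0.1
    rt_mean_incompatible: float = 0.357
    rt_nce_shift: float = 0.046  # added to compatible-trial RT means
    rt_sd: float = 0.06
    rt_shift: float = 0.15  # location shift of the log-normal RT law
    rt_max: float = 1.2  # responses slower than this count as misses
    error_rate_by_condition: tuple[float, float] = (0.07, 0.035)
    dprime_loudness: float = 2.25
    criterion_by_condition: tuple[float, float] = (0.2, 0.0)
    auditory_effect_window: tuple[float, float] = (0.387, 0.477)
    auditory_effect_amplitude: float = 6.0
    tone_response_amplitude: float = 10.0
    motor_amplitude: float = 6.0
    motor_phase1_window: tuple[float, float] = (0.25, 0.45)
    motor_phase2_window: tuple[float, float] = (0.45, 0.60)
    noise_sd: float = 0.008
    spatial_noise_correlation: float = 0.6
    line_noise_amplitude: float = 0.0
    line_noise_freq: float = 50.0
    epoch_tmin: float = -0.5
    epoch_post_tone2: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            raise ConfigError("n_subjects and n_trials_per_condition must be >= 1")
        if self.fs <= 0:
            raise ConfigError("fs must be > 0")
        for name in (
            "prime_target_soa",
            "tone1_delay_after_press",
            "tone2_delay_after_press",
            "tone_duration",
            "rt_mean_incompatible",
            "rt_sd",
            "rt_max",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("error_rate_by_condition",):
            lo, hi = 0.0, 1.0
            for p in getattr(self, name):
                if not (lo <= p <= hi):
                    raise ConfigError(f"{name} entries must be probabilities")
        if not (0.0 <= self.spatial_noise_correlation <= 1.0):
            raise ConfigError("spatial_noise_correlation must lie in [0, 1]")
        for name in (
            "auditory_effect_window",
            "motor_phase1_window",
            "motor_phase2_window",
        ):
            a, b = getattr(self, name)
            if not a < b:
                raise ConfigError(f"{name} must satisfy start < end")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def epoch_tmax(self) -> float:
        """Epoch end: covers tone 2 plus margin for the slowest allowed RT."""
        return (
            self.prime_target_soa
            + self.rt_max
            + self.tone2_delay_after_press
            + self.epoch_post_tone2
        )


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class SensorLayout:
    """Sensor positions on a spherical cap with a neighborhood relation."""

    positions: np.ndarray  # (n_sensors, 3)
    adjacency: np.ndarray  # (n_sensors, n_sensors) bool, symmetric, irreflexive

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class LeadField:
    """Toy forward model: sensors x sources gain with source coordinates."""

    gain: np.ndarray  # (n_sensors, n_sources)
    source_positions: np.ndarray  # (n_sources, 3), mm, MNI-like
    source_labels: list = field(default_factory=list)

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    def label_index(self, label: str) -> int:
        try:
            return self.source_labels.index(label)
        except ValueError:
            raise KeyError(f"no source labeled {label!r}") from None


@dataclass
class SensorEpochs:
    """Epoched sensor data: trials x sensors x time, prime-locked."""

    data: np.ndarray  # (n_trials, n_sensors, n_time)
    time: np.ndarray  # (n_time,), seconds relative to prime onset
    fs: float
    layout: SensorLayout
    trial_index: np.ndarray  # (n_trials,) indices into the trial table
    rejected: np.ndarray = None  # (n_trials,) bool

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(self.data.shape[0], dtype=bool)
        if len(self.trial_index) != self.data.shape[0]:
            raise ValueError("trial_index length must match number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "SensorEpochs":
        return SensorEpochs(
            data=self.data.copy(),
            time=self.time.copy(),
            fs=self.fs,
            layout=self.layout,
            trial_index=self.trial_index.copy(),
            rejected=self.rejected.copy(),
        )


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match (mu, sigma) of exp(N(mu, sigma^2)) to the given moments."""
    var = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - var / 2.0
    return mu, np.sqrt(var)


def _draw_rts(rng, n: int, mean: float, sd: float, shift: float) -> np.ndarray:
    m0 = mean - shift
    if m0 <= 0:
        raise ConfigError("rt mean must exceed the log-normal location shift")
    mu, sigma = _lognormal_params(m0, sd)
    return shift + rng.lognormal(mu, sigma, size=n)


def generate_behavior(config: SimConfig) -> pd.DataFrame:
    """Simulate the behavioral trial table for all subjects.

    Per subject and condition, ``n_trials_per_condition`` trials are drawn.
    Reaction times follow a shifted log-normal law whose mean is raised by
    ``rt_nce_shift`` on compatible trials.  Loudness judgments come from an
    equal-variance SDT observer: with the second tone physically softer the
    decision variable is N(+d'/2, 1), otherwise N(-d'/2, 1), and the observer
    reports "first_louder" (equivalently: second tone softer) when the
    variable exceeds the condition's criterion.  Hence
    ``P(first_louder | tone2 softer) = Phi(d'/2 - c)`` and
    ``P(first_louder | tone2 louder) = Phi(-d'/2 - c)``: a positive criterion
    is a bias toward reporting the first tone as the softer.  Trials with an
    incorrect (or too slow) target response carry no loudness judgment.
    """
    rng = np.random.default_rng(config.seed)
    d = config.dprime_loudness
    rows = []
    for subject in range(config.n_subjects):
        for ci, condition in enumerate(CONDITIONS):
            n = config.n_trials_per_condition
            prime = rng.integers(0, 2, size=n)  # 0 = left, 1 = right
            target = prime if condition == "compatible" else 1 - prime
            rt_mean = config.rt_mean_incompatible
            if condition == "compatible":
                rt_mean += config.rt_nce_shift
            rt = _draw_rts(rng, n, rt_mean, config.rt_sd, config.rt_shift)
            wrong = rng.random(n) < config.error_rate_by_condition[ci]
            correct = ~wrong & (rt <= config.rt_max)
            hand = np.where(correct, target, 1 - target)
            tone2_softer = rng.random(n) < 0.5
            dv = rng.normal(np.where(tone2_softer, d / 2.0, -d / 2.0), 1.0)
            first_louder = dv > config.criterion_by_condition[ci]
            for i in range(n):
                rows.append(
                    (
                        subject,
                        condition,
                        "left" if prime[i] == 0 else "right",
                        "left" if target[i] == 0 else "right",
                        "left" if hand[i] == 0 else "right",
                        rt[i],
                        bool(correct[i]),
                        "softer" if tone2_softer[i] else "louder",
                        (
                            ("first_louder" if first_louder[i] else "first_softer")
                            if correct[i]
                            else ""
                        ),
                    )
                )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    trials.index.name = "trial"
    return trials


def generate_prime_recognition(
    n_subjects: int,
    n_trials: int = 100,
    dprime_by_subject=None,
    seed: int = 0,
) -> list:
    """Simulate the forced-choice prime-recognition control task.

    Returns a list of ``(stimulus_labels, responses)`` string-array pairs, one
    per subject.  ``dprime_by_subject`` (default all zero: chance performance)
    sets each subject's true sensitivity; a clearly positive value models a
    participant with residual prime awareness.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if dprime_by_subject is None:
        dprime_by_subject = np.zeros(n_subjects)
    dprime_by_subject = np.asarray(dprime_by_subject, dtype=float)
    out = []
    for s in range(n_subjects):
        d = dprime_by_subject[s]
        stim = np.where(rng.random(n_trials) < 0.5, "left", "right")
        mu = np.where(stim == "left", d / 2.0, -d / 2.0)
        resp = np.where(rng.normal(mu, 1.0) > 0.0, "left", "right")
        out.append((stim, resp))
    return out


# ---------------------------------------------------------------------------
# Layout, source grid, lead field
# ---------------------------------------------------------------------------

#: Neighborhood rule: sensors closer than this multiple of the median
#: nearest-neighbor distance are adjacent.
ADJACENCY_FACTOR = 1.4

#: Softening constant (mm) of the lead-field kernel 1 / (delta^2 + d^2).
LEADFIELD_SOFTENING_MM = 30.0


def _fibonacci_cap(n: int, radius: float, cos_theta_min: float) -> np.ndarray:
    """Quasi-uniform points on a spherical cap (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (1.0 - cos_theta_min) * (i + 0.5) / n  # cos(theta), uniform
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    return radius * pts


def adjacency_from_positions(
    positions: np.ndarray, factor: float = ADJACENCY_FACTOR
) -> np.ndarray:
    """Distance-based neighborhood: d <= factor x median nearest-neighbor d."""
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    nn = dist.min(axis=1)
    cutoff = factor * np.median(nn)
    adj = dist <= cutoff
    np.fill_diagonal(adj, False)
    return adj


def generate_layout(n_sensors: int, seed: int = 0) -> SensorLayout:
    """Quasi-uniform sensors on a spherical cap around the head.

    The cap (radius 110 mm, centered 10 mm above the head origin) covers the
    upper ~120 degrees so temporal sources remain visible.  A small seeded
    jitter breaks exact lattice symmetries.  Sensors are neighbors iff their
    distance is at most ``ADJACENCY_FACTOR`` times the median nearest-neighbor
    distance; every sensor is guaranteed at least one neighbor by linking it
    to its nearest sensor otherwise.
    """
    if n_sensors < 4:
        raise ConfigError("n_sensors must be >= 4")
    rng = np.random.default_rng(seed)
    pts = _fibonacci_cap(n_sensors, 110.0, cos_theta_min=-0.5)
    # jitter tangentially (~2 mm) and re-project to the sphere
    pts = pts + rng.normal(0.0, 2.0, size=pts.shape)
    pts *= 110.0 / np.linalg.norm(pts, axis=1, keepdims=True)
    pts = pts + np.array([0.0, 0.0, 10.0])
    adj = adjacency_from_positions(pts)
    # guarantee >= 1 neighbor
    isolated = ~adj.any(axis=1)
    if isolated.any():
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(dist, np.inf)
        for i in np.flatnonzero(isolated):
            j = int(np.argmin(dist[i]))
            adj[i, j] = adj[j, i] = True
    return SensorLayout(positions=pts, adjacency=adj)


#: Labeled sources (MNI-like mm), mirror-symmetric by construction.
SPECIAL_SOURCES = {
    "left-auditory": (-55.0, -38.0, 11.0),
    "right-auditory": (55.0, -38.0, 11.0),
    "left-hand-knob": (-33.0, -18.0, 60.0),
    "right-hand-knob": (33.0, -18.0, 60.0),
}


def default_source_grid(spacing: float = 20.0) -> tuple[np.ndarray, list]:
    """Regular mirror-symmetric cortical-shell grid plus four labeled sources.

    Grid points at the given spacing are kept inside a spherical *shell*
    (45-70 mm from a point just above the head origin, z >= -15): like a
    cortical sheet, the model has no deep midline sources, which keeps
    minimum-norm statistics of superficial activity from aliasing onto the
    center of the head.  The labeled auditory and hand-knob sources are
    appended at mirrored coordinates near their anatomical locations.
    """
    half = np.arange(spacing / 2.0, 80.0, spacing)
    xs = np.concatenate([-half[::-1], half])  # symmetric about x = 0
    ys = np.arange(-80.0, 80.1, spacing) - 15.0
    zs = np.arange(-15.0, 80.1, spacing)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    center = np.array([0.0, -15.0, 15.0])
    radii = np.linalg.norm(pts - center, axis=1)
    keep = (radii <= 70.0) & (radii >= 45.0)
    pts = pts[keep]
    labels = [None] * len(pts)
    special = np.array(list(SPECIAL_SOURCES.values()))
    pts = np.vstack([pts, special])
    labels.extend(SPECIAL_SOURCES.keys())
    return pts, labels


def generate_lead_field(
    layout: SensorLayout,
    source_positions: np.ndarray,
    source_labels=None,
    softening: float = LEADFIELD_SOFTENING_MM,
) -> LeadField:
    """Distance-decay gain: gain(s, q) = 1 / (softening^2 + ||p_s - p_q||^2).

    The kernel is smooth, monotone in distance and full rank in practice; it
    deliberately ignores dipole orientation (orientation effects enter the
    pipeline only through the ROI sign-flip mechanism).
    """
    source_positions = np.asarray(source_positions, dtype=float)
    if source_positions.ndim != 2 or source_positions.shape[0] < 1:
        raise ValueError("need at least one source position")
    diff = layout.positions[:, None, :] - source_positions[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if np.any(d2 == 0.0):
        raise ValueError("coincident sensor and source position (singular kernel)")
    gain = 1.0 / (softening**2 + d2)
    labels = list(source_labels) if source_labels is not None else [None] * len(
        source_positions
    )
    return LeadField(gain=gain, source_positions=source_positions, source_labels=labels)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------


def _hann_bump(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Hann window supported on [start, end], peak amplitude 1."""
    out = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[inside] - start) / (end - start)))
    return out


def _m100(t: np.ndarray, onset: float) -> np.ndarray:
    """Biphasic tone-evoked template peaking ~100 ms after onset."""
    x = t - onset
    return np.exp(-((x - 0.10) ** 2) / (2 * 0.025**2)) - 0.5 * np.exp(
        -((x - 0.19) ** 2) / (2 * 0.04**2)
    )


def _ramp(t: np.ndarray, start: float, peak: float, hold: float, end: float) -> np.ndarray:
    """Smooth rise from `start` to 1 at `peak`, hold, then fall to 0 at `end`."""
    out = np.zeros_like(t)
    if peak <= start:  # degenerate: step at peak
        out[t >= peak] = 1.0
    else:
        up = (t >= start) & (t < peak)
        out[up] = 0.5 * (1.0 - np.cos(np.pi * (t[up] - start) / (peak - start)))
        out[t >= peak] = 1.0
    dn = (t > hold) & (t <= end)
    out[dn] = 0.5 * (1.0 + np.cos(np.pi * (t[dn] - hold) / (end - hold)))
    out[t > end] = 0.0
    return out


def epoch_time_axis(config: SimConfig) -> np.ndarray:
    """The prime-locked time axis used by :func:`generate_epochs`."""
    n_time = int(round((config.epoch_tmax - config.epoch_tmin) * config.fs)) + 1
    return config.epoch_tmin + np.arange(n_time) / config.fs


def trial_event_times(config: SimConfig, trials: pd.DataFrame) -> pd.DataFrame:
    """Press, tone-1 and tone-2 onset times (s, prime-locked) per trial."""
    press = config.prime_target_soa + trials["rt"].to_numpy(float)
    return pd.DataFrame(
        {
            "press": press,
            "tone1": press + config.tone1_delay_after_press,
            "tone2": press + config.tone2_delay_after_press,
        },
        index=trials.index,
    )


def _noise_color_matrix(layout: SensorLayout, rho: float) -> np.ndarray:
    """Symmetric square root of a Gaussian distance-decay sensor covariance.

    The length scale is set so that nearest-neighbor sensors correlate at
    ``rho``; rho = 0 yields white noise.  The Gaussian kernel is positive
    semidefinite for any length scale.
    """
    if rho <= 0.0:
        return np.eye(layout.n_sensors)
    rho = min(rho, 0.99)
    dist = np.linalg.norm(
        layout.positions[:, None, :] - layout.positions[None, :, :], axis=-1
    )
    nn = np.where(np.eye(len(dist), dtype=bool), np.inf, dist).min(axis=1)
    ell = np.median(nn) / np.sqrt(-2.0 * np.log(rho))
    cov = np.exp(-(dist**2) / (2.0 * ell**2))
    w, v = np.linalg.eigh(cov)
    return (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T


def generate_epochs(
    config: SimConfig,
    trials: pd.DataFrame,
    leadfield: LeadField,
    layout: SensorLayout,
    dtype=np.float64,
) -> SensorEpochs:
    """Project per-trial source waveforms through the lead field, add noise.

    Only trials with a correct target response receive an epoch (error trials
    ended without a tone and are excluded from all MEG analyses).  Source
    activity comprises (i) tone-evoked biphasic responses in both auditory
    sources at both tone onsets, (ii) the compatible-only transient in the
    left auditory source inside ``auditory_effect_window``, and (iii)
    hand-knob activity contralateral to the currently prepared hand with a
    prime-driven first phase, a reversed second phase and convergence on the
    executed hand at movement time.
    """
    if layout.n_sensors != leadfield.n_sensors:
        raise ValueError("layout and lead field disagree on the number of sensors")
    correct = trials[trials["target_response_correct"]]
    n_trials = len(correct)
    if n_trials == 0:
        raise ValueError("no correct-response trials to epoch")
    time = epoch_time_axis(config)
    n_time = len(time)

    active = [
        leadfield.label_index(lbl)
        for lbl in ("left-auditory", "right-auditory", "left-hand-knob", "right-hand-knob")
    ]
    g_active = leadfield.gain[:, active]  # (n_sensors, 4)

    # Seed derivation: deterministic for identical inputs, decorrelated across
    # disjoint trial subsets (e.g. per-subject calls with one shared config).
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7, int(correct.index.min()), n_trials])
    )
    color = _noise_color_matrix(layout, config.spatial_noise_correlation)
    events = trial_event_times(config, correct)
    b1 = _hann_bump(time, *config.motor_phase1_window)
    b2 = _hann_bump(time, *config.motor_phase2_window)
    effect = config.auditory_effect_amplitude * _hann_bump(
        time, *config.auditory_effect_window
    )

    press_t = events["press"].to_numpy()
    tone1_t = events["tone1"].to_numpy()
    tone2_t = events["tone2"].to_numpy()
    is_compat = (correct["condition"] == "compatible").to_numpy()
    e_sign = np.where(correct["response_hand"].to_numpy() == "left", 1.0, -1.0)
    p_sign = np.where(correct["prime_direction"].to_numpy() == "left", 1.0, -1.0)

    data = np.empty((n_trials, layout.n_sensors, n_time), dtype=dtype)
    src = np.empty((4, n_time))
    for k in range(n_trials):
        aud = config.tone_response_amplitude * (
            _m100(time, tone1_t[k]) + _m100(time, tone2_t[k])
        )
        src[0] = aud + effect if is_compat[k] else aud  # left auditory
        src[1] = aud  # right auditory
        # motor preparation: u(t) in [-1, 1], +1 = left hand prepared;
        # activity is contralateral to the prepared hand
        press = press_t[k]
        b3 = _ramp(
            time,
            min(config.motor_phase2_window[1], press - 0.12),
            press,
            press + 0.05,
            press + 0.25,
        )
        u = p_sign[k] * (b1 - b2) + e_sign[k] * b3
        src[2] = -0.5 * config.motor_amplitude * u  # left hemi = right hand
        src[3] = 0.5 * config.motor_amplitude * u
        data[k] = g_active @ src

    if config.noise_sd > 0:
        # batched spatially correlated noise, chunked to bound memory
        chunk = max(1, int(2e7) // (n_time * layout.n_sensors))
        scaled_color = (config.noise_sd * color).astype(dtype)
        for lo in range(0, n_trials, chunk):
            hi = min(lo + chunk, n_trials)
            white = rng.standard_normal(
                (layout.n_sensors, (hi - lo) * n_time), dtype=dtype
            )
            colored = scaled_color @ white
            data[lo:hi] += colored.reshape(
                layout.n_sensors, hi - lo, n_time
            ).transpose(1, 0, 2)
    if config.line_noise_amplitude > 0:
        line_coupling = rng.uniform(0.5, 1.5, size=layout.n_sensors)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
        carrier = 2.0 * np.pi * config.line_noise_freq * time
        for k in range(n_trials):
            data[k] += config.line_noise_amplitude * np.outer(
                line_coupling, np.sin(carrier + phases[k])
            )

    return SensorEpochs(
        data=data,
        time=time,
        fs=config.fs,
        layout=layout,
        trial_index=correct.index.to_numpy(),
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_trials_tsv(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=True, index_label="trial")


def read_trials_tsv(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t", index_col="trial")
    trials["loudness_response"] = trials["loudness_response"].fillna("")
    return trials


def save_dataset(
    path, epochs: SensorEpochs, leadfield: LeadField = None
) -> None:
    """Write epochs (+ layout, optionally the lead field) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("time", data=epochs.time)
        f.create_dataset("sensor_pos", data=epochs.layout.positions)
        f.create_dataset("adjacency", data=epochs.layout.adjacency)
        f.create_dataset("trial_index", data=epochs.trial_index)
        f.create_dataset("rejected", data=epochs.rejected)
        f.attrs["fs"] = epochs.fs
        f.attrs["units"] = "arbitrary sensor units; time in s, positions in mm"
        if leadfield is not None:
            f.create_dataset("gain", data=leadfield.gain)
            f.create_dataset("source_pos", data=leadfield.source_positions)
            labels = [l if l is not None else "" for l in leadfield.source_labels]
            f.create_dataset("source_labels", data=np.array(labels, dtype="S"))


def load_dataset(path) -> tuple[SensorEpochs, LeadField]:
    """Read the HDF5 container written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        layout = SensorLayout(
            positions=f["sensor_pos"][()], adjacency=f["adjacency"][()].astype(bool)
        )
        epochs = SensorEpochs(
            data=f["epochs"][()],
            time=f["time"][()],
            fs=float(f.attrs["fs"]),
            layout=layout,
            trial_index=f["trial_index"][()],
            rejected=f["rejected"][()].astype(bool),
        )
        leadfield = None
        if "gain" in f:
            labels = [
                s.decode() if s else None for s in f["source_labels"][()]
            ]
            leadfield = LeadField(
                gain=f["gain"][()],
                source_positions=f["source_pos"][()],
                source_labels=labels,
            )
    return epochs, leadfield
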