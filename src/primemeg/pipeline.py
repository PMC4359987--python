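"""End-to-end analysis pipeline over synthetic datasets.

Stages, in order: behavioral simulation -> prime-awareness exclusion ->
behavioral SDT/RT contrasts -> epoch generation with artifact rejection (and
an optional notch filter) -> sensor-level cluster permutation test ->
source localization, localizer-defined auditory ROIs and the ROI cluster
test -> topography-correlation test -> lateralized motor time courses with
latency ordering -> RT-matched ROI re-analysis.  Every stochastic step is
seeded from the run configuration; two runs with the same config produce
identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import behavior, cluster, inverse, lrp, preprocess, rtmatch, synthetic
from .behavior import AwarenessTest
from .cluster import PermutationSpec
from .synthetic import SimConfig

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "exclude_aware_subjects",
    "calibrate_null",
]

log = logging.getLogger("primemeg")


@dataclass
class RunConfig:
    """Hierarchical configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    perm: PermutationSpec = field(default_factory=PermutationSpec)
    interest_window_start: float = 0.3  # s after prime (100 ms post target)
    localizer_window: tuple[float, float] = (0.05, 0.15)  # s after tone 2
    localizer_baseline: float = 0.05  # s before tone 2
    roi_radius: float = 25.0  # mm
    roi_top_n: int = 150
    n_sensors: int = 32
    source_grid_spacing: float = 20.0  # mm
    smoothing_kernel_ms: float = 20.0
    variance_threshold: float = 5.0
    inverse_snr: float = 3.0
    rt_match_alpha: float = 0.05
    n_aware_extra: int = 0  # extra simulated subjects with prime awareness
    aware_dprime: float = 0.8
    n_recognition_trials: int = 200
    awareness_resamples: int = 100_000
    run_awareness_stage: bool = True
    run_rt_match_stage: bool = True
    run_sensor_cluster_stage: bool = True

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]

    def to_yaml(self) -> str:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return yaml.safe_dump(
            {"sim": plain(self.sim), "perm": plain(self.perm), **{
                k: plain(v)
                for k, v in dataclasses.asdict(self).items()
                if k not in ("sim", "perm")
            }},
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        sim_raw = raw.pop("sim", {})
        perm_raw = raw.pop("perm", {})
        for key in ("error_rate_by_condition", "criterion_by_condition",
                    "auditory_effect_window", "motor_phase1_window",
                    "motor_phase2_window"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        for key in ("localizer_window",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=SimConfig(**sim_raw), perm=PermutationSpec(**perm_raw), **raw)


@dataclass
class RunReport:
    config: RunConfig
    config_hash: str
    excluded_subjects: list
    behavioral_table: pd.DataFrame
    behavioral_contrasts: pd.DataFrame
    sensor_clusters: list
    sensor_cluster_extent: tuple  # (t_start, t_end) or None
    roi_left: object
    roi_right: object
    roi_clusters: list
    roi_cluster_extent: tuple  # or None
    rt_matched_clusters: list
    rt_matched_extent: tuple
    rt_match_table: pd.DataFrame
    topo_correlation: tuple  # (t, df, p, mean_z)
    lrp_traces: dict  # condition -> LateralizedTimecourse (smoothed)
    lrp_landmarks: dict  # condition -> landmark dict
    latency_ordering: dict
    roi_timecourses: dict  # condition -> grand-average left-ROI trace
    time_axis: np.ndarray
    interest_slice: slice

    def significant(self, clusters: list) -> list:
        alpha = self.config.perm.cluster_alpha / 2.0
        return [c for c in clusters if c.p_value is not None and c.p_value < alpha]

    def summary_text(self) -> str:
        buf = io.StringIO()
        w = buf.write
        w(f"primemeg run (config {self.config_hash})\n")
        w(f"excluded subjects: {self.excluded_subjects}\n\n")
        w("behavioral contrasts (one-tailed paired t):\n")
        w(self.behavioral_contrasts.to_string(index=False))
        w("\n\n")
        for name, clusters, extent in [
            ("sensor-level", self.sensor_clusters, self.sensor_cluster_extent),
            ("left-ROI", self.roi_clusters, self.roi_cluster_extent),
            ("RT-matched left-ROI", self.rt_matched_clusters, self.rt_matched_extent),
        ]:
            sig = self.significant(clusters)
            w(f"{name} clusters: {len(clusters)} found, {len(sig)} significant")
            if extent is not None:
                w(f"; leading extent {extent[0]*1000:.0f}-{extent[1]*1000:.0f} ms")
            if clusters:
                best = min(clusters, key=lambda c: c.p_value)
                w(f"; min p = {best.p_value:.4g}")
            w("\n")
        t, df, p, mean_z = self.topo_correlation
        w(f"\ntopography correlation: mean z = {mean_z:.3f}, "
          f"t({df}) = {t:.2f}, p = {p:.4g}\n")
        w(f"latency ordering: {self.latency_ordering}\n")
        return buf.getvalue()

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# primemeg config {self.config_hash}\n"

        def tsv(frame, name):
            with open(outdir / name, "w") as f:
                f.write(header)
                frame.to_csv(f, sep="\t")

        tsv(self.behavioral_table, "behavior_subjects.tsv")
        tsv(self.behavioral_contrasts.set_index("contrast"), "behavior_contrasts.tsv")
        tsv(self.rt_match_table, "rt_match.tsv")
        tsv(cluster_table(self.sensor_clusters, self.time_axis), "clusters_sensor.tsv")
        tsv(cluster_table(self.roi_clusters, self.time_axis), "clusters_roi.tsv")
        tsv(
            cluster_table(self.rt_matched_clusters, self.time_axis),
            "clusters_roi_rtmatched.tsv",
        )
        with open(outdir / "summary.txt", "w") as f:
            f.write(header + self.summary_text())
        with open(outdir / "config.yaml", "w") as f:
            f.write(self.config.to_yaml())


def cluster_table(clusters: list, time_axis: np.ndarray) -> pd.DataFrame:
    rows = []
    for c in clusters:
        t0, t1, chans = cluster.report_cluster_extent(c, time_axis)
        rows.append(
            {
                "sign": "+" if c.sign > 0 else "-",
                "mass": c.mass,
                "p": c.p_value,
                "t_start": t0,
                "t_end": t1,
                "n_channels": len(chans),
                "channels": ",".join(str(ch) for ch in sorted(chans)),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["sign", "mass", "p", "t_start", "t_end", "n_channels", "channels"]
    )
    frame.index.name = "cluster"
    return frame


def exclude_aware_subjects(
    subject_tests: dict, trials: pd.DataFrame
) -> tuple[pd.DataFrame, list]:
    """Drop subjects whose awareness test flagged above-chance recognition."""
    excluded = sorted(s for s, t in subject_tests.items() if t.excluded)
    filtered = trials[~trials["subject_id"].isin(excluded)]
    if filtered.empty:
        raise ValueError("all subjects excluded by the awareness test")
    return filtered, excluded


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _window_slice(time: np.ndarray, start: float, end: float) -> slice:
    idx = np.flatnonzero((time >= start) & (time <= end))
    return slice(int(idx[0]), int(idx[-1]) + 1)


def _subject_pass(cfg, sub_trials, leadfield, layout, interest):
    """Generate and preprocess one subject, returning the per-subject pieces
    the group stages need."""
    sim = cfg.sim
    epochs = synthetic.generate_epochs(
        sim, sub_trials, leadfield, layout, dtype=np.float32
    )
    epochs = preprocess.reject_by_variance(epochs, cfg.variance_threshold)
    if sim.line_noise_amplitude > 0:
        epochs = preprocess.notch_filter(epochs)
    keep = ~epochs.rejected
    data = epochs.data  # rejected trials get zero weight below
    meta = sub_trials.loc[epochs.trial_index[keep]]
    time = epochs.time
    n_sens, n_time = data.shape[1], data.shape[2]

    # trial-mean evokeds per condition and per (condition, hand) cell, as one
    # weighted matmul over the (trials, sensors*time) view
    masks = {}
    for cond in synthetic.CONDITIONS:
        cmask = keep & (sub_trials.loc[epochs.trial_index, "condition"] == cond).to_numpy()
        masks[cond] = cmask
        for hand in ("left", "right"):
            m = cmask & (
                sub_trials.loc[epochs.trial_index, "response_hand"] == hand
            ).to_numpy()
            if not m.any():
                raise ValueError(f"no trials for condition={cond}, hand={hand}")
            masks[(cond, hand)] = m
    weights = np.stack([masks[k] / masks[k].sum() for k in masks]).astype(data.dtype)
    means = (weights @ data.reshape(data.shape[0], -1)).reshape(
        len(masks), n_sens, n_time
    )
    means = dict(zip(masks, means.astype(np.float64)))
    evoked = {cond: means[cond] for cond in synthetic.CONDITIONS}
    cell_evoked = {k: v for k, v in means.items() if isinstance(k, tuple)}
    keep_idx = np.flatnonzero(keep)

    # tone-2-locked localizer: fixed-length segments around each trial's tone2
    events = synthetic.trial_event_times(sim, meta)
    fs = sim.fs
    pre = int(round(cfg.localizer_baseline * fs))
    post = int(round(cfg.localizer_window[1] * fs))
    seg = np.zeros((n_sens, pre + post + 1))
    tone2_samp = np.round((events["tone2"].to_numpy() - time[0]) * fs).astype(int)
    for k, s0 in zip(keep_idx, tone2_samp):
        seg += data[k, :, s0 - pre : s0 + post + 1]
    seg /= len(keep_idx)
    seg_time = np.arange(-pre, post + 1) / fs
    win = _window_slice(seg_time, *cfg.localizer_window)
    base = _window_slice(seg_time, -cfg.localizer_baseline, 0.0)
    localizer_topo = seg[:, win].mean(axis=1) - seg[:, base].mean(axis=1)

    # per-trial sensor data inside the interest window, for RT matching
    per_trial = np.ascontiguousarray(data[:, :, interest], dtype=np.float64)[keep_idx]
    return {
        "evoked": evoked,
        "cell_evoked": cell_evoked,
        "localizer_topo": localizer_topo,
        "localizer_seg": seg,
        "seg_time": seg_time,
        "per_trial": per_trial,
        "meta": meta,
        "time": time,
        "press_mean": {
            cond: float(events["press"][meta["condition"] == cond].mean())
            for cond in synthetic.CONDITIONS
        },
    }


def run_pipeline(cfg: RunConfig) -> RunReport:
    t_start = _time.time()
    sim = cfg.sim
    n_total = sim.n_subjects + cfg.n_aware_extra
    log.info("stage simulate: %d subjects (%d with prime awareness)",
             n_total, cfg.n_aware_extra)
    trials = synthetic.generate_behavior(sim.replace(n_subjects=n_total))

    # --- awareness exclusion -------------------------------------------------
    excluded = []
    if cfg.run_awareness_stage:
        dps = np.zeros(n_total)
        if cfg.n_aware_extra:
            dps[-cfg.n_aware_extra :] = cfg.aware_dprime
        recognition = synthetic.generate_prime_recognition(
            n_total, cfg.n_recognition_trials, dps, seed=sim.seed + 1
        )
        tests = {
            s: behavior.awareness_resampling_test(
                resp, stim, cfg.awareness_resamples, seed=sim.seed + 100 + s
            )
            for s, (stim, resp) in enumerate(recognition)
        }
        trials, excluded = exclude_aware_subjects(tests, trials)
        log.info("awareness exclusion: removed %s", excluded)
    subjects = sorted(trials["subject_id"].unique())

    # --- behavior ------------------------------------------------------------
    behavioral_table, contrasts = behavior.behavioral_summary(trials)

    # --- forward/inverse model ----------------------------------------------
    layout = synthetic.generate_layout(cfg.n_sensors, seed=sim.seed)
    source_pos, source_labels = synthetic.default_source_grid(cfg.source_grid_spacing)
    leadfield = synthetic.generate_lead_field(layout, source_pos, source_labels)
    lam = inverse.default_lambda(leadfield, cfg.inverse_snr)
    op = inverse.minimum_norm_operator(leadfield, lam)
    src_adj = synthetic.adjacency_from_positions(
        source_pos, factor=inverse.SOURCE_ADJACENCY_FACTOR
    )

    # --- interest window: 300 ms after prime up to the mean tone-1 onset -----
    time_axis = synthetic.epoch_time_axis(sim)
    correct = trials[trials["target_response_correct"]]
    events_all = synthetic.trial_event_times(sim, correct)
    tone1_mean = float(events_all["tone1"].mean())
    interest = _window_slice(time_axis, cfg.interest_window_start, tone1_mean)
    interest_time = time_axis[interest]

    # --- per-subject generation + preprocessing ------------------------------
    per_subject = {}
    for s in subjects:
        per_subject[s] = _subject_pass(
            cfg, trials[trials["subject_id"] == s], leadfield, layout, interest
        )
    log.info("interest window: %.3f-%.3f s after prime",
             interest_time[0], interest_time[-1])

    # --- sensor-level cluster test ------------------------------------------
    ev = {
        cond: np.stack([per_subject[s]["evoked"][cond] for s in subjects])
        for cond in synthetic.CONDITIONS
    }
    sensor_clusters = []
    sensor_extent = None
    if cfg.run_sensor_cluster_stage:
        sensor_clusters = cluster.permutation_test(
            ev["compatible"][:, :, interest],
            ev["incompatible"][:, :, interest],
            layout.adjacency,
            cfg.perm,
        )
        sig = [c for c in sensor_clusters
               if c.p_value < cfg.perm.cluster_alpha / 2.0]
        if sig:
            t0, t1, _ = cluster.report_cluster_extent(sig[0], interest_time)
            sensor_extent = (t0, t1)
    log.info("sensor clusters: %d", len(sensor_clusters))

    # --- source localizer + ROIs --------------------------------------------
    loc_win_vals, loc_base_vals = [], []
    for s in subjects:
        seg_src = inverse.apply_inverse(op, per_subject[s]["localizer_seg"])
        seg_time = per_subject[s]["seg_time"]
        win = _window_slice(seg_time, *cfg.localizer_window)
        base = _window_slice(seg_time, -cfg.localizer_baseline, 0.0)
        loc_win_vals.append(seg_src[:, win].mean(axis=1))
        loc_base_vals.append(seg_src[:, base].mean(axis=1))
    t_map, F_map = inverse.localizer_stats(
        np.stack(loc_win_vals), np.stack(loc_base_vals)
    )
    roi_left = inverse.define_roi(
        F_map, t_map, source_pos, cfg.roi_radius, cfg.roi_top_n,
        mask=source_pos[:, 0] < 0, adjacency=src_adj,
    )
    roi_right = inverse.define_roi(
        F_map, t_map, source_pos, cfg.roi_radius, cfg.roi_top_n,
        mask=source_pos[:, 0] > 0, adjacency=src_adj,
    )

    # --- ROI cluster test (left auditory) ------------------------------------
    def roi_weight(roi):
        w = (roi.sign_flips[:, None] * op.weights[roi.member_indices]).mean(axis=0)
        return w  # (n_sensors,)

    w_left = roi_weight(roi_left)
    roi_tc = {
        cond: np.stack([w_left @ per_subject[s]["evoked"][cond] for s in subjects])
        for cond in synthetic.CONDITIONS
    }
    single = np.zeros((1, 1), dtype=bool)
    roi_clusters = cluster.permutation_test(
        roi_tc["compatible"][:, None, interest],
        roi_tc["incompatible"][:, None, interest],
        single,
        cfg.perm,
    )
    roi_extent = None
    sig = [c for c in roi_clusters if c.p_value < cfg.perm.cluster_alpha / 2.0]
    if sig:
        t0, t1, _ = cluster.report_cluster_extent(sig[0], interest_time)
        roi_extent = (t0, t1)
    log.info("ROI clusters: %d (extent %s)", len(roi_clusters), roi_extent)

    # --- topography correlation ----------------------------------------------
    if sensor_extent is not None:
        topo_slice = _window_slice(time_axis, *sensor_extent)
    elif roi_extent is not None:
        topo_slice = _window_slice(time_axis, *roi_extent)
    else:
        topo_slice = interest
    effect_topos = np.stack(
        [
            (
                per_subject[s]["evoked"]["compatible"]
                - per_subject[s]["evoked"]["incompatible"]
            )[:, topo_slice].mean(axis=1)
            for s in subjects
        ]
    )
    localizer_topos = np.stack(
        [per_subject[s]["localizer_topo"] for s in subjects]
    )
    topo_corr = cluster.topo_correlation_test(effect_topos, localizer_topos)

    # --- lateralized motor time courses --------------------------------------
    idx_lk = leadfield.label_index("left-hand-knob")
    idx_rk = leadfield.label_index("right-hand-knob")
    traces, landmarks = {}, {}
    press_mean = {
        cond: float(np.mean([per_subject[s]["press_mean"][cond] for s in subjects]))
        for cond in synthetic.CONDITIONS
    }
    for cond in synthetic.CONDITIONS:
        cells = {}
        for hand in ("left", "right"):
            cell = np.mean(
                [per_subject[s]["cell_evoked"][(cond, hand)] for s in subjects],
                axis=0,
            )
            src = op.weights[[idx_lk, idx_rk]] @ cell
            cells[hand] = src
        trace = lrp.lateralized_timecourse(
            cells["left"][0], cells["right"][0],
            cells["left"][1], cells["right"][1],
            time_axis, cond, response_time=press_mean[cond],
        )
        trace.values = lrp.smooth_boxcar(
            trace.values, sim.fs, cfg.smoothing_kernel_ms
        )
        traces[cond] = trace
        landmarks[cond] = lrp.phase_landmarks(
            trace, sim.prime_target_soa, press_mean[cond]
        )
    ordering = lrp.compare_latencies(roi_extent, landmarks["compatible"])

    # --- RT-matched re-analysis ----------------------------------------------
    rt_matched_clusters, rt_matched_extent = [], None
    rt_table = pd.DataFrame()
    if cfg.run_rt_match_stage:
        match_results, rts_by_subject = {}, {}
        matched_tc = {"compatible": [], "incompatible": []}
        for s in subjects:
            p = per_subject[s]
            is_comp = (p["meta"]["condition"] == "compatible").to_numpy()
            rts_a = p["meta"]["rt"].to_numpy()[is_comp]
            rts_b = p["meta"]["rt"].to_numpy()[~is_comp]
            res = rtmatch.match_subject(rts_a, rts_b, cfg.rt_match_alpha)
            match_results[s] = res
            rts_by_subject[s] = (rts_a, rts_b)
            tc = w_left @ p["per_trial"]  # (n_trials, interest bins)
            tc_a = tc[is_comp][res.retained_a]
            tc_b = tc[~is_comp][res.retained_b]
            matched_tc["compatible"].append(tc_a.mean(axis=0))
            matched_tc["incompatible"].append(tc_b.mean(axis=0))
        rt_table = rtmatch.matched_summary(match_results, rts_by_subject)
        rt_matched_clusters = cluster.permutation_test(
            np.stack(matched_tc["compatible"])[:, None, :],
            np.stack(matched_tc["incompatible"])[:, None, :],
            single,
            cfg.perm,
        )
        sig = [c for c in rt_matched_clusters
               if c.p_value < cfg.perm.cluster_alpha / 2.0]
        if sig:
            t0, t1, _ = cluster.report_cluster_extent(sig[0], interest_time)
            rt_matched_extent = (t0, t1)

    log.info("pipeline done in %.1f s", _time.time() - t_start)
    return RunReport(
        config=cfg,
        config_hash=cfg.config_hash(),
        excluded_subjects=excluded,
        behavioral_table=behavioral_table,
        behavioral_contrasts=contrasts,
        sensor_clusters=sensor_clusters,
        sensor_cluster_extent=sensor_extent,
        roi_left=roi_left,
        roi_right=roi_right,
        roi_clusters=roi_clusters,
        roi_cluster_extent=roi_extent,
        rt_matched_clusters=rt_matched_clusters,
        rt_matched_extent=rt_matched_extent,
        rt_match_table=rt_table,
        topo_correlation=topo_corr,
        lrp_traces=traces,
        lrp_landmarks=landmarks,
        latency_ordering=ordering,
        roi_timecourses={c: roi_tc[c].mean(axis=0) for c in synthetic.CONDITIONS},
        time_axis=time_axis,
        interest_slice=interest,
    )


def calibrate_null(
    n_replicates: int = 200,
    n_subjects: int = 12,
    n_channels: int = 30,
    n_bins: int = 100,
    spec: PermutationSpec = None,
    seed: int = 0,
) -> dict:
    """Family-wise false-positive rate of the cluster test under the null.

    Each replicate draws two independent white-noise condition arrays (no
    effect anywhere) on a chain-adjacent channel set and counts whether *any*
    cluster comes out significant at the two-tailed 5% family-wise level.
    Returns the empirical rate together with the binomial 95% CI around the
    nominal alpha.
    """
    spec = spec if spec is not None else PermutationSpec()
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_channels, n_channels), dtype=bool)
    for i in range(n_channels - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    alpha = spec.cluster_alpha
    hits = 0
    for r in range(n_replicates):
        a = rng.standard_normal((n_subjects, n_channels, n_bins))
        b = rng.standard_normal((n_subjects, n_channels, n_bins))
        rep_spec = dataclasses.replace(spec, seed=int(rng.integers(2**31)))
        clusters = cluster.permutation_test(a, b, adj, rep_spec)
        if any(c.p_value < alpha / 2.0 for c in clusters):
            hits += 1
    from scipy import stats as _st

    lo, hi = _st.binom.interval(0.95, n_replicates, alpha)
    return {
        "false_positive_rate": hits / n_replicates,
        "n_replicates": n_replicates,
        "nominal_alpha": alpha,
        "ci_low": lo / n_replicates,
        "ci_high": hi / n_replicates,
        "within_ci": lo <= hits <= hi,
    }
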