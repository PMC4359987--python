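"""Generator contracts: determinism, behavioral structure, layout/lead-field
geometry, and noiseless projection algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from primemeg import synthetic
from primemeg.synthetic import ConfigError, SimConfig

from conftest import make_trials


SMALL = SimConfig(n_subjects=2, n_trials_per_condition=24, seed=7)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_trials_per_condition": 0},
            {"fs": -1.0},
            {"error_rate_by_condition": (0.5, 1.5)},
            {"auditory_effect_window": (0.5, 0.4)},
            {"spatial_noise_correlation": 1.2},
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimConfig(**kwargs)

    def test_epoch_covers_tone2_plus_margin(self):
        cfg = SimConfig()
        assert cfg.epoch_tmax >= (
            cfg.prime_target_soa + cfg.rt_max + cfg.tone2_delay_after_press + 0.3
        )


class TestBehavior:
    def test_same_seed_identical_tables(self):
        a = synthetic.generate_behavior(SMALL)
        b = synthetic.generate_behavior(SMALL)
        pd.testing.assert_frame_equal(a, b)

    def test_trial_counts_and_condition_consistency(self):
        trials = synthetic.generate_behavior(SMALL)
        counts = trials.groupby(["subject_id", "condition"]).size()
        assert (counts == SMALL.n_trials_per_condition).all()
        compat = trials["condition"] == "compatible"
        same_dir = trials["prime_direction"] == trials["target_direction"]
        assert (compat == same_dir).all()
        assert (trials["rt"] > 0).all()

    def test_error_trials_carry_no_loudness_response(self):
        trials = synthetic.generate_behavior(
            SimConfig(n_subjects=2, n_trials_per_condition=200,
                      error_rate_by_condition=(0.3, 0.3), seed=3)
        )
        errors = trials[~trials["target_response_correct"]]
        assert len(errors) > 0
        assert (errors["loudness_response"] == "").all()
        ok = trials[trials["target_response_correct"]]
        assert ok["loudness_response"].isin(["first_louder", "first_softer"]).all()

    def test_rt_shift_recovered_at_large_n(self):
        cfg = SimConfig(n_subjects=4, n_trials_per_condition=2500, seed=5)
        trials = synthetic.generate_behavior(cfg)
        means = trials.groupby("condition")["rt"].mean()
        diff = means["compatible"] - means["incompatible"]
        # Monte-Carlo tolerance: ~3 x sqrt(2) x sd / sqrt(n_per_condition)
        tol = 3.0 * np.sqrt(2) * cfg.rt_sd / np.sqrt(10_000)
        assert diff == pytest.approx(cfg.rt_nce_shift, abs=tol)

    def test_observer_matches_closed_form_response_probabilities(self):
        # oracle: P(first_louder | tone2 class) = Phi(+/- d'/2 - c)
        d, c = 2.25, 0.2
        cfg = SimConfig(
            n_subjects=1, n_trials_per_condition=40_000, seed=9,
            dprime_loudness=d, criterion_by_condition=(c, 0.0),
            error_rate_by_condition=(0.0, 0.0),
        )
        trials = synthetic.generate_behavior(cfg)
        comp = trials[trials["condition"] == "compatible"]
        for cls, mu in (("softer", d / 2.0), ("louder", -d / 2.0)):
            sub = comp[comp["tone2_class"] == cls]
            p_hat = (sub["loudness_response"] == "first_louder").mean()
            p_true = stats.norm.cdf(mu - c)
            se = np.sqrt(p_true * (1 - p_true) / len(sub))
            assert p_hat == pytest.approx(p_true, abs=4 * se)


class TestLayout:
    def test_minimum_sensor_count_enforced(self):
        with pytest.raises(ConfigError):
            synthetic.generate_layout(3)

    def test_adjacency_symmetric_irreflexive_connected(self):
        for n in (4, 30):
            lay = synthetic.generate_layout(n, seed=2)
            adj = lay.adjacency
            assert (adj == adj.T).all()
            assert not adj.diagonal().any()
            assert adj.any(axis=1).all()

    def test_determinism(self):
        a = synthetic.generate_layout(30, seed=4)
        b = synthetic.generate_layout(30, seed=4)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.adjacency, b.adjacency)

    def test_neighbor_rule_matches_bruteforce_distances(self):
        lay = synthetic.generate_layout(30, seed=6)
        pos = lay.positions
        # independent pairwise-distance oracle
        nn = []
        for i in range(len(pos)):
            d = [np.linalg.norm(pos[i] - pos[j]) for j in range(len(pos)) if j != i]
            nn.append(min(d))
        cutoff = synthetic.ADJACENCY_FACTOR * np.median(nn)
        expected = np.zeros_like(lay.adjacency)
        for i in range(len(pos)):
            for j in range(len(pos)):
                if i != j and np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                    expected[i, j] = True
        # the generator may add links to rescue isolated sensors
        rescued = expected.any(axis=1)
        assert np.array_equal(lay.adjacency[rescued][:, rescued],
                              expected[rescued][:, rescued])


class TestLeadField:
    def test_matches_direct_kernel_evaluation(self, layout32, rng):
        pos = rng.uniform(-50, 50, size=(5, 3))
        lf = synthetic.generate_lead_field(layout32, pos)
        soft = synthetic.LEADFIELD_SOFTENING_MM
        for s in range(layout32.n_sensors):
            for q in range(5):
                d2 = np.sum((layout32.positions[s] - pos[q]) ** 2)
                assert lf.gain[s, q] == pytest.approx(1.0 / (soft**2 + d2), rel=1e-12)

    def test_closest_sensor_has_max_gain(self, layout32):
        # a source just beneath sensor 0
        target = layout32.positions[0] * 0.8
        lf = synthetic.generate_lead_field(layout32, target[None, :])
        assert np.argmax(lf.gain[:, 0]) == 0

    def test_mirror_symmetric_sources_give_mirrored_columns(self):
        pos = np.array(
            [[50.0, 0.0, 80.0], [-50.0, 0.0, 80.0], [0.0, 50.0, 80.0]]
        )
        lay = synthetic.SensorLayout(
            positions=pos, adjacency=np.ones((3, 3), bool) ^ np.eye(3, dtype=bool)
        )
        sources = np.array([[30.0, 0.0, 40.0], [-30.0, 0.0, 40.0]])
        lf = synthetic.generate_lead_field(lay, sources)
        # mirroring x swaps sensors 0<->1 and fixes sensor 2
        assert lf.gain[[0, 1, 2], 0] == pytest.approx(lf.gain[[1, 0, 2], 1])

    def test_coincident_sensor_source_rejected(self, layout32):
        with pytest.raises(ValueError, match="singular"):
            synthetic.generate_lead_field(layout32, layout32.positions[:1])


class TestEpochs:
    def test_determinism_bit_identical(self, layout32, leadfield32):
        trials = synthetic.generate_behavior(SMALL)
        a = synthetic.generate_epochs(SMALL, trials, leadfield32, layout32)
        b = synthetic.generate_epochs(SMALL, trials, leadfield32, layout32)
        assert np.array_equal(a.data, b.data)

    def test_noiseless_data_lies_in_active_gain_column_space(
        self, layout32, leadfield32
    ):
        cfg = SMALL.replace(noise_sd=0.0, line_noise_amplitude=0.0)
        trials = synthetic.generate_behavior(cfg).iloc[:3]
        ep = synthetic.generate_epochs(cfg, trials, leadfield32, layout32)
        cols = [
            leadfield32.label_index(l)
            for l in ("left-auditory", "right-auditory",
                      "left-hand-knob", "right-hand-knob")
        ]
        G = leadfield32.gain[:, cols]
        for k in range(ep.n_trials):
            sources, *_ = np.linalg.lstsq(G, ep.data[k], rcond=None)
            assert np.allclose(G @ sources, ep.data[k], atol=1e-12)

    def test_condition_difference_is_exactly_the_injected_transient(
        self, layout32, leadfield32
    ):
        # same RT/hand, motor silenced: compatible - incompatible must equal
        # the left-auditory gain column times the Hann-windowed transient
        cfg = SMALL.replace(noise_sd=0.0, motor_amplitude=0.0)
        rows = [
            (0, "compatible", "left", "left", "left", 0.4, True, "softer", "first_louder"),
            (0, "incompatible", "right", "left", "left", 0.4, True, "softer", "first_louder"),
        ]
        trials = make_trials(rows)
        ep = synthetic.generate_epochs(cfg, trials, leadfield32, layout32)
        diff = ep.data[0] - ep.data[1]
        t = ep.time
        a, b = cfg.auditory_effect_window
        bump = np.zeros_like(t)
        inside = (t >= a) & (t <= b)
        bump[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - a) / (b - a)))
        g = leadfield32.gain[:, leadfield32.label_index("left-auditory")]
        expected = cfg.auditory_effect_amplitude * np.outer(g, bump)
        assert np.allclose(diff, expected, atol=1e-10)

    def test_error_trials_get_no_epoch(self, layout32, leadfield32):
        trials = synthetic.generate_behavior(
            SMALL.replace(error_rate_by_condition=(0.5, 0.5))
        )
        ep = synthetic.generate_epochs(SMALL, trials, leadfield32, layout32)
        assert ep.n_trials == trials["target_response_correct"].sum()
        assert trials.loc[ep.trial_index, "target_response_correct"].all()

    def test_sensor_mismatch_rejected(self, leadfield32):
        lay = synthetic.generate_layout(8, seed=0)
        trials = synthetic.generate_behavior(SMALL)
        with pytest.raises(ValueError, match="sensors"):
            synthetic.generate_epochs(SMALL, trials, leadfield32, lay)


class TestIO:
    def test_trials_tsv_roundtrip(self, tmp_path):
        trials = synthetic.generate_behavior(SMALL)
        path = tmp_path / "trials.tsv"
        synthetic.write_trials_tsv(trials, path)
        back = synthetic.read_trials_tsv(path)
        pd.testing.assert_frame_equal(trials, back)

    def test_hdf5_roundtrip(self, tmp_path, layout32, leadfield32):
        trials = synthetic.generate_behavior(SMALL)
        ep = synthetic.generate_epochs(SMALL, trials, leadfield32, layout32)
        path = tmp_path / "data.h5"
        synthetic.save_dataset(path, ep, leadfield32)
        ep2, lf2 = synthetic.load_dataset(path)
        assert np.array_equal(ep.data, ep2.data)
        assert np.array_equal(ep.time, ep2.time)
        assert ep2.fs == ep.fs
        assert np.array_equal(ep.trial_index, ep2.trial_index)
        assert np.array_equal(leadfield32.gain, lf2.gain)
        assert lf2.source_labels == leadfield32.source_labels
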