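"""Cluster permutation machinery against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from primemeg import cluster
from primemeg.cluster import PermutationSpec


def bruteforce_clusters(t_map, adjacency, threshold):
    """Independent oracle: BFS over supra-threshold (channel, bin) cells."""
    n_ch, n_time = t_map.shape
    out = []
    for sign in (1, -1):
        mask = sign * t_map >= threshold
        seen = set()
        for start in zip(*np.nonzero(mask)):
            if start in seen:
                continue
            comp, queue = [], [start]
            seen.add(start)
            while queue:
                c, t = queue.pop()
                comp.append((c, t))
                neighbors = [(c, t - 1), (c, t + 1)] + [
                    (c2, t) for c2 in np.flatnonzero(adjacency[c])
                ]
                for nb in neighbors:
                    if (
                        0 <= nb[1] < n_time
                        and 0 <= nb[0] < n_ch
                        and mask[nb]
                        and nb not in seen
                    ):
                        seen.add(nb)
                        queue.append(nb)
            out.append((frozenset(comp), sum(t_map[c, t] for c, t in comp), sign))
    return out


def bruteforce_permutation_p(cond_a, cond_b, adjacency, alpha=0.05):
    """Exhaustive sign-flip oracle for small subject counts."""
    diff = cond_a - cond_b
    n = diff.shape[0]
    df = n - 1
    thr = stats.t.ppf(1 - alpha / 2, df)

    def tmap(d):
        m, sd = d.mean(0), d.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sd == 0, 0.0, m / (sd / np.sqrt(n)))

    observed = bruteforce_clusters(tmap(diff), adjacency, thr)
    max_pos, min_neg = [], []
    for signs in itertools.product([1.0, -1.0], repeat=n):
        cl = bruteforce_clusters(
            tmap(diff * np.array(signs)[:, None, None]), adjacency, thr
        )
        masses = [m for _, m, _ in cl]
        max_pos.append(max([m for m in masses if m > 0], default=0.0))
        min_neg.append(min([m for m in masses if m < 0], default=0.0))
    ps = {}
    for members, mass, sign in observed:
        if sign > 0:
            ps[members] = np.mean([m >= mass for m in max_pos])
        else:
            ps[members] = np.mean([m <= mass for m in min_neg])
    return ps


class TestPairedTMap:
    def test_identical_conditions_zero(self, rng):
        a = rng.standard_normal((5, 3, 7))
        assert np.all(cluster.paired_t_map(a, a.copy()) == 0.0)

    def test_known_effect_size(self):
        # across-subject differences with mean 1 and sd 1 at every bin -> t=4
        diffs = np.array([1.0 + v for v in
                          [-1.5, -0.5, 0.5, 1.5] * 4])
        diffs = diffs * (1.0 / diffs.std(ddof=1))
        diffs += 1.0 - diffs.mean()
        n = len(diffs)
        a = np.tile(diffs[:, None, None], (1, 2, 3))
        t = cluster.paired_t_map(a, np.zeros_like(a))
        expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
        assert np.allclose(t, expected)
        assert expected == pytest.approx(4.0)

    def test_antisymmetric_under_swap(self, rng):
        a = rng.standard_normal((6, 2, 5))
        b = rng.standard_normal((6, 2, 5))
        assert np.allclose(cluster.paired_t_map(a, b), -cluster.paired_t_map(b, a))


class TestFindClusters:
    def test_zero_map_no_clusters(self):
        adj = np.zeros((3, 3), bool)
        assert cluster.find_clusters(np.zeros((3, 4)), adj, df=10) == []

    def test_isolated_bin(self):
        t = np.zeros((2, 3))
        t[0, 1] = 3.0
        adj = np.zeros((2, 2), bool)
        (res,) = cluster.find_clusters(t, adj, df=10)
        assert res.mass == 3.0 and res.sign == 1 and res.members == {(0, 1)}

    def test_worked_two_sensor_example(self):
        # critical t at df=18 is ~2.10
        t = np.array([[2.5, 2.5, 0.0], [2.5, 0.0, -2.6]])
        adj = np.array([[False, True], [True, False]])
        res = cluster.find_clusters(t, adj, df=18)
        pos = [c for c in res if c.sign > 0]
        neg = [c for c in res if c.sign < 0]
        assert len(pos) == 1 and len(neg) == 1
        assert pos[0].members == {(0, 0), (0, 1), (1, 0)}
        assert pos[0].mass == pytest.approx(7.5)
        assert neg[0].members == {(1, 2)}
        assert neg[0].mass == pytest.approx(-2.6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        n_ch, n_time = 6, 12
        t = rng.standard_normal((n_ch, n_time)) * 2.0
        pos = rng.uniform(0, 10, size=(n_ch, 3))
        from primemeg.synthetic import adjacency_from_positions

        adj = adjacency_from_positions(pos)
        df = 9
        thr = stats.t.ppf(0.975, df)
        got = {
            (frozenset(c.members), round(c.mass, 9), c.sign)
            for c in cluster.find_clusters(t, adj, df)
        }
        want = {
            (m, round(mass, 9), s) for m, mass, s in bruteforce_clusters(t, adj, thr)
        }
        assert got == want


class TestPermutationTest:
    def test_identical_conditions_empty(self, rng):
        a = rng.standard_normal((5, 2, 3))
        assert cluster.permutation_test(a, a.copy(), np.zeros((2, 2), bool)) == []

    def test_exhaustive_matches_bruteforce_exactly(self, rng):
        a = rng.standard_normal((5, 2, 3)) + 1.0
        b = rng.standard_normal((5, 2, 3))
        adj = np.array([[False, True], [True, False]])
        spec = PermutationSpec(n_permutations=32, exhaustive="always", seed=0)
        res = cluster.permutation_test(a, b, adj, spec)
        oracle = bruteforce_permutation_p(a, b, adj)
        assert len(res) == len(oracle)
        for c in res:
            assert c.p_value == pytest.approx(oracle[frozenset(c.members)], abs=1e-12)

    def test_random_mode_within_monte_carlo_error(self, rng):
        a = rng.standard_normal((5, 2, 3)) + 1.2
        b = rng.standard_normal((5, 2, 3))
        adj = np.array([[False, True], [True, False]])
        oracle = bruteforce_permutation_p(a, b, adj)
        res = cluster.permutation_test(
            a, b, adj, PermutationSpec(n_permutations=4000,
                                       exhaustive="never", seed=3)
        )
        for c in res:
            p_exact = oracle[frozenset(c.members)]
            se = np.sqrt(p_exact * (1 - p_exact) / 4000) + 1e-9
            assert c.p_value == pytest.approx(p_exact, abs=3 * se + 1.0 / 4000)

    def test_global_swap_mirrors_signs_and_pvalues(self, rng):
        a = rng.standard_normal((5, 2, 4)) + 0.8
        b = rng.standard_normal((5, 2, 4))
        adj = np.array([[False, True], [True, False]])
        spec = PermutationSpec(n_permutations=32, exhaustive="always")
        res_ab = cluster.permutation_test(a, b, adj, spec)
        res_ba = cluster.permutation_test(b, a, adj, spec)
        key = lambda res: sorted(
            (frozenset(c.members), -c.sign, round(c.p_value, 12)) for c in res
        )
        assert key(res_ab) == [
            (m, s, p) for m, s, p in sorted(
                (frozenset(c.members), c.sign, round(c.p_value, 12))
                for c in res_ba
            )
        ]

    def test_scaling_a_real_effect_never_hurts(self, rng):
        adj = np.zeros((1, 1), bool)
        effect = np.zeros((8, 1, 20))
        effect[:, 0, 5:12] = 1.0
        noise = rng.standard_normal((8, 1, 20))
        spec = PermutationSpec(n_permutations=256, exhaustive="always")
        ps = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            res = cluster.permutation_test(
                noise + scale * effect, np.zeros_like(effect), adj, spec
            )
            sig = min((c.p_value for c in res if c.sign > 0), default=1.0)
            ps.append(sig)
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_minimum_reportable_p(self, rng):
        a = rng.standard_normal((10, 1, 10)) + 5.0
        b = rng.standard_normal((10, 1, 10))
        res = cluster.permutation_test(
            a, b, np.zeros((1, 1), bool),
            PermutationSpec(n_permutations=200, exhaustive="never", seed=0),
        )
        assert min(c.p_value for c in res) >= 1.0 / 200


class TestTopoCorrelation:
    def test_null_topographies_near_zero_z(self, rng):
        a = rng.standard_normal((12, 30))
        b = rng.standard_normal((12, 30))
        t, df, p, mean_z = cluster.topo_correlation_test(a, b)
        assert df == 11
        assert abs(mean_z) < 0.2

    def test_shared_structure_detected(self, rng):
        base = rng.standard_normal((10, 30))
        eff = base + 0.7 * rng.standard_normal((10, 30))
        t, df, p, mean_z = cluster.topo_correlation_test(eff, base)
        assert t > 0 and p < 0.01 and mean_z > 0.3

    def test_fisher_z_of_half_and_degenerate_variance(self):
        # construct 4 subjects with identical r = 0.5
        x = np.array([1.0, -1.0, 2.0, -2.0, 0.5])
        y_unit = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        y_unit = y_unit - y_unit.mean()
        x_c = x - x.mean()
        y_orth = y_unit - (y_unit @ x_c) / (x_c @ x_c) * x_c
        r_target = 0.5
        y = r_target * x_c / np.linalg.norm(x_c) + np.sqrt(
            1 - r_target**2
        ) * y_orth / np.linalg.norm(y_orth)
        a = np.tile(x, (4, 1))
        b = np.tile(y, (4, 1))
        with pytest.warns(UserWarning):
            t, df, p, mean_z = cluster.topo_correlation_test(a, b)
        assert mean_z == pytest.approx(np.arctanh(0.5), abs=1e-9)
        assert t == np.inf and p == 0.0

    def test_zero_variance_topo_names_subject(self):
        a = np.ones((3, 5))
        b = np.random.default_rng(0).standard_normal((3, 5))
        with pytest.raises(ValueError, match="subject 0"):
            cluster.topo_correlation_test(a, b)


class TestReportExtent:
    def test_single_bin(self):
        c = cluster.ClusterResult(
            channels=np.array([2]), bins=np.array([3]), mass=2.5, sign=1
        )
        time = np.linspace(0, 1, 11)
        t0, t1, chans = cluster.report_cluster_extent(c, time)
        assert t0 == t1 == pytest.approx(time[3])
        assert chans == {2}

    def test_invariant_to_channel_relabeling(self):
        c1 = cluster.ClusterResult(
            channels=np.array([0, 1]), bins=np.array([2, 4]), mass=5.0, sign=1
        )
        c2 = cluster.ClusterResult(
            channels=np.array([7, 3]), bins=np.array([2, 4]), mass=5.0, sign=1
        )
        time = np.linspace(0, 1, 6)
        assert cluster.report_cluster_extent(c1, time)[:2] == \
            cluster.report_cluster_extent(c2, time)[:2]
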