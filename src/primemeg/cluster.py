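"""Spatiotemporal cluster-based permutation statistics.

Inference follows the max-statistic scheme: first-level paired t-values are
thresholded two-tailed, supra-threshold (channel, time-bin) elements are
grouped into clusters that are connected through sensor adjacency (same time
bin) or temporal succession (same channel, consecutive bins), and each
cluster's mass (summed t) is compared against the permutation distribution of
the maximum cluster mass of its own sign, obtained by flipping each subject's
condition pair independently with probability 1/2.  Positive and negative
clusters are each tested at half the cluster alpha, the two-tailed reading of
a 5% family-wise level.

When ``2^n_subjects <= n_permutations`` the flip space is enumerated
exhaustively and the p-values are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ClusterResult",
    "PermutationSpec",
    "paired_t_map",
    "find_clusters",
    "permutation_test",
    "topo_correlation_test",
    "report_cluster_extent",
]


@dataclass
class ClusterResult:
    channels: np.ndarray  # per member
    bins: np.ndarray  # per member (time-bin index)
    mass: float  # sum of first-level t over members
    sign: int  # +1 or -1
    p_value: float = None

    @property
    def members(self) -> set:
        return set(zip(self.channels.tolist(), self.bins.tolist()))

    @property
    def size(self) -> int:
        return len(self.channels)


@dataclass
class PermutationSpec:
    n_permutations: int = 500
    first_level_alpha: float = 0.05  # two-tailed, per (channel, bin)
    cluster_alpha: float = 0.05  # two-tailed, family-wise
    seed: int = 0
    exhaustive: str = "auto"  # "auto" | "always" | "never"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for a in (self.first_level_alpha, self.cluster_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("alphas must lie in (0, 1)")


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """Paired t across subjects at every (channel, time) bin; zero-variance
    bins yield t = 0."""
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition arrays must have identical shapes")
    if cond_a.shape[0] < 2:
        raise ValueError("need at least two subjects")
    diff = cond_a - cond_b
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd == 0.0, 0.0, mean / (sd / np.sqrt(n)))
    return t


class _SpatioTemporalGraph:
    """Sparse adjacency over (channel, time-bin) nodes: channel neighbors at
    the same bin, plus the same channel at consecutive bins."""

    def __init__(self, adjacency: np.ndarray, n_time: int):
        adjacency = np.asarray(adjacency, dtype=bool)
        n_ch = adjacency.shape[0]
        self.n_ch, self.n_time = n_ch, n_time
        rows, cols = [], []
        ci, cj = np.nonzero(adjacency)
        for t in range(n_time):
            rows.append(ci * n_time + t)
            cols.append(cj * n_time + t)
        ch = np.arange(n_ch)
        for t in range(n_time - 1):
            rows.append(ch * n_time + t)
            cols.append(ch * n_time + t + 1)
            rows.append(ch * n_time + t + 1)
            cols.append(ch * n_time + t)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        n = n_ch * n_time
        self.matrix = sparse.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
        )

    def components(self, mask_flat: np.ndarray) -> list:
        """Connected components (arrays of flat node ids) of a boolean mask."""
        nodes = np.flatnonzero(mask_flat)
        if len(nodes) == 0:
            return []
        sub = self.matrix[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        return [nodes[labels == k] for k in range(n_comp)]


def _clusters_from_tmap(t_flat, threshold, graph):
    """Signed clusters of a flattened t map; returns list of (nodes, mass, sign)."""
    out = []
    for sign in (1, -1):
        mask = sign * t_flat >= threshold
        for nodes in graph.components(mask):
            out.append((nodes, float(t_flat[nodes].sum()), sign))
    return out


def find_clusters(
    t_map: np.ndarray,
    adjacency: np.ndarray,
    df: int,
    first_level_alpha: float = 0.05,
) -> list:
    """Supra-threshold clusters (no p-values) of a channels x time t map."""
    t_map = np.asarray(t_map, dtype=float)
    n_ch, n_time = t_map.shape
    graph = _SpatioTemporalGraph(adjacency, n_time)
    threshold = stats.t.ppf(1.0 - first_level_alpha / 2.0, df)
    results = []
    for nodes, mass, sign in _clusters_from_tmap(t_map.ravel(), threshold, graph):
        results.append(
            ClusterResult(
                channels=nodes // n_time,
                bins=nodes % n_time,
                mass=mass,
                sign=sign,
            )
        )
    return results


def _sign_matrix(n_subjects: int, spec: PermutationSpec) -> tuple[np.ndarray, bool]:
    """Within-subject flip patterns: exhaustive when feasible, else random."""
    exhaustive = spec.exhaustive == "always" or (
        spec.exhaustive == "auto" and 2**n_subjects <= spec.n_permutations
    )
    if exhaustive:
        codes = np.arange(2**n_subjects, dtype=np.int64)
        bits = (codes[:, None] >> np.arange(n_subjects)) & 1
        return 1.0 - 2.0 * bits, True
    rng = np.random.default_rng(spec.seed)
    signs = rng.choice([-1.0, 1.0], size=(spec.n_permutations, n_subjects))
    return signs, False


def permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: np.ndarray,
    spec: PermutationSpec = None,
) -> list:
    """Cluster-based permutation test of cond_a vs cond_b (subjects x
    channels x time).

    Returns the observed clusters with permutation p-values attached: each
    cluster's mass is compared against the null distribution of the maximum
    cluster mass of its own sign (ties count as exceedance, and p is never
    reported below 1 / n_permutations).  A cluster is conventionally called
    significant when p < cluster_alpha / 2 for its sign.
    """
    spec = spec if spec is not None else PermutationSpec()
    cond_a = np.asarray(cond_a, dtype=float)
    cond_b = np.asarray(cond_b, dtype=float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition arrays must have identical shapes")
    n_subj, n_ch, n_time = cond_a.shape
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    diff = (cond_a - cond_b).reshape(n_subj, n_ch * n_time)
    df = n_subj - 1
    threshold = stats.t.ppf(1.0 - spec.first_level_alpha / 2.0, df)
    graph = _SpatioTemporalGraph(adjacency, n_time)

    t_obs = _t_rows(diff, np.ones((1, n_subj)))[0]
    observed = _clusters_from_tmap(t_obs, threshold, graph)
    if not observed:
        return []

    signs, exhaustive = _sign_matrix(n_subj, spec)
    n_perm = signs.shape[0]
    max_pos = np.zeros(n_perm)
    min_neg = np.zeros(n_perm)
    # compute permutation t maps in blocks: one matmul per block
    block = max(1, int(5e6) // diff.shape[1])
    for lo in range(0, n_perm, block):
        t_blk = _t_rows(diff, signs[lo : lo + block])
        for j in range(t_blk.shape[0]):
            masses = [m for _, m, s in _clusters_from_tmap(t_blk[j], threshold, graph)]
            if masses:
                max_pos[lo + j] = max(max(masses), 0.0)
                min_neg[lo + j] = min(min(masses), 0.0)

    results = []
    for nodes, mass, sign in observed:
        if sign > 0:
            p = float(np.mean(max_pos >= mass))
        else:
            p = float(np.mean(min_neg <= mass))
        if not exhaustive:
            p = max(p, 1.0 / n_perm)
        results.append(
            ClusterResult(
                channels=nodes // n_time,
                bins=nodes % n_time,
                mass=mass,
                sign=sign,
                p_value=p,
            )
        )
    results.sort(key=lambda c: abs(c.mass), reverse=True)
    return results


def _t_rows(diff: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Paired t maps for many sign-flip patterns at once.

    ``diff`` is subjects x bins; ``signs`` is patterns x subjects.  Squared
    values are flip-invariant, so only the mean needs a matmul.
    """
    n = diff.shape[0]
    mean = signs @ diff / n
    meansq = np.einsum("sb,sb->b", diff, diff) / n
    var = (meansq[None, :] - mean**2) * (n / (n - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var <= 0.0, 0.0, mean / np.sqrt(var / n))
    return t


def topo_correlation_test(
    effect_topos: np.ndarray, localizer_topos: np.ndarray
) -> tuple[float, int, float, float]:
    """Topographical-similarity test between two per-subject sensor maps.

    Per subject, the Pearson correlation across sensors between the effect
    topography and the localizer topography is Fisher z-transformed; the z
    values are tested against zero with a two-tailed one-sample t-test.
    Returns ``(t, df, p, mean_z)``.
    """
    a = np.atleast_2d(np.asarray(effect_topos, dtype=float))
    b = np.atleast_2d(np.asarray(localizer_topos, dtype=float))
    if a.shape != b.shape:
        raise ValueError("topography arrays must have identical shapes")
    n_subj, n_sens = a.shape
    if n_subj < 2 or n_sens < 3:
        raise ValueError("need >= 2 subjects and >= 3 sensors")
    zs = np.empty(n_subj)
    for s in range(n_subj):
        if a[s].std() == 0.0 or b[s].std() == 0.0:
            raise ValueError(f"zero-variance topography for subject {s}")
        r = float(np.corrcoef(a[s], b[s])[0, 1])
        if abs(r) >= 1.0:
            warnings.warn(f"|r| = 1 for subject {s}; clamping before Fisher z")
            r = np.clip(r, -(1.0 - 1e-12), 1.0 - 1e-12)
        zs[s] = np.arctanh(r)
    df = n_subj - 1
    mean_z = float(zs.mean())
    sd = zs.std(ddof=1)
    if sd == 0.0:
        warnings.warn("identical Fisher z across subjects; returning infinite t")
        if mean_z == 0.0:
            return 0.0, df, 1.0, mean_z
        return (np.inf if mean_z > 0 else -np.inf), df, 0.0, mean_z
    t, p = stats.ttest_1samp(zs, 0.0)
    return float(t), df, float(p), mean_z


def report_cluster_extent(
    cluster: ClusterResult, time_axis: np.ndarray
) -> tuple[float, float, set]:
    """Map a cluster to (t_start, t_end, channel set) in seconds."""
    if cluster.size == 0:
        raise ValueError("empty cluster")
    time_axis = np.asarray(time_axis)
    return (
        float(time_axis[cluster.bins.min()]),
        float(time_axis[cluster.bins.max()]),
        set(cluster.channels.tolist()),
    )
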