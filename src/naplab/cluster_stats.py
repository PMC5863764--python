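"""Nonparametric cluster-based permutation inference for paired designs.

The observed statistic map is a paired-samples t-test across subjects at
every grid point (time, channel x time, or channel x time x frequency).
Points exceeding the cluster-forming threshold are grouped into connected
clusters (adjacent grid steps along time/frequency; a fixed neighbour
list for the 8-channel montage), and each cluster's mass is the sum of
its member t-values. The null distribution is built by randomly
exchanging the two condition labels within subjects (equivalently,
flipping the sign of each subject's difference), recomputing the map, and
recording the maximum absolute cluster mass; a cluster's Monte Carlo p is
the corrected proportion of null maxima at least as large as its own
absolute mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# declared adjacency for the fixed 8-channel montage
MONTAGE_NEIGHBORS = {
    "F3": ["C3", "F4"], "F4": ["C4", "F3"],
    "C3": ["F3", "P3", "C4"], "C4": ["F4", "P4", "C3"],
    "P3": ["C3", "O1", "P4"], "P4": ["C4", "O2", "P3"],
    "O1": ["P3", "O2"], "O2": ["P4", "O1"],
}


@dataclass
class Cluster:
    points: np.ndarray          # (n_points, n_dims) grid indices
    mass: float
    polarity: str               # "positive" or "negative"
    p_value: float = float("nan")


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    null_max_mass: np.ndarray = field(repr=False, default=None)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def paired_t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired-samples t statistic across the first (subject) axis.

    Grid points where every subject shows the same difference get an
    infinite sentinel (sign of the mean), or 0 when that difference is 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("need matched (subjects, ...) arrays with >= 2 subjects")
    return _t_from_diffs(a - b)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if np.any(zero_var):
        t = np.where(zero_var, np.sign(mean) * np.inf, t)
        t = np.where(zero_var & (mean == 0), 0.0, t)
    return t


def _neighbor_offsets(shape: tuple[int, ...], channel_axis: int | None):
    offsets = []
    for ax in range(len(shape)):
        if ax == channel_axis:
            continue
        for step in (-1, 1):
            off = [0] * len(shape)
            off[ax] = step
            offsets.append(tuple(off))
    return offsets


def form_clusters(t_grid: np.ndarray, threshold: float,
                  channel_names: list[str] | None = None,
                  channel_axis: int | None = None) -> list[Cluster]:
    """Connected supra-threshold clusters, one polarity at a time.

    ``channel_axis`` marks the grid axis indexed by ``channel_names``;
    adjacency along it follows :data:`MONTAGE_NEIGHBORS`. All other axes
    use adjacent-step connectivity.
    """
    t_grid = np.asarray(t_grid, float)
    if channel_axis is not None and channel_names is None:
        raise ValueError("channel_names required with channel_axis")
    chan_adj = None
    if channel_axis is not None:
        index = {c: i for i, c in enumerate(channel_names)}
        chan_adj = {i: [index[n] for n in MONTAGE_NEIGHBORS.get(c, [])
                        if n in index]
                    for c, i in index.items()}
    offsets = _neighbor_offsets(t_grid.shape, channel_axis)

    clusters: list[Cluster] = []
    for polarity, mask in (("positive", t_grid > threshold),
                           ("negative", t_grid < -threshold)):
        seen = np.zeros_like(mask, dtype=bool)
        for start in zip(*np.nonzero(mask & ~seen)):
            if seen[start]:
                continue
            stack, members = [start], []
            seen[start] = True
            while stack:
                p = stack.pop()
                members.append(p)
                for off in offsets:
                    q = tuple(np.add(p, off))
                    if all(0 <= qi < s for qi, s in zip(q, t_grid.shape)) \
                            and mask[q] and not seen[q]:
                        seen[q] = True
                        stack.append(q)
                if chan_adj is not None:
                    for nb in chan_adj[p[channel_axis]]:
                        q = p[:channel_axis] + (nb,) + p[channel_axis + 1:]
                        if mask[q] and not seen[q]:
                            seen[q] = True
                            stack.append(q)
            pts = np.array(members, int)
            mass = float(t_grid[tuple(pts.T)].sum())
            clusters.append(Cluster(points=pts, mass=mass, polarity=polarity))
    return clusters


def permutation_p(a: np.ndarray, b: np.ndarray, threshold: float | None = None,
                  n_permutations: int = 1000, seed: int | None = 0,
                  channel_names: list[str] | None = None,
                  channel_axis: int | None = None) -> ClusterResult:
    """Cluster-based permutation test for paired conditions ``a`` vs ``b``.

    ``threshold`` defaults to the two-sided paired-t critical value at
    alpha = 0.05 for the given number of subjects. ``channel_axis`` indexes
    the statistic grid, i.e. the data axes after the leading subject axis
    (channel-first data uses ``channel_axis=0``). P-values carry the +1
    correction, so the smallest attainable p is 1/(n_permutations + 1).
    """
    from scipy import stats as sps

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    n_subj = a.shape[0]
    if threshold is None:
        threshold = float(sps.t.ppf(0.975, n_subj - 1))
    diffs = a - b
    observed = form_clusters(_t_from_diffs(diffs), threshold,
                             channel_names, channel_axis)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    flip_shape = (n_subj,) + (1,) * (diffs.ndim - 1)
    for k in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_subj).reshape(flip_shape)
        perm_clusters = form_clusters(_t_from_diffs(diffs * signs), threshold,
                                      channel_names, channel_axis)
        null_max[k] = max((abs(c.mass) for c in perm_clusters), default=0.0)
    for c in observed:
        c.p_value = float((1 + np.sum(null_max >= abs(c.mass))) /
                          (n_permutations + 1))
    return ClusterResult(clusters=observed, threshold=threshold,
                         n_permutations=n_permutations, null_max_mass=null_max)
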