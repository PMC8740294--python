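"""Cluster-based permutation test over channels x time.

Compares two independent groups of subject-level TEP traces inside an
analysis window while controlling the multiple-comparisons problem:
a pooled two-sample t statistic is computed per (channel, sample), the
t-map is thresholded at the two-sided pointwise p = 0.05 critical value,
supra-threshold points of common sign are grouped into spatiotemporally
connected clusters (temporal contiguity within a channel, spatial
adjacency across channels at a common sample), clusters without at least
two adjacent channels co-active at some sample are discarded, and each
surviving cluster's mass (summed t) is referred to a permutation null of
the per-permutation maximum cluster mass.  Positive and negative tails
are tested separately at alpha = 0.025 (two-tailed control).

The null is generated by permuting subject-level group labels: the
comparison is between independent groups of subjects, and exchanging
subject labels is the randomization that matches that null hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .montage import ChannelLayout, TimeWindow

__all__ = [
    "Adjacency",
    "Cluster",
    "ClusterResult",
    "build_adjacency",
    "pointwise_t",
    "find_clusters",
    "permutation_test",
]

DEFAULT_RADIUS = 0.25


@dataclass(frozen=True)
class Adjacency:
    """Symmetric, irreflexive channel neighbourhood sets."""

    names: tuple[str, ...]
    neighbors: tuple[tuple[int, ...], ...]

    def __len__(self) -> int:
        return len(self.names)

    def matrix(self) -> np.ndarray:
        m = np.zeros((len(self), len(self)), dtype=bool)
        for i, nb in enumerate(self.neighbors):
            m[i, list(nb)] = True
        return m

    def are_adjacent(self, i: int, j: int) -> bool:
        return j in self.neighbors[i]


def build_adjacency(layout: ChannelLayout,
                    radius: float = DEFAULT_RADIUS) -> Adjacency:
    """Channels are neighbours iff their planar distance is below ``radius``.

    Warns (and still returns) if some channel ends up isolated.
    """
    pos = layout.pos2d
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    close = d < radius
    np.fill_diagonal(close, False)
    neighbors = tuple(tuple(np.flatnonzero(row)) for row in close)
    isolated = [layout.names[i] for i, nb in enumerate(neighbors) if not nb]
    if isolated:
        warnings.warn(f"isolated channels under radius {radius}: {isolated}",
                      stacklevel=2)
    return Adjacency(names=tuple(layout.names), neighbors=neighbors)


def pointwise_t(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per (channel, sample).

    ``group_a``/``group_b`` are ``(n_subjects, channels, samples)`` stacks of
    subject-level traces.  Points with zero variance in both groups yield
    NaN (undefined, excluded from clustering).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    t[denom == 0] = np.nan
    return t


@dataclass(frozen=True)
class Cluster:
    """One spatiotemporal cluster of supra-threshold points."""

    members: tuple[tuple[int, int], ...]  # (channel index, window sample index)
    mass: float
    tail: str  # "pos" | "neg"
    p_perm: float | None = None

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted({ch for ch, _ in self.members}))

    @property
    def sample_range(self) -> tuple[int, int]:
        samples = [i for _, i in self.members]
        return min(samples), max(samples)


@dataclass
class ClusterResult:
    """Observed clusters with permutation p-values."""

    clusters: list[Cluster]
    t_map: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    df: int
    n_perm: int
    alpha_cluster: float = 0.05
    alpha_perm: float = 0.025

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters
                if c.p_perm is not None and c.p_perm < self.alpha_perm]


def _components(mask: np.ndarray, neighbors) -> list[list[tuple[int, int]]]:
    """Connected components of a (channels x samples) boolean map.

    Connectivity: (ch, i) ~ (ch, i +/- 1) and (ch, i) ~ (nb, i) for spatial
    neighbours nb.
    """
    n_ch, n_s = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    idx = np.argwhere(mask)
    for ch0, i0 in idx:
        if seen[ch0, i0]:
            continue
        stack = [(int(ch0), int(i0))]
        seen[ch0, i0] = True
        comp = []
        while stack:
            ch, i = stack.pop()
            comp.append((ch, i))
            if i > 0 and mask[ch, i - 1] and not seen[ch, i - 1]:
                seen[ch, i - 1] = True
                stack.append((ch, i - 1))
            if i + 1 < n_s and mask[ch, i + 1] and not seen[ch, i + 1]:
                seen[ch, i + 1] = True
                stack.append((ch, i + 1))
            for nb in neighbors[ch]:
                if mask[nb, i] and not seen[nb, i]:
                    seen[nb, i] = True
                    stack.append((nb, i))
        comps.append(comp)
    return comps


def _has_adjacent_pair(comp, neighbors) -> bool:
    by_sample: dict[int, list[int]] = {}
    for ch, i in comp:
        by_sample.setdefault(i, []).append(ch)
    for chans in by_sample.values():
        cset = set(chans)
        for ch in chans:
            if cset.intersection(neighbors[ch]):
                return True
    return False


def find_clusters(t_map: np.ndarray, adjacency: Adjacency, df: int,
                  p_threshold: float = 0.05,
                  min_channels: int = 2) -> list[Cluster]:
    """Threshold a t-map and form candidate spatiotemporal clusters.

    Points with |t| above the two-sided ``p_threshold`` critical value are
    grouped, separately per sign.  Clusters whose channel support never
    contains two spatially adjacent channels at a common sample are
    discarded (when ``min_channels`` >= 2).
    """
    t_crit = float(stats.t.ppf(1.0 - p_threshold / 2.0, df))
    tm = np.asarray(t_map, dtype=float)
    out: list[Cluster] = []
    for tail, mask in (("pos", tm > t_crit), ("neg", tm < -t_crit)):
        mask = mask & np.isfinite(tm)
        for comp in _components(mask, adjacency.neighbors):
            if min_channels >= 2 and not _has_adjacent_pair(
                    comp, adjacency.neighbors):
                continue
            mass = float(sum(tm[ch, i] for ch, i in comp))
            out.append(Cluster(members=tuple(sorted(comp)), mass=mass, tail=tail))
    out.sort(key=lambda c: -abs(c.mass))
    return out


def _perm_t_maps(X: np.ndarray, labels_a: np.ndarray) -> np.ndarray:
    """t-maps for many label permutations at once.

    ``X`` is ``(n_subjects, n_points)``; ``labels_a`` is a boolean
    ``(n_perm, n_subjects)`` matrix marking group-A membership per
    permutation.  Returns ``(n_perm, n_points)``.
    """
    n = X.shape[0]
    na = int(labels_a[0].sum())
    nb = n - na
    L = labels_a.astype(float)
    tot = X.sum(axis=0)
    tot2 = (X**2).sum(axis=0)
    sa = L @ X
    sa2 = L @ (X**2)
    sb = tot - sa
    sb2 = tot2 - sa2
    ma, mb = sa / na, sb / nb
    va = (sa2 - na * ma**2) / (na - 1)
    vb = (sb2 - nb * mb**2) / (nb - 1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    t[denom == 0] = np.nan
    return t


def permutation_test(group_a: np.ndarray, group_b: np.ndarray,
                     times: np.ndarray, adjacency: Adjacency,
                     window: TimeWindow | None = None,
                     n_perm: int = 5000, seed: int = 0,
                     p_threshold: float = 0.05, alpha_perm: float = 0.025,
                     min_channels: int = 2,
                     block: int = 250) -> ClusterResult:
    """Cluster-mass permutation test between two groups of subject traces.

    Group labels are permuted across subjects; each permutation's maximum
    cluster mass (per tail) forms the null.  The observed statistic is
    included in the null (the +1 convention), so p >= 1/(n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are unstable",
                      stacklevel=2)
    times = np.asarray(times, dtype=float)
    if window is not None:
        m = window.mask(times)
        a, b, wtimes = a[:, :, m], b[:, :, m], times[m]
    else:
        wtimes = times
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    n_ch, n_s = a.shape[1], a.shape[2]

    t_obs = pointwise_t(a, b)
    observed = find_clusters(t_obs, adjacency, df, p_threshold, min_channels)

    X = np.concatenate([a, b], axis=0).reshape(na + nb, -1)
    rng = np.random.default_rng(seed)
    max_pos = np.zeros(n_perm)
    min_neg = np.zeros(n_perm)
    done = 0
    while done < n_perm:
        nblock = min(block, n_perm - done)
        labels = np.zeros((nblock, na + nb), dtype=bool)
        for r in range(nblock):
            labels[r, rng.permutation(na + nb)[:na]] = True
        tmaps = _perm_t_maps(X, labels).reshape(nblock, n_ch, n_s)
        for r in range(nblock):
            clusters = find_clusters(tmaps[r], adjacency, df,
                                     p_threshold, min_channels)
            pos = [c.mass for c in clusters if c.tail == "pos"]
            neg = [c.mass for c in clusters if c.tail == "neg"]
            max_pos[done + r] = max(pos) if pos else 0.0
            min_neg[done + r] = min(neg) if neg else 0.0
        done += nblock

    scored = []
    for c in observed:
        if c.tail == "pos":
            exceed = int(np.sum(max_pos >= c.mass))
        else:
            exceed = int(np.sum(min_neg <= c.mass))
        p = (1 + exceed) / (n_perm + 1)
        scored.append(Cluster(members=c.members, mass=c.mass,
                              tail=c.tail, p_perm=p))
    return ClusterResult(clusters=scored, t_map=t_obs, times=wtimes, df=df,
                         n_perm=n_perm, alpha_cluster=p_threshold,
                         alpha_perm=alpha_perm)
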