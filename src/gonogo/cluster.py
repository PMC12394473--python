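"""Modified cluster-based permutation test for ERP waveform contrasts.

The test follows the cluster-permutation logic familiar from FieldTrip
but with two substitutions: the pointwise statistic is a normal
approximation of the Wilcoxon signed-rank test (paired contrasts) or
of the Mann-Whitney rank-sum test (independent groups), and the
cluster-level statistic is the sum of z-scores within a cluster.
Suprathreshold points (two-sided pointwise p below the cluster-forming
alpha) are grouped into same-sign clusters that are contiguous in time
within a channel and linked across channels through a declared
adjacency (Fz-Cz by default); inference compares each observed
cluster's |mass| to the permutation distribution of the maximum
cluster |mass|.

The permutation scheme is exact for the designs used here: random sign
flips of per-subject difference waves under the paired null, random
group-label permutations under the independent null, with exhaustive
enumeration whenever the full permutation group is no larger than the
requested count.  Permutation p-values use the (1 + more extreme) /
(1 + n_permutations) convention, so they are valid at any sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import comb, ndtr, ndtri
from scipy.stats import rankdata

from .montage import adjacency_matrix
from .synth import _substream

# ---------------------------------------------------------------------------
# Pointwise rank statistics (vectorised over an arbitrary point grid)


def _tie_term(col: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of the finite values in ``col``."""
    vals = col[np.isfinite(col)]
    if vals.size == 0:
        return 0.0
    _, counts = np.unique(vals, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t ** 3 - t).sum())


def signed_rank_ingredients(d: np.ndarray):
    """Decompose the signed-rank statistic for fast sign-flip permutation.

    ``d`` is (n, points).  Zero differences are dropped per point (the
    classical convention), so the effective n can vary across points.
    Returns ``(signed_ranks, sigma, n_eff)`` with the identity

        W+ - n(n+1)/4 = signed_ranks.sum(axis=0) / 2

    and ``sigma**2 = n(n+1)(2n+1)/24 - sum(t^3 - t)/48`` per point, so
    that any sign-flip pattern s gives z = (s @ signed_ranks) / (2 sigma).
    """
    d = np.asarray(d, dtype=float)
    absd = np.where(d == 0, np.nan, np.abs(d))
    ranks = rankdata(absd, method="average", axis=0, nan_policy="omit")
    ranks = np.where(np.isnan(ranks), 0.0, ranks)
    signed = ranks * np.sign(d)
    n_eff = (d != 0).sum(axis=0)
    base = n_eff * (n_eff + 1.0) * (2 * n_eff + 1.0) / 24.0
    ties = np.array([_tie_term(absd[:, j]) for j in range(absd.shape[1])])
    var = base - ties / 48.0
    sigma = np.sqrt(np.maximum(var, 0.0))
    return signed, sigma, n_eff


def _z_from_signed(signed_sum: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = 0.5 * signed_sum / sigma
    return np.where(sigma > 0, z, 0.0)


def rank_sum_ingredients(pooled: np.ndarray, n1: int, n2: int):
    """Ranks and null moments of the Mann-Whitney U for label permutation.

    ``pooled`` is (n1 + n2, points); for any subset A of n1 rows,
    U_A = ranks[A].sum(axis=0) - n1(n1+1)/2 and
    z = (U_A - n1 n2 / 2) / sigma with the tie-corrected variance
    n1 n2 / 12 * (N + 1 - sum(t^3 - t) / (N (N - 1))).
    """
    N = n1 + n2
    ranks = rankdata(pooled, method="average", axis=0)
    ties = np.array([_tie_term(pooled[:, j]) for j in range(pooled.shape[1])])
    var = n1 * n2 / 12.0 * (N + 1.0 - ties / (N * (N - 1.0)))
    sigma = np.sqrt(np.maximum(var, 0.0))
    return ranks, sigma


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.minimum(1.0, 2.0 * ndtr(-np.abs(z)))


@dataclass
class PointwiseStatMap:
    """Signed z and two-sided p over a channels x time grid."""
    z: np.ndarray
    p: np.ndarray
    n_pairs: int | None = None
    n1: int | None = None
    n2: int | None = None
    n_effective: np.ndarray | None = None  # per point, after zero-difference drop


def wilcoxon_signed_rank_z(diffs: np.ndarray) -> PointwiseStatMap:
    """Pointwise signed-rank z over paired differences.

    ``diffs`` is (n_pairs, channels, time) (or (n_pairs, points)).
    z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3-t)/48), with
    zero differences dropped before ranking; all-zero points get z = 0
    and p = 1.
    """
    diffs = np.asarray(diffs, dtype=float)
    shape = diffs.shape[1:]
    flat = diffs.reshape(diffs.shape[0], -1)
    signed, sigma, n_eff = signed_rank_ingredients(flat)
    z = _z_from_signed(signed.sum(axis=0), sigma)
    p = np.where(n_eff > 0, _two_sided_p(z), 1.0)
    return PointwiseStatMap(z=z.reshape(shape), p=p.reshape(shape),
                            n_pairs=diffs.shape[0],
                            n_effective=n_eff.reshape(shape))


def rank_sum_z(a: np.ndarray, b: np.ndarray) -> PointwiseStatMap:
    """Pointwise Mann-Whitney z between two independent groups.

    ``a`` is (n1, channels, time), ``b`` is (n2, channels, time); z is
    signed by the direction of A - B (positive when A tends larger).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group point grids differ")
    shape = a.shape[1:]
    n1, n2 = a.shape[0], b.shape[0]
    pooled = np.concatenate([a.reshape(n1, -1), b.reshape(n2, -1)], axis=0)
    ranks, sigma = rank_sum_ingredients(pooled, n1, n2)
    u = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - n1 * n2 / 2.0) / sigma
    z = np.where(sigma > 0, z, 0.0)
    return PointwiseStatMap(z=z.reshape(shape), p=_two_sided_p(z).reshape(shape),
                            n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# Cluster formation

@dataclass
class Cluster:
    """A same-sign connected set of suprathreshold (channel, time) points."""
    members: list[tuple[int, int]]      # (channel index, time index)
    sign: int                           # +1 or -1
    mass: float                         # sum of member z (signed)
    p_value: float | None = None

    @property
    def time_indices(self) -> np.ndarray:
        return np.array(sorted({t for _, t in self.members}))


def _grid_components(mask: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of True points: time-contiguous within channel,
    linked across adjacent channels at the same time point."""
    n_ch, n_t = mask.shape
    flat_idx = np.flatnonzero(mask.ravel())
    if flat_idx.size == 0:
        return []
    node_of = np.full(n_ch * n_t, -1, dtype=np.int64)
    node_of[flat_idx] = np.arange(flat_idx.size)
    rows, cols = [], []
    # temporal edges
    tmask = mask[:, :-1] & mask[:, 1:]
    ci, ti = np.nonzero(tmask)
    rows.append(ci * n_t + ti)
    cols.append(ci * n_t + ti + 1)
    # spatial edges at identical time points
    ai, aj = np.nonzero(np.triu(adjacency, k=1))
    for i, j in zip(ai, aj):
        t = np.nonzero(mask[i] & mask[j])[0]
        rows.append(i * n_t + t)
        cols.append(j * n_t + t)
    rows = node_of[np.concatenate(rows)] if rows else np.empty(0, dtype=np.int64)
    cols = node_of[np.concatenate(cols)] if cols else np.empty(0, dtype=np.int64)
    graph = coo_matrix((np.ones(rows.size), (rows, cols)),
                       shape=(flat_idx.size, flat_idx.size))
    n_comp, labels = connected_components(graph, directed=False)
    return [flat_idx[labels == k] for k in range(n_comp)]


def form_clusters(stat_map: PointwiseStatMap, cluster_alpha: float = 0.05,
                  adjacency: np.ndarray | None = None) -> list[Cluster]:
    """Partition suprathreshold points into maximal same-sign clusters.

    ``adjacency`` is a boolean channels x channels matrix (default: the
    Fz-Cz pair is adjacent when the map has two channels, otherwise no
    cross-channel links).
    """
    if not 0.0 < cluster_alpha < 1.0:
        raise ValueError("cluster_alpha must be in (0, 1)")
    z, p = np.atleast_2d(stat_map.z), np.atleast_2d(stat_map.p)
    n_ch, n_t = z.shape
    if adjacency is None:
        adjacency = np.zeros((n_ch, n_ch), dtype=bool)
        if n_ch == 2:
            adjacency[0, 1] = adjacency[1, 0] = True
    supra = p < cluster_alpha
    clusters = []
    for sign in (+1, -1):
        mask = supra & ((z > 0) if sign > 0 else (z < 0))
        for comp in _grid_components(mask, adjacency):
            ch, t = np.unravel_index(comp, z.shape)
            clusters.append(Cluster(members=list(zip(ch.tolist(), t.tolist())),
                                    sign=sign,
                                    mass=float(z.ravel()[comp].sum())))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_cluster_masses(z_maps: np.ndarray, z_crit: float,
                        adjacency: np.ndarray) -> np.ndarray:
    """Maximum |sum of z| over clusters, per permutation map (B, C, T)."""
    out = np.zeros(z_maps.shape[0])
    for b in range(z_maps.shape[0]):
        z = z_maps[b]
        best = 0.0
        for sign in (+1, -1):
            mask = (z * sign) > z_crit
            for comp in _grid_components(mask, adjacency):
                m = abs(float(z.ravel()[comp].sum()))
                if m > best:
                    best = m
        out[b] = best
    return out


# ---------------------------------------------------------------------------
# Permutation inference

@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_permutations: int
    max_null_distribution: np.ndarray
    seed: int
    design: str
    exhaustive: bool
    cluster_alpha: float
    alpha: float
    channel_names: list[str]
    time_ms: np.ndarray
    stat_map: PointwiseStatMap

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None
                and c.p_value < self.alpha]

    def summary(self):
        import pandas as pd
        rows = []
        for c in self.clusters:
            t = c.time_indices
            rows.append({
                "channels": "+".join(sorted({self.channel_names[ch]
                                             for ch, _ in c.members})),
                "t_start_ms": float(self.time_ms[t[0]]),
                "t_end_ms": float(self.time_ms[t[-1]]),
                "n_points": len(c.members),
                "sign": c.sign, "mass": c.mass, "p_value": c.p_value,
                "significant": c.p_value is not None and c.p_value < self.alpha,
            })
        return pd.DataFrame(rows)


def _all_sign_patterns(n: int) -> np.ndarray:
    bits = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
    return 2.0 * bits - 1.0


def _crop(time_ms: np.ndarray, window):
    if window is None:
        return np.ones(time_ms.size, dtype=bool)
    lo, hi = window
    return (time_ms >= lo) & (time_ms < hi)


def permutation_test(data, design: str = "paired", n_permutations: int = 1000,
                     seed: int = 0, cluster_alpha: float = 0.05,
                     alpha: float = 0.05,
                     channel_names: tuple[str, ...] = ("Fz", "Cz"),
                     time_ms: np.ndarray | None = None,
                     time_window_ms: tuple[float, float] | None = (200.0, 600.0),
                     adjacency: np.ndarray | None = None) -> ClusterTestResult:
    """Cluster-based permutation test with sum-of-z cluster mass.

    ``design="paired"``: ``data`` is (n_subjects, channels, time) paired
    differences (e.g. per-subject NOGO-GO waves, or pre-post changes of
    difference waves); the null is simulated by random sign flips.
    ``design="independent"``: ``data`` is a ``(group_a, group_b)`` tuple
    of (n, channels, time) arrays; the null permutes group labels.

    Analysis is restricted to ``time_window_ms`` (default 200-600 ms)
    and the supplied channels.  If the full permutation group is no
    larger than ``n_permutations`` it is enumerated exhaustively and
    p-values are exact; otherwise p = (1 + #{null >= observed}) /
    (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = _substream(seed, "cluster-perm")
    if adjacency is None:
        adjacency = adjacency_matrix(channels=tuple(channel_names))
    z_crit = float(-ndtri(cluster_alpha / 2.0))

    if design == "paired":
        d = np.asarray(data, dtype=float)
        n, n_ch, n_t = d.shape
        if time_ms is None:
            time_ms = (np.arange(n_t) - 50) * 4.0
        keep = _crop(time_ms, time_window_ms)
        dw = d[:, :, keep].reshape(n, -1)
        grid_shape = (n_ch, int(keep.sum()))
        signed, sigma, n_eff = signed_rank_ingredients(dw)
        z_obs = _z_from_signed(signed.sum(axis=0), sigma).reshape(grid_shape)
        p_obs = np.where(n_eff.reshape(grid_shape) > 0, _two_sided_p(z_obs), 1.0)
        stat_map = PointwiseStatMap(z=z_obs, p=p_obs, n_pairs=n,
                                    n_effective=n_eff.reshape(grid_shape))
        exhaustive = 2 ** n <= n_permutations
        if exhaustive:
            S = _all_sign_patterns(n)
        else:
            S = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        Z = _z_from_signed(S @ signed, sigma[None, :])
        Z = Z.reshape((S.shape[0],) + grid_shape)
        denom = S.shape[0] if exhaustive else n_permutations + 1
    elif design == "independent":
        a, b = (np.asarray(x, dtype=float) for x in data)
        if a.shape[0] == 0 or b.shape[0] == 0:
            raise ValueError("both groups must be non-empty")
        n1, n2 = a.shape[0], b.shape[0]
        n_ch, n_t = a.shape[1:]
        if time_ms is None:
            time_ms = (np.arange(n_t) - 50) * 4.0
        keep = _crop(time_ms, time_window_ms)
        grid_shape = (n_ch, int(keep.sum()))
        pooled = np.concatenate([a[:, :, keep].reshape(n1, -1),
                                 b[:, :, keep].reshape(n2, -1)], axis=0)
        ranks, sigma = rank_sum_ingredients(pooled, n1, n2)
        N = n1 + n2
        mu = n1 * n2 / 2.0
        offset = n1 * (n1 + 1) / 2.0

        def z_of(indicator):
            u = indicator @ ranks - offset
            with np.errstate(divide="ignore", invalid="ignore"):
                zz = (u - mu) / sigma[None, :]
            return np.where(sigma[None, :] > 0, zz, 0.0)

        obs_ind = np.zeros((1, N))
        obs_ind[0, :n1] = 1.0
        z_obs = z_of(obs_ind)[0].reshape(grid_shape)
        stat_map = PointwiseStatMap(z=z_obs, p=_two_sided_p(z_obs), n1=n1, n2=n2)
        n_total = comb(N, n1, exact=True)
        exhaustive = n_total <= n_permutations
        if exhaustive:
            M = np.zeros((n_total, N))
            for r, idx in enumerate(combinations(range(N), n1)):
                M[r, list(idx)] = 1.0
        else:
            M = np.zeros((n_permutations, N))
            for r in range(n_permutations):
                M[r, rng.permutation(N)[:n1]] = 1.0
        Z = z_of(M).reshape((M.shape[0],) + grid_shape)
        denom = M.shape[0] if exhaustive else n_permutations + 1
    else:
        raise ValueError("design must be 'paired' or 'independent'")

    null = _max_cluster_masses(Z, z_crit, adjacency)
    clusters = form_clusters(stat_map, cluster_alpha, adjacency)
    for c in clusters:
        extreme = int((null >= abs(c.mass)).sum())
        c.p_value = (extreme if exhaustive else 1 + extreme) / denom
    return ClusterTestResult(
        clusters=clusters, n_permutations=len(null),
        max_null_distribution=null, seed=seed, design=design,
        exhaustive=exhaustive, cluster_alpha=cluster_alpha, alpha=alpha,
        channel_names=list(channel_names), time_ms=time_ms[keep],
        stat_map=stat_map)
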