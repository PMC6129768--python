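"""Cluster-based localization plausibility metric.

Instead of scoring a reconstruction by its single maximum-activity vertex,
the top 5% of the solution space (by per-vertex amplitude norm) is clustered
with DBSCAN — each hemisphere separately, with neighborhood radius and core
threshold derived from the mesh tessellation — and the smallest Euclidean
distance from any cluster's activation-weighted center of mass (COM) to an a
priori reference region is reported.  Because more clusters mean more
chances to land near the region, the raw distance d(c) is normalized by the
mean distance d_r(N_c) that randomly drawn source distributions with the
same cluster count achieve:

    d_n(c, N_c) = d(c) / d_r(N_c),

where d_r is a power law a * N_c^b fitted on log-log means of seeded random
draws.  d_n = 1 therefore means "no better than chance"; 0 is a direct hit.
A maximum-based variant normalizes the distance of the single
maximum-norm vertex by the *empirical* one-cluster baseline mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import DBSCAN
from statsmodels.stats.multitest import multipletests

from .source_space import ReferenceRegion, SourceSpace

__all__ = [
    "TopSelection",
    "ClusterSet",
    "BaselineFit",
    "DistanceResult",
    "select_top_sources",
    "cluster_sources",
    "cluster_com",
    "distance_to_region",
    "vertex_distances_to_region",
    "nearest_cluster_distance",
    "summed_nearest_distance",
    "random_baseline",
    "fit_power_law",
    "sample_min_distances",
    "normalized_distance",
    "max_distance",
    "compare_methods",
]


@dataclass
class TopSelection:
    """The highest-amplitude fraction of the solution space."""

    vertex_ids: np.ndarray
    activations: np.ndarray
    fraction: float = 0.05

    def __len__(self) -> int:
        return len(self.vertex_ids)


@dataclass
class Cluster:
    member_ids: np.ndarray
    weights: np.ndarray
    com: np.ndarray


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    noise_ids: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def coms(self) -> np.ndarray:
        return np.array([c.com for c in self.clusters]).reshape(-1, 3)


@dataclass
class BaselineFit:
    """Random-chance distance baseline d_r(N_c) = a * N_c^b.

    Stores the per-N_c empirical means (and their standard errors) alongside
    the fitted power law; ``one_cluster_mean`` is the empirical mean at
    N_c = 1 used by the maximum-based metric variant.  ``prediction_se``
    gives the OLS standard error of log d_r at a given N_c, needed because
    the normalization denominator is itself an estimate.
    """

    mean_distance_by_Nc: dict[int, float]
    se_by_Nc: dict[int, float]
    coeff_a: float
    exponent_b: float
    n_samples: int
    seed: int
    _xtx_inv: np.ndarray = field(repr=False, default=None)
    _resid_ms: float = field(repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.coeff_a <= 0:
            raise ValueError("power-law coefficient must be positive")

    @property
    def one_cluster_mean(self) -> float:
        return self.mean_distance_by_Nc[1]

    def predict(self, n_clusters: int | np.ndarray) -> np.ndarray | float:
        """Fitted d_r(N_c); extrapolates beyond the fitted range."""
        return self.coeff_a * np.asarray(n_clusters, dtype=float) ** self.exponent_b

    def prediction_se(self, n_clusters: int | np.ndarray) -> np.ndarray | float:
        """Standard error of log d_r(N_c) under the log-log OLS fit."""
        if self._xtx_inv is None:
            return 0.0 * np.asarray(n_clusters, dtype=float)
        x = np.log(np.asarray(n_clusters, dtype=float))
        xv = np.stack([np.ones_like(x), x], axis=-1)
        var = self._resid_ms * np.einsum("...i,ij,...j->...", xv, self._xtx_inv, xv)
        return np.sqrt(var)


@dataclass
class DistanceResult:
    raw_distance: float
    normalized: float | None
    nearest_cluster: int | None
    n_clusters: int
    variant: str = "cluster"  # cluster | maximum


def select_top_sources(norms: np.ndarray, fraction: float = 0.05) -> TopSelection:
    """The round(fraction * N_s) vertices of largest amplitude norm.

    Ties at the cutoff are broken toward lower vertex indices.
    """
    norms = np.asarray(norms, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not np.any(norms > 0):
        raise ValueError("all-zero amplitudes: nothing to rank")
    k = max(1, int(np.floor(fraction * len(norms) + 0.5)))
    order = np.lexsort((np.arange(len(norms)), -norms))  # by -norm, then index
    ids = np.sort(order[:k])
    return TopSelection(ids, norms[ids], fraction)


def cluster_com(members: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Activation-weighted center of mass of member positions."""
    members = np.atleast_2d(np.asarray(members, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if len(members) == 0:
        raise ValueError("cluster has no members")
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    return (weights[:, None] * members).sum(axis=0) / weights.sum()


def cluster_sources(
    selection: TopSelection,
    space: SourceSpace,
    eps: float,
    min_points: int,
) -> ClusterSet:
    """DBSCAN the selected vertices, each hemisphere independently.

    Euclidean metric on the 3-D vertex coordinates; clusters from the two
    hemispheres are concatenated (never merged across the midline); points
    in no cluster are returned as noise.  Cluster COMs are weighted by the
    selected vertices' activations.
    """
    if eps <= 0 or min_points < 1:
        raise ValueError("eps must be positive and min_points >= 1")
    if len(selection) == 0:
        raise ValueError("empty selection")
    clusters: list[Cluster] = []
    noise: list[np.ndarray] = []
    for hemi in ("left", "right"):
        mask = space.hemisphere[selection.vertex_ids] == hemi
        ids = selection.vertex_ids[mask]
        if len(ids) == 0:
            continue
        acts = selection.activations[mask]
        pos = space.vertices[ids]
        labels = DBSCAN(eps=eps, min_samples=min_points).fit_predict(pos)
        for lab in np.unique(labels):
            if lab == -1:
                noise.append(ids[labels == -1])
                continue
            sel = labels == lab
            clusters.append(Cluster(ids[sel], acts[sel], cluster_com(pos[sel], acts[sel])))
    noise_ids = np.sort(np.concatenate(noise)) if noise else np.empty(0, dtype=int)
    return ClusterSet(clusters, noise_ids)


def distance_to_region(point: np.ndarray, region: ReferenceRegion, space: SourceSpace) -> float:
    """Euclidean mm distance from a point to the region.

    Zero when the source-space vertex nearest to the point belongs to the
    region (so slightly off-surface COMs over the region count as hits);
    otherwise the minimum distance to any region vertex.
    """
    point = np.asarray(point, dtype=float)
    d_all = np.linalg.norm(space.vertices - point, axis=1)
    if int(d_all.argmin()) in set(region.vertex_ids.tolist()):
        return 0.0
    return float(d_all[region.vertex_ids].min())


def vertex_distances_to_region(space: SourceSpace, region: ReferenceRegion) -> np.ndarray:
    """Per-vertex distance-to-region vector (region members are 0)."""
    d = np.linalg.norm(
        space.vertices[:, None, :] - space.vertices[region.vertex_ids][None, :, :], axis=2
    ).min(axis=1)
    d[region.vertex_ids] = 0.0
    return d


def nearest_cluster_distance(
    clusters: ClusterSet, region: ReferenceRegion, space: SourceSpace
) -> DistanceResult:
    """Smallest COM-to-region distance over all clusters."""
    if clusters.n_clusters == 0:
        raise ValueError("no clusters (all points noise); caller decides fallback")
    dists = [distance_to_region(c.com, region, space) for c in clusters.clusters]
    best = int(np.argmin(dists))
    return DistanceResult(float(dists[best]), None, best, clusters.n_clusters, "cluster")


def sample_min_distances(
    dist_vector: np.ndarray,
    n_clusters: int,
    n_samples: int,
    rng: np.random.Generator,
    batch: int = 2000,
) -> np.ndarray:
    """Min distance-to-region over ``n_clusters`` vertices drawn uniformly
    without replacement, repeated ``n_samples`` times (vectorized)."""
    n_v = len(dist_vector)
    if n_clusters > n_v:
        raise ValueError("cannot draw more surrogate COMs than vertices")
    out = np.empty(n_samples)
    done = 0
    while done < n_samples:
        m = min(batch, n_samples - done)
        keys = rng.random((m, n_v))
        idx = np.argpartition(keys, n_clusters - 1, axis=1)[:, :n_clusters]
        out[done : done + m] = dist_vector[idx].min(axis=1)
        done += m
    return out


def summed_nearest_distance(
    clusters: ClusterSet, regions: list[ReferenceRegion], space: SourceSpace
) -> float:
    """Sum of nearest-cluster distances over several reference regions.

    Minimal multi-region support for tasks expecting more than one generator
    (one nearest distance per region, summed, unweighted).
    """
    if not regions:
        raise ValueError("no reference regions given")
    return float(
        sum(nearest_cluster_distance(clusters, r, space).raw_distance for r in regions)
    )


def random_baseline(
    space: SourceSpace,
    region: ReferenceRegion,
    max_Nc: int = 15,
    n_samples: int = 20_000,
    seed: int = 0,
) -> BaselineFit:
    """Chance-level distance baseline from seeded random source distributions.

    For each N_c in 1..max_Nc, N_c surrogate COMs are drawn uniformly without
    replacement from the source-space vertices and the minimum distance to
    the region recorded; the per-N_c means are fitted with d_r = a * N_c^b by
    ordinary least squares on the log-log scale.
    """
    if max_Nc < 1:
        raise ValueError("max_Nc must be >= 1")
    if n_samples < 100:
        raise ValueError("need at least 100 samples per cluster count")
    rng = np.random.default_rng(seed)
    dist_vec = vertex_distances_to_region(space, region)
    means: dict[int, float] = {}
    ses: dict[int, float] = {}
    for nc in range(1, max_Nc + 1):
        mins = sample_min_distances(dist_vec, nc, n_samples, rng)
        means[nc] = float(mins.mean())
        ses[nc] = float(mins.std(ddof=1) / np.sqrt(n_samples))
    ncs = np.arange(1, max_Nc + 1)
    a, b, xtx_inv, resid_ms = fit_power_law(ncs, np.array([means[int(n)] for n in ncs]))
    return BaselineFit(means, ses, a, b, n_samples, seed, _xtx_inv=xtx_inv, _resid_ms=resid_ms)


def fit_power_law(n_clusters: np.ndarray, means: np.ndarray) -> tuple[float, float, np.ndarray, float]:
    """OLS power-law fit d_r = a * N_c^b on the log-log scale.

    Returns (a, b, (X'X)^-1, residual mean square) — the latter two feed the
    prediction standard error of the fitted curve.
    """
    ncs = np.asarray(n_clusters, dtype=float)
    y = np.log(np.asarray(means, dtype=float))
    x = np.stack([np.ones_like(ncs), np.log(ncs)], axis=1)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = max(len(ncs) - 2, 1)
    return (
        float(np.exp(coef[0])),
        float(coef[1]),
        np.linalg.inv(x.T @ x),
        float((resid**2).sum() / dof),
    )


def normalized_distance(raw: float, n_clusters: int, fit: BaselineFit) -> float:
    """d_n = raw / d_r(N_c), extrapolating through the fitted power law."""
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    return float(raw / fit.predict(n_clusters))


def max_distance(
    norms: np.ndarray,
    region: ReferenceRegion,
    space: SourceSpace,
    one_cluster_baseline: float,
) -> DistanceResult:
    """Distance of the maximum-norm vertex to the region, normalized by the
    empirical one-cluster baseline mean (ties at the maximum: lowest index)."""
    norms = np.asarray(norms, dtype=float)
    if not np.any(norms):
        raise ValueError("all-zero amplitudes")
    vmax = int(np.argmax(norms))  # argmax takes the first (lowest index) tie
    raw = distance_to_region(space.vertices[vmax], region, space)
    return DistanceResult(raw, raw / one_cluster_baseline, None, 1, "maximum")


def compare_methods(paired: dict[str, np.ndarray]) -> dict:
    """Pairwise Wilcoxon signed-rank tests with Bonferroni-Holm correction.

    ``paired`` maps method name to an equal-length vector of per-trial
    distances.  Returns raw and Holm-adjusted p-values per unordered pair;
    pairs whose differences are all zero are reported with p = 1 and a
    ``degenerate`` flag.
    """
    names = list(paired)
    lengths = {len(v) for v in paired.values()}
    if len(lengths) != 1:
        raise ValueError("paired samples must have equal length")
    (n,) = lengths
    if n < 5:
        raise ValueError("need at least 5 paired samples")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if not pairs:
        return {"pairs": [], "p_raw": [], "p_holm": [], "degenerate": []}
    raw_p, degenerate = [], []
    for a, b in pairs:
        diff = np.asarray(paired[a], float) - np.asarray(paired[b], float)
        if np.all(diff == 0):
            raw_p.append(1.0)
            degenerate.append(True)
        else:
            raw_p.append(float(stats.wilcoxon(paired[a], paired[b]).pvalue))
            degenerate.append(False)
    _, adj, _, _ = multipletests(raw_p, method="holm")
    return {
        "pairs": [f"{a} vs {b}" for a, b in pairs],
        "p_raw": raw_p,
        "p_holm": [float(p) for p in adj],
        "degenerate": degenerate,
    }
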