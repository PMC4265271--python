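"""Density-based clustering primitives: DBSCAN, OPTICS, forced-k extraction.

These are written from scratch (not wrappers) because the cluster semantics
— the neighbourhood radius ("cluster distance"), the minimum cluster
occupancy, deterministic scan-order tie-breaking for border points and
priority ties, and threshold-based extraction of a user-requested number of
clusters from an OPTICS reachability profile — are the core of the calling
method.  scikit-learn's implementations serve as an independent cross-check
in the test-suite only.

Points live on a 2-D scaled plane (theta, weighted r); panels are at most a
few thousand samples per marker, so neighbourhoods use a dense all-pairs
distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import heapq

import numpy as np

__all__ = [
    "NOISE",
    "UNDEFINED",
    "DensityParams",
    "PointSet",
    "ClusterLabeling",
    "ReachabilityProfile",
    "dbscan",
    "optics",
    "extract_at_threshold",
    "extract_k_clusters",
]

#: label for points not assigned to any cluster
NOISE = -1

#: sentinel for undefined reachability / core distance
UNDEFINED = np.inf


@dataclass(frozen=True)
class DensityParams:
    """The two density parameters shared by DBSCAN and OPTICS.

    ``cluster_distance`` is the neighbourhood radius epsilon; ``min_points``
    is the minimum number of points (the point itself included) inside that
    radius for a point to be a core point, and also the minimum occupancy of
    a reported cluster.
    """

    cluster_distance: float = 0.07
    min_points: int = 10

    def __post_init__(self) -> None:
        if self.cluster_distance <= 0:
            raise ValueError("cluster_distance must be > 0")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class PointSet:
    """Ordered 2-D points with sample identifiers.

    Order is stable and defines every deterministic tie-break downstream
    (border-point assignment, OPTICS priority ties).
    """

    coords: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.sample_ids is None:
            self.sample_ids = np.arange(len(self.coords))
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != len(self.coords):
                raise ValueError("sample_ids length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((d**2).sum(axis=2))


@dataclass
class ClusterLabeling:
    """Per-point cluster index (1..n_clusters) or NOISE."""

    labels: np.ndarray
    n_clusters: int
    shortfall: bool = False  # set when a forced-k extraction could not reach k

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in range(1, self.n_clusters + 1):
            out[c] = int(np.sum(self.labels == c))
        return out


@dataclass
class ReachabilityProfile:
    """OPTICS output: visit order plus reachability/core distances.

    ``order`` lists point indices in visit order; ``reachability[i]`` and
    ``core_distance[i]`` are indexed by point (not by visit position) and
    are ``UNDEFINED`` (inf) where the algorithm leaves them undefined — the
    first seed of each density-connected component has undefined
    reachability, and non-core points have undefined core distance.
    """

    order: np.ndarray
    reachability: np.ndarray
    core_distance: np.ndarray
    params: DensityParams
    coords: np.ndarray | None = None  # kept for border attachment at extraction

    def __len__(self) -> int:
        return len(self.order)


def _neighbor_structures(points: PointSet, params: DensityParams):
    dist = points.distance_matrix()
    within = dist <= params.cluster_distance
    counts = within.sum(axis=1)  # the point itself is always included
    core = counts >= params.min_points
    return dist, within, core


def dbscan(points: PointSet, params: DensityParams) -> ClusterLabeling:
    """Standard DBSCAN on a PointSet, deterministic given input order.

    Core point: >= min_points neighbours within cluster_distance (itself
    included).  Clusters are the connected components of core points under
    the epsilon-neighbour relation; a border (non-core) point joins the
    cluster of its first core neighbour in scan order; everything else is
    NOISE.  Cluster indices are 1..k in order of first appearance of a core
    member in the scan.
    """
    n = len(points)
    if n == 0:
        raise ValueError("empty PointSet")
    _, within, core = _neighbor_structures(points, params)

    labels = np.full(n, NOISE, dtype=int)
    n_clusters = 0
    # flood-fill connected components of core points, in scan order
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        n_clusters += 1
        stack = [i]
        labels[i] = n_clusters
        while stack:
            j = stack.pop()
            for k in np.flatnonzero(within[j] & core):
                if labels[k] == NOISE:
                    labels[k] = n_clusters
                    stack.append(int(k))
    # border points: first core neighbour in index order decides
    for i in range(n):
        if labels[i] != NOISE or core[i]:
            continue
        neigh = np.flatnonzero(within[i] & core)
        if len(neigh):
            labels[i] = labels[neigh[0]]
    return ClusterLabeling(labels=labels, n_clusters=n_clusters)


def optics(points: PointSet, params: DensityParams) -> ReachabilityProfile:
    """OPTICS ordering with distances bounded by ``cluster_distance``.

    Classic algorithm: repeatedly visit the unprocessed point with the
    smallest current reachability (ties broken by point index; fresh
    components start at the lowest-index unprocessed point), then relax the
    reachability of its epsilon-neighbours through its core distance.
    """
    n = len(points)
    if n == 0:
        raise ValueError("empty PointSet")
    dist, within, core = _neighbor_structures(points, params)

    # core distance: distance to the min_points-th closest point (self = 1st)
    core_dist = np.full(n, UNDEFINED)
    if params.min_points <= n:
        part = np.partition(dist, params.min_points - 1, axis=1)
        kth = part[:, params.min_points - 1]
        core_dist[core] = kth[core]

    reach = np.full(n, UNDEFINED)
    processed = np.zeros(n, dtype=bool)
    order: list[int] = []
    heap: list[tuple[float, int]] = []

    for start in range(n):
        if processed[start]:
            continue
        heapq.heappush(heap, (np.inf, start))
        while heap:
            r, i = heapq.heappop(heap)
            if processed[i]:
                continue
            # stale entries are skipped; reach[i] holds the current best
            if np.isfinite(reach[i]) and r > reach[i]:
                continue
            processed[i] = True
            order.append(i)
            if core[i]:
                neigh = np.flatnonzero(within[i] & ~processed)
                new_reach = np.maximum(core_dist[i], dist[i, neigh])
                for j, nr in zip(neigh, new_reach):
                    if nr < reach[j]:
                        reach[j] = nr
                        heapq.heappush(heap, (float(nr), int(j)))
    return ReachabilityProfile(
        order=np.asarray(order, dtype=int),
        reachability=reach,
        core_distance=core_dist,
        params=params,
        coords=points.coords,
    )


def extract_at_threshold(profile: ReachabilityProfile, threshold: float) -> ClusterLabeling:
    """Cut a reachability profile at a threshold.

    Core points at level ``threshold`` (core distance <= threshold) are
    segmented by the walk: a core point with reachability > threshold
    starts a new cluster, any other core point continues the current one.
    Non-core points are then attached exactly as DBSCAN border points —
    to the cluster of their first threshold-core neighbour (in point-index
    order) within ``threshold`` — or stay NOISE.  Cutting at
    threshold = cluster_distance therefore reproduces the DBSCAN partition
    under the shared border tie rule.
    """
    n = len(profile)
    labels = np.full(n, NOISE, dtype=int)
    core = profile.core_distance <= threshold
    n_clusters = 0
    current = NOISE
    for pos in profile.order:
        if not core[pos]:
            continue
        if profile.reachability[pos] > threshold:
            n_clusters += 1
            current = n_clusters
        labels[pos] = current
    if profile.coords is not None and n_clusters:
        core_idx = np.flatnonzero(core)
        for i in np.flatnonzero(~core):
            d = np.sqrt(
                ((profile.coords[core_idx] - profile.coords[i]) ** 2).sum(axis=1)
            )
            near = core_idx[d <= threshold]
            if len(near):
                labels[i] = labels[near[0]]
    return ClusterLabeling(labels=labels, n_clusters=n_clusters)


def _valid_cut(labeling: ClusterLabeling, min_points: int) -> ClusterLabeling:
    """Demote clusters below the occupancy floor to NOISE and relabel 1..k."""
    sizes = labeling.sizes()
    keep = [c for c in range(1, labeling.n_clusters + 1) if sizes.get(c, 0) >= min_points]
    relabel = {c: i + 1 for i, c in enumerate(keep)}
    labels = np.array(
        [relabel.get(l, NOISE) for l in labeling.labels], dtype=int
    )
    return ClusterLabeling(labels=labels, n_clusters=len(keep))


def extract_k_clusters(
    profile: ReachabilityProfile, k: int, params: DensityParams | None = None
) -> ClusterLabeling:
    """Force a user-requested number of clusters out of a profile.

    Scans the candidate thresholds (the sorted distinct reachability and
    core-distance values, capped at cluster_distance) from the largest down
    and returns the cut at the *largest* threshold yielding exactly ``k``
    clusters of at least ``min_points`` members each.  If no threshold
    achieves ``k``, the cut with the greatest achievable count below ``k``
    (again at the largest such threshold) is returned with
    ``shortfall=True``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(profile) == 0:
        raise ValueError("empty profile")
    params = params or profile.params
    eps = params.cluster_distance

    values = np.concatenate([profile.reachability, profile.core_distance])
    values = values[np.isfinite(values)]
    candidates = np.unique(np.concatenate([values[values <= eps], [eps]]))[::-1]

    best: ClusterLabeling | None = None
    best_count = -1
    for t in candidates:
        cut = _valid_cut(extract_at_threshold(profile, float(t)), params.min_points)
        if cut.n_clusters == k:
            return cut
        if cut.n_clusters < k and cut.n_clusters > best_count:
            best = cut
            best_count = cut.n_clusters
    if best is None:
        best = ClusterLabeling(
            labels=np.full(len(profile), NOISE, dtype=int), n_clusters=0
        )
    best.shortfall = True
    return best
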