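"""Lloyd's K-means with pluggable distance metrics, including ASED.

ASED (Amplified Squared Euclidean Distance) is

    ASED(a, b) = (Σ_i (a_i − b_i)²)²  =  L2(a, b)⁴,

a strictly increasing transform of the Euclidean distance that amplifies the
penalty for large dissimilarities while shrinking it for small ones. Because
argmin is invariant under strictly increasing transforms, assignment under
ASED coincides with assignment under L2, so full Lloyd trajectories under the
two metrics are identical given the same initialization — a property the test
suite asserts.

The within-cluster sum of squares (WSS, inertia) is always the sum of
*squared* Euclidean distances of points to their assigned centroid: the mean
update step is the exact minimizer of that objective, and it is the quantity
the elbow scan monitors.

Feature space is arbitrary; in the descriptor-similarity pipeline the points
are the rows of the molecule × molecule correlation matrix Mcorr, so that
each molecule is represented by its correlation profile against the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

METRICS = ("ased", "l2", "manhattan", "cosine", "correlation")
INITS = ("random", "kmeanspp")


class ClusteringError(ValueError):
    """Raised on invalid clustering inputs or configuration."""


def l2(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-length vectors."""
    a, b = _check_pair(a, b)
    return float(np.sqrt(np.sum((a - b) ** 2)))


def ased(a: np.ndarray, b: np.ndarray) -> float:
    """Amplified squared Euclidean distance: (Σ (a_i − b_i)²)² = L2⁴."""
    a, b = _check_pair(a, b)
    return float(np.sum((a - b) ** 2) ** 2)


def manhattan(a: np.ndarray, b: np.ndarray) -> float:
    a, b = _check_pair(a, b)
    return float(np.sum(np.abs(a - b)))


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − cosine similarity."""
    a, b = _check_pair(a, b)
    return float(cdist(a[None, :], b[None, :], metric="cosine")[0, 0])


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 − Pearson correlation of the two vectors."""
    a, b = _check_pair(a, b)
    return float(cdist(a[None, :], b[None, :], metric="correlation")[0, 0])


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ClusteringError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


DISTANCE_FUNCTIONS = {
    "ased": ased,
    "l2": l2,
    "manhattan": manhattan,
    "cosine": cosine_distance,
    "correlation": correlation_distance,
}


def pairwise_distances(points: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    """Distance matrix (n_points × n_centers) under the named metric."""
    if metric not in METRICS:
        raise ClusteringError(f"unknown metric {metric!r}; expected one of {METRICS}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if points.shape[1] != centers.shape[1]:
        raise ClusteringError(
            f"dimension mismatch: points d={points.shape[1]}, centers d={centers.shape[1]}"
        )
    if metric == "ased":
        return cdist(points, centers, metric="sqeuclidean") ** 2
    if metric == "l2":
        return cdist(points, centers, metric="euclidean")
    if metric == "manhattan":
        return cdist(points, centers, metric="cityblock")
    return cdist(points, centers, metric=metric)


@dataclass(frozen=True)
class KMeansConfig:
    """Configuration for one K-means run.

    ``seed`` is mandatory: there is no silent nondeterminism. ``tol`` is the
    centroid-shift threshold (max Euclidean move of any centroid between
    iterations) below which the run is declared converged.
    """

    k: int
    seed: int
    metric: str = "ased"
    init: str = "kmeanspp"
    n_init: int = 10
    max_iter: int = 300
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ClusteringError(f"k must be >= 1, got {self.k}")
        if self.metric not in METRICS:
            raise ClusteringError(f"unknown metric {self.metric!r}")
        if self.init == "bayesian":
            raise NotImplementedError(
                "'bayesian' initialization is not defined; use 'random' or 'kmeanspp'"
            )
        if self.init not in INITS:
            raise ClusteringError(f"unknown init {self.init!r}; expected one of {INITS}")
        if self.n_init < 1 or self.max_iter < 1 or self.tol < 0:
            raise ClusteringError("n_init, max_iter must be >= 1 and tol >= 0")


@dataclass
class ClusteringResult:
    """Labels, centroids and convergence record of the best K-means restart."""

    labels: np.ndarray
    centroids: np.ndarray
    wss: float
    wss_trajectory: list[float]
    n_iter: int
    converged: bool
    config: KMeansConfig


def assign(points: np.ndarray, centroids: np.ndarray, metric: str = "l2") -> np.ndarray:
    """Assign each point to its nearest centroid; ties go to the lowest index."""
    centroids = np.atleast_2d(centroids)
    if centroids.shape[0] == 0:
        raise ClusteringError("empty centroid set")
    d = pairwise_distances(points, centroids, metric)
    return np.argmin(d, axis=1)  # argmin returns the first (lowest) index on ties


def update_centroids(
    points: np.ndarray,
    labels: np.ndarray,
    k: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Coordinate-wise mean of each cluster's members.

    An empty cluster is re-seeded with the point farthest from its currently
    assigned centroid (deterministic; ``rng`` is accepted for interface
    symmetry but unused by this rule).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    centroids = np.empty((k, points.shape[1]), dtype=float)
    empty = []
    for c in range(k):
        members = points[labels == c]
        if len(members) == 0:
            empty.append(c)
        else:
            centroids[c] = members.mean(axis=0)
    for c in empty:
        filled = [i for i in range(k) if i not in empty]
        dist_to_own = np.array([
            np.sum((points[i] - centroids[labels[i]]) ** 2) if labels[i] in filled else -1.0
            for i in range(len(points))
        ])
        far = int(np.argmax(dist_to_own))
        centroids[c] = points[far]
        labels = labels.copy()
        labels[far] = c
    return centroids


def wss(points: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances (inertia)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    diffs = points - centroids[np.asarray(labels)]
    return float(np.sum(diffs ** 2))


def _init_centroids(
    points: np.ndarray, k: int, init: str, rng: np.random.Generator
) -> np.ndarray:
    n = len(points)
    if init == "random":
        idx = rng.choice(n, size=k, replace=False)
        return points[idx].copy()
    # k-means++: D² sampling
    centroids = np.empty((k, points.shape[1]), dtype=float)
    centroids[0] = points[rng.integers(n)]
    closest_sq = cdist(points, centroids[:1], metric="sqeuclidean")[:, 0]
    for c in range(1, k):
        total = closest_sq.sum()
        if total <= 0:  # all points coincide with chosen centroids
            centroids[c:] = points[rng.choice(n, size=k - c)]
            break
        probs = closest_sq / total
        centroids[c] = points[rng.choice(n, p=probs)]
        new_sq = cdist(points, centroids[c:c + 1], metric="sqeuclidean")[:, 0]
        closest_sq = np.minimum(closest_sq, new_sq)
    return centroids


def _lloyd_single(
    points: np.ndarray, config: KMeansConfig, rng: np.random.Generator
) -> ClusteringResult:
    centroids = _init_centroids(points, config.k, config.init, rng)
    trajectory: list[float] = []
    converged = False
    labels = assign(points, centroids, config.metric)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        new_centroids = update_centroids(points, labels, config.k)
        shift = np.sqrt(np.sum((new_centroids - centroids) ** 2, axis=1)).max()
        centroids = new_centroids
        labels = assign(points, centroids, config.metric)
        trajectory.append(wss(points, labels, centroids))
        if shift < config.tol:
            converged = True
            break
    return ClusteringResult(
        labels=labels,
        centroids=centroids,
        wss=wss(points, labels, centroids),
        wss_trajectory=trajectory,
        n_iter=n_iter,
        converged=converged,
        config=config,
    )


def kmeans(points: np.ndarray, config: KMeansConfig) -> ClusteringResult:
    """Best-of-``n_init`` Lloyd's K-means, deterministic given the seed.

    Each restart iterates assign → update-centroids until the maximum centroid
    shift drops below ``tol`` or ``max_iter`` is reached; the restart with the
    lowest final WSS wins.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ClusteringError("points must be finite")
    n = len(points)
    if config.k > n:
        raise ClusteringError(f"k={config.k} exceeds number of points n={n}")
    rng = np.random.default_rng(config.seed)
    best: ClusteringResult | None = None
    for _ in range(config.n_init):
        result = _lloyd_single(points, config, rng)
        if best is None or result.wss < best.wss:
            best = result
    assert best is not None
    return best


@dataclass
class ElbowResult:
    """WSS-per-k scan with a knee suggestion."""

    ks: list[int]
    wss_values: list[float]
    suggested_k: int | None = field(default=None)


def elbow_scan(
    points: np.ndarray, k_range: range | list[int], config: KMeansConfig
) -> ElbowResult:
    """Best-of-``n_init`` WSS for each k, plus a simple knee suggestion.

    The suggestion is the k maximizing the second difference
    WSS(k−1) − 2·WSS(k) + WSS(k+1) over the interior of the scanned range —
    the crudest discrete-curvature estimate of the elbow. Restarts for each k
    use a seed derived from ``config.seed`` and k, so the scan is
    reproducible while ks stay independent.
    """
    ks = sorted(set(int(k) for k in k_range))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if ks[0] < 1 or ks[-1] > len(points):
        raise ClusteringError(f"k range {ks[0]}..{ks[-1]} outside [1, {len(points)}]")
    values = []
    for k in ks:
        cfg = replace(config, k=k, seed=(config.seed * 100003 + k) % (2 ** 31))
        values.append(kmeans(points, cfg).wss)
    suggested = None
    if len(ks) >= 3:
        curvature = [
            values[i - 1] - 2 * values[i] + values[i + 1] for i in range(1, len(ks) - 1)
        ]
        suggested = ks[1 + int(np.argmax(curvature))]
    return ElbowResult(ks=ks, wss_values=values, suggested_k=suggested)
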