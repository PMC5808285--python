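"""K-means clustering written out from first principles.

Assignment uses plain Euclidean distance, the objective is the
within-cluster sum of squared distances, centroids are recomputed as the
arithmetic mean of their members, and iteration stops the first time no
point changes cluster.  Initialization is either a uniform random sample
of distinct points or a deterministic farthest-apart sweep.  No feature
scaling is applied: reflectance bands share units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterModel",
    "Assignment",
    "KMeansTrace",
    "init_centroids",
    "assign",
    "objective",
    "update_centroids",
    "fit",
    "predict",
]


@dataclass
class ClusterModel:
    """Fitted cluster centers, one row per cluster."""

    centroids: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or len(self.centroids) < 1:
            raise ValueError("centroids must be a c x bands matrix with c >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def c(self) -> int:
        return len(self.centroids)


@dataclass
class Assignment:
    """Cluster index per data point."""

    cluster_index: np.ndarray
    c: int

    def __post_init__(self) -> None:
        self.cluster_index = np.asarray(self.cluster_index, dtype=np.int64)
        if self.cluster_index.size and (
            self.cluster_index.min() < 0 or self.cluster_index.max() >= self.c
        ):
            raise ValueError("cluster indices must lie in [0, c)")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_index, minlength=self.c)


@dataclass
class KMeansTrace:
    """Objective and reassignment counts per iteration."""

    objective: list[float] = field(default_factory=list)
    n_reassigned: list[int] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.objective)


def _distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """n x c Euclidean distance matrix."""
    diff = points[:, None, :] - centroids[None, :, :]
    return np.sqrt(np.einsum("ncb,ncb->nc", diff, diff))


def init_centroids(
    points: np.ndarray,
    c: int,
    method: str = "farthest",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Choose ``c`` starting centers from the data points.

    ``random`` samples c distinct points without replacement.  ``farthest``
    is deterministic: the first center is the point nearest the data mean
    and each subsequent center the point maximizing its minimum distance
    to those already chosen.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < c:
        raise ValueError(f"need at least c={c} points, got {n}")
    if method == "random":
        rng = np.random.default_rng() if rng is None else rng
        take = rng.choice(n, size=c, replace=False)
        return points[take].copy()
    if method == "farthest":
        chosen = [int(np.argmin(np.linalg.norm(points - points.mean(axis=0), axis=1)))]
        while len(chosen) < c:
            d = _distances(points, points[chosen])
            min_d = d.min(axis=1)
            min_d[chosen] = -1.0
            chosen.append(int(np.argmax(min_d)))
        return points[chosen].copy()
    raise ValueError(f"unknown init method '{method}'")


def assign(points: np.ndarray, centroids: np.ndarray) -> Assignment:
    """Assign every point to its nearest center (ties -> lowest index)."""
    points = np.asarray(points, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    if points.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: points have {points.shape[1]} features, "
            f"centroids {centroids.shape[1]}"
        )
    d = _distances(points, centroids)
    return Assignment(cluster_index=np.argmin(d, axis=1), c=len(centroids))


def objective(points: np.ndarray, centroids: np.ndarray, assignment: Assignment) -> float:
    """Within-cluster sum of squared Euclidean distances."""
    points = np.asarray(points, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    diff = points - centroids[assignment.cluster_index]
    return float(np.einsum("nb,nb->", diff, diff))


def update_centroids(
    points: np.ndarray, assignment: Assignment, c: int
) -> np.ndarray:
    """Recompute each center as the mean of its members.

    A cluster left empty is re-seeded at the point farthest from its
    nearest current centroid (the worst-served point).
    """
    points = np.asarray(points, dtype=float)
    centroids = np.empty((c, points.shape[1]))
    sizes = np.bincount(assignment.cluster_index, minlength=c)
    for i in range(c):
        if sizes[i] > 0:
            members = points[assignment.cluster_index == i]
            centroids[i] = members.mean(axis=0)
            # constant features must come back exactly, not with summation
            # round-off (otherwise degenerate inputs cycle forever)
            const = members.min(axis=0) == members.max(axis=0)
            centroids[i, const] = members[0, const]
    empty = np.nonzero(sizes == 0)[0]
    if len(empty):
        occupied = centroids[sizes > 0]
        for i in empty:
            if len(occupied) == 0:
                centroids[i] = points.mean(axis=0)
                continue
            min_d = _distances(points, occupied).min(axis=1)
            centroids[i] = points[int(np.argmax(min_d))]
            occupied = np.vstack([occupied, centroids[i]])
    return centroids


def fit(
    points: np.ndarray,
    c: int,
    init_method: str = "farthest",
    rng: np.random.Generator | None = None,
    max_iter: int = 300,
    wavelengths: np.ndarray | None = None,
) -> tuple[ClusterModel, KMeansTrace]:
    """Run the full assign/update loop until no point is reassigned.

    The objective is recorded after every assignment step; a ``max_iter``
    cap guards against pathological cycling (convergence flag stays False
    if the cap is hit first).
    """
    points = np.asarray(points, dtype=float)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if len(points) < c:
        raise ValueError(f"need at least c={c} points, got {len(points)}")
    centroids = init_centroids(points, c, method=init_method, rng=rng)
    assignment = assign(points, centroids)
    trace = KMeansTrace()
    trace.objective.append(objective(points, centroids, assignment))
    trace.n_reassigned.append(len(points))  # everything assigned fresh
    for _ in range(max_iter):
        centroids = update_centroids(points, assignment, c)
        new_assignment = assign(points, centroids)
        moved = int(np.count_nonzero(new_assignment.cluster_index != assignment.cluster_index))
        trace.objective.append(objective(points, centroids, new_assignment))
        trace.n_reassigned.append(moved)
        assignment = new_assignment
        if moved == 0:
            trace.converged = True
            break
    model = ClusterModel(centroids=centroids, wavelengths=wavelengths)
    return model, trace


def predict(model: ClusterModel, points: np.ndarray) -> Assignment:
    """Nearest-centroid assignment with no centroid update; idempotent."""
    return assign(points, model.centroids)
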