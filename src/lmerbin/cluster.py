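"""k-means over composition vectors with the rank-band distance.

Assignment uses the modified Chebychev distance; the center update is the
plain arithmetic mean of the assigned rows (Forgy initialisation, k
distinct data rows).  Because the mean is not the analytic minimiser of
the band-restricted distance, the objective is not guaranteed to decrease
monotonically across iterations; convergence is declared when the
assignment vector stops changing.  The algorithm is restarted from several
seeds and the run with the smallest objective is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import DistanceParams, band_distances, modified_chebychev
from .errors import InputError, ParameterError


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of one k-means run (or the best of several restarts)."""

    assignments: np.ndarray  # int cluster id per row, 0..k-1
    centers: np.ndarray      # (k, m)
    objective: float
    n_iter: int
    seed: int
    converged: bool

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def assign_to_centers(matrix: np.ndarray, centers: np.ndarray,
                      params: DistanceParams | None = None) -> np.ndarray:
    """Assign every row to the nearest center; ties go to the lowest index."""
    centers = np.atleast_2d(centers)
    if centers.shape[0] < 1:
        raise InputError("centers must be non-empty")
    d = band_distances(matrix, centers, params)
    return np.argmin(d, axis=1)  # argmin returns first minimum: lowest index


def update_centers(matrix: np.ndarray, assignments: np.ndarray, k: int,
                   prev_centers: np.ndarray | None = None,
                   params: DistanceParams | None = None) -> np.ndarray:
    """Componentwise mean of the rows assigned to each cluster.

    An empty cluster is re-seeded with the data row farthest (by the band
    distance) from the cluster's previous center, so the result always has
    ``k`` usable centers; this requires ``prev_centers``.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    matrix = np.asarray(matrix, dtype=float)
    assignments = np.asarray(assignments)
    if assignments.shape[0] != matrix.shape[0]:
        raise InputError("assignments length does not match matrix rows")
    if assignments.min(initial=0) < 0 or assignments.max(initial=0) >= k:
        raise InputError("assignments contain ids outside 0..k-1")
    centers = np.empty((k, matrix.shape[1]))
    empties = []
    for j in range(k):
        members = assignments == j
        if members.any():
            centers[j] = matrix[members].mean(axis=0)
        else:
            empties.append(j)
    if empties:
        if prev_centers is None:
            raise InputError(
                f"clusters {empties} are empty and no previous centers were "
                f"given for re-seeding")
        taken: set[int] = set()
        for j in empties:
            d = band_distances(matrix, prev_centers[j][None, :], params)[:, 0]
            for i in taken:
                d[i] = -np.inf
            row = int(np.argmax(d))
            taken.add(row)
            centers[j] = matrix[row]
    return centers


def objective(matrix: np.ndarray, assignments: np.ndarray,
              centers: np.ndarray,
              params: DistanceParams | None = None) -> float:
    """Sum over rows of the band distance to the assigned cluster center."""
    d = band_distances(matrix, centers, params)
    return float(d[np.arange(d.shape[0]), np.asarray(assignments)].sum())


def kmeans(matrix: np.ndarray, k: int,
           params: DistanceParams | None = None,
           max_iter: int = 100, seed: int = 0) -> ClusteringResult:
    """One seeded k-means run.

    Initial centers are ``k`` distinct rows sampled without replacement;
    assignment and update alternate until the assignment vector repeats or
    ``max_iter`` is reached.  Identical inputs and seed give identical
    output.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of rows n={n}")
    if max_iter < 1:
        raise ParameterError(f"max_iter must be >= 1, got {max_iter}")
    rng = np.random.default_rng(seed)
    centers = matrix[rng.choice(n, size=k, replace=False)].copy()
    prev_assign: np.ndarray | None = None
    assign = np.zeros(n, dtype=np.int64)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        assign = assign_to_centers(matrix, centers, params)
        # repair empty clusters before accepting the assignment
        for _ in range(k):
            sizes = np.bincount(assign, minlength=k)
            if sizes.min() > 0:
                break
            centers = update_centers(matrix, assign, k, prev_centers=centers,
                                     params=params)
            assign = assign_to_centers(matrix, centers, params)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            converged = True
            break
        prev_assign = assign
        centers = update_centers(matrix, assign, k, prev_centers=centers,
                                 params=params)
    obj = objective(matrix, assign, centers, params)
    return ClusteringResult(assignments=assign, centers=centers,
                            objective=obj, n_iter=n_iter, seed=int(seed),
                            converged=converged)


def best_of_restarts(matrix: np.ndarray, k: int,
                     params: DistanceParams | None = None,
                     restarts: int = 10, max_iter: int = 100,
                     base_seed: int = 0) -> ClusteringResult:
    """Run ``kmeans`` with seeds ``base_seed .. base_seed+restarts-1`` and
    return the run with the minimum objective (ties: lowest seed)."""
    if restarts < 1:
        raise ParameterError(f"restarts must be >= 1, got {restarts}")
    best: ClusteringResult | None = None
    for s in range(base_seed, base_seed + restarts):
        res = kmeans(matrix, k, params=params, max_iter=max_iter, seed=s)
        if best is None or res.objective < best.objective:
            best = res
    assert best is not None
    return best
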