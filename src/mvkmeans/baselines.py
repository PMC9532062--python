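"""Single-view baselines: classical K-means (Lloyd) and fuzzy C-means.

These are the comparison models of the survey protocol. They consume one
feature matrix; multi-view data is fed to them as the column-wise
concatenation of its views.

Conventions shared with the multi-view model (so that trajectories are
directly comparable):

* initial centers are ``k`` distinct data rows drawn uniformly at random;
* restart r uses the r-th child of ``numpy.random.SeedSequence(seed)``;
* ties in nearest-center assignment break toward the lowest center index;
* an empty cluster is repaired by reseeding its center at the point farthest
  from its currently assigned center (which strictly lowers the objective);
* convergence: assignments unchanged, |dJ| <= tol, or the iteration cap
  (default 100).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KMeansModel",
    "FCMModel",
    "assign_nearest",
    "update_centers",
    "kmeans_objective",
    "kmeans_fit",
    "kmeans_predict",
    "fcm_membership",
    "fcm_objective",
    "fcm_fit",
    "fcm_harden",
    "fcm_predict",
]


# ---------------------------------------------------------------------------
# Shared helpers (also used by the multi-view model)
# ---------------------------------------------------------------------------

def restart_rngs(seed, n_restarts: int) -> list[np.random.Generator]:
    """One RNG per restart, all derived from a single integer seed."""
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    return [np.random.default_rng(c) for c in children]


def init_rows(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Indices of k distinct data rows chosen uniformly at random."""
    return rng.choice(n, size=k, replace=False)


def squared_distances(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """N x k matrix of squared Euclidean distances."""
    d2 = (
        (X * X).sum(axis=1)[:, None]
        + (centers * centers).sum(axis=1)[None, :]
        - 2.0 * X @ centers.T
    )
    return np.maximum(d2, 0.0)


def repair_empty_clusters(
    d2_to_own: np.ndarray, assignment: np.ndarray, k: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Reseed each empty cluster at the point farthest from its own center.

    ``d2_to_own[i]`` is point i's squared distance to its assigned center.
    Moving the globally worst point into the empty cluster zeroes that
    point's cost and leaves every other term unchanged, so the objective
    strictly decreases. Returns the repaired assignment and the (cluster,
    point) reseeds performed.
    """
    assignment = assignment.copy()
    d2_to_own = d2_to_own.copy()
    moves: list[tuple[int, int]] = []
    counts = np.bincount(assignment, minlength=k)
    for j in np.flatnonzero(counts == 0):
        eligible = counts[assignment] > 1
        if not eligible.any():  # k > number of distinct points; leave empty
            continue
        i = int(np.flatnonzero(eligible)[np.argmax(d2_to_own[eligible])])
        logger.debug("empty cluster %d reseeded at point %d", j, i)
        counts[assignment[i]] -= 1
        counts[j] += 1
        assignment[i] = j
        d2_to_own[i] = 0.0
        moves.append((j, i))
    return assignment, moves


# ---------------------------------------------------------------------------
# K-means
# ---------------------------------------------------------------------------

@dataclass
class KMeansModel:
    """Fitted K-means state: centers z_j, hard assignment, J trajectory."""

    centers: np.ndarray
    assignment: np.ndarray
    objective_trajectory: list[float]
    n_iter: int
    converged: bool
    seed: object = None
    assignment_trajectory: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def objective(self) -> float:
        return self.objective_trajectory[-1]

    def to_json_dict(self) -> dict:
        return {
            "algo": "kmeans",
            "centers": self.centers.tolist(),
            "assignment": self.assignment.tolist(),
            "objective_trajectory": list(map(float, self.objective_trajectory)),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def assign_nearest(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Assign each point to the center minimizing squared Euclidean distance.

    Ties break toward the lowest center index.
    """
    return np.argmin(squared_distances(np.asarray(X, float), np.asarray(centers, float)), axis=1)


def update_centers(X: np.ndarray, assignment: np.ndarray, k: int | None = None) -> np.ndarray:
    """Each center becomes the arithmetic mean of its assigned points.

    Raises on an empty cluster: the fitting loop repairs empties *before*
    calling this (see :func:`repair_empty_clusters`).
    """
    X = np.asarray(X, float)
    assignment = np.asarray(assignment)
    if k is None:
        k = int(assignment.max()) + 1
    counts = np.bincount(assignment, minlength=k)
    if (counts == 0).any():
        raise ValueError(f"empty cluster(s) {np.flatnonzero(counts == 0).tolist()}")
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, assignment, X)
    return sums / counts[:, None]


def kmeans_objective(X: np.ndarray, centers: np.ndarray, assignment: np.ndarray) -> float:
    """Error squared sum criterion: sum of squared distances to assigned centers."""
    X = np.asarray(X, float)
    diff = X - np.asarray(centers, float)[np.asarray(assignment)]
    return float((diff * diff).sum())


def _lloyd(X, centers, k, max_iter, tol):
    """One Lloyd run from given initial centers."""
    trajectory: list[float] = []
    assignments: list[np.ndarray] = []
    prev_assignment = None
    converged = False
    for _ in range(max_iter):
        d2 = squared_distances(X, centers)
        assignment = np.argmin(d2, axis=1)
        assignment, moves = repair_empty_clusters(
            d2[np.arange(len(assignment)), assignment], assignment, k
        )
        centers = update_centers(X, assignment, k)
        trajectory.append(kmeans_objective(X, centers, assignment))
        assignments.append(assignment)
        if prev_assignment is not None and np.array_equal(assignment, prev_assignment):
            converged = True
            break
        if len(trajectory) >= 2 and abs(trajectory[-2] - trajectory[-1]) <= tol:
            converged = True
            break
        prev_assignment = assignment
    return centers, assignment, trajectory, assignments, converged


def kmeans_fit(
    X: np.ndarray,
    k: int,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed=None,
    n_restarts: int = 10,
    init: np.ndarray | None = None,
) -> KMeansModel:
    """Lloyd's algorithm, best of ``n_restarts`` random-row initializations.

    ``init`` may supply explicit initial centers (k x d), in which case a
    single run is performed from them.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= N={n}")
    if init is not None:
        starts = [np.asarray(init, dtype=float).copy()]
    else:
        starts = [X[init_rows(rng, n, k)].copy() for rng in restart_rngs(seed, n_restarts)]

    best = None
    for centers0 in starts:
        centers, assignment, trajectory, assignments, converged = _lloyd(
            X, centers0, k, max_iter, tol
        )
        if best is None or trajectory[-1] < best[2][-1]:
            best = (centers, assignment, trajectory, assignments, converged)

    centers, assignment, trajectory, assignments, converged = best
    return KMeansModel(
        centers=centers,
        assignment=assignment,
        objective_trajectory=trajectory,
        n_iter=len(trajectory),
        converged=converged,
        seed=seed,
        assignment_trajectory=assignments,
    )


def kmeans_predict(model: KMeansModel, X: np.ndarray) -> np.ndarray:
    if np.asarray(X).shape[1] != model.centers.shape[1]:
        raise ValueError("dimension mismatch between data and model centers")
    return assign_nearest(X, model.centers)


# ---------------------------------------------------------------------------
# Fuzzy C-means
# ---------------------------------------------------------------------------

@dataclass
class FCMModel:
    """Fitted fuzzy C-means state.

    ``membership`` rows live on the probability simplex; ``fuzzifier`` m > 1
    controls how soft the partition is.
    """

    centers: np.ndarray
    membership: np.ndarray
    fuzzifier: float
    objective_trajectory: list[float]
    n_iter: int
    converged: bool
    seed: object = None

    @property
    def objective(self) -> float:
        return self.objective_trajectory[-1]

    def to_json_dict(self) -> dict:
        return {
            "algo": "fcm",
            "centers": self.centers.tolist(),
            "fuzzifier": self.fuzzifier,
            "assignment": fcm_harden(self.membership).tolist(),
            "objective_trajectory": list(map(float, self.objective_trajectory)),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def fcm_membership(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update: u_ik proportional to d_ik^(-2/(m-1)).

    A point coinciding with one or more centers gets its mass split equally
    over those centers (the limit convention).
    """
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    d2 = squared_distances(np.asarray(X, float), np.asarray(centers, float))
    zero = d2 <= 0.0
    u = np.zeros_like(d2)
    on_center = zero.any(axis=1)
    if on_center.any():
        z = zero[on_center]
        u[on_center] = z / z.sum(axis=1, keepdims=True)
    rest = ~on_center
    if rest.any():
        r = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = r / r.sum(axis=1, keepdims=True)
    return u


def fcm_objective(X: np.ndarray, centers: np.ndarray, membership: np.ndarray, m: float) -> float:
    d2 = squared_distances(np.asarray(X, float), np.asarray(centers, float))
    return float(((membership ** m) * d2).sum())


def fcm_harden(membership: np.ndarray) -> np.ndarray:
    """Hard assignment by per-row argmax (ties toward the lowest index)."""
    return np.argmax(membership, axis=1)


def fcm_fit(
    X: np.ndarray,
    k: int,
    m: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed=None,
    n_restarts: int = 1,
) -> FCMModel:
    """Alternating membership/center updates from random-row initial centers."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    if k < 1 or k > n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= N={n}")

    best = None
    for rng in restart_rngs(seed, n_restarts):
        centers = X[init_rows(rng, n, k)].copy()
        trajectory: list[float] = []
        membership = None
        converged = False
        for _ in range(max_iter):
            membership = fcm_membership(X, centers, m)
            um = membership ** m
            weights = um.sum(axis=0)
            # a cluster with vanishing total membership keeps its old center
            nz = weights > 0
            new_centers = centers.copy()
            new_centers[nz] = (um.T[nz] @ X) / weights[nz, None]
            centers = new_centers
            trajectory.append(fcm_objective(X, centers, membership, m))
            if len(trajectory) >= 2 and abs(trajectory[-2] - trajectory[-1]) <= tol:
                converged = True
                break
        if best is None or trajectory[-1] < best[2][-1]:
            best = (centers, membership, trajectory, converged)

    centers, membership, trajectory, converged = best
    return FCMModel(
        centers=centers,
        membership=membership,
        fuzzifier=m,
        objective_trajectory=trajectory,
        n_iter=len(trajectory),
        converged=converged,
        seed=seed,
    )


def fcm_predict(model: FCMModel, X: np.ndarray) -> np.ndarray:
    if np.asarray(X).shape[1] != model.centers.shape[1]:
        raise ValueError("dimension mismatch between data and model centers")
    return fcm_harden(fcm_membership(X, model.centers, model.fuzzifier))
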