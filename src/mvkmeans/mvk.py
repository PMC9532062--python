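"""Weighted multi-view K-means (MvK-means).

K-means extended to V aligned views with per-view centers and a learned
weight vector w on the probability simplex controlling each view's influence.
The objective is

    J_H = sum_v w_v^p * D_v + eta * sum_v w_v^p,
    D_v = sum_j sum_i phi_ij ||x_i^(v) - z_j^(v)||^2,

where phi_ij is the hard cluster-membership indicator, p > 1 the weight
exponent and eta >= 0 a regularizer that softens weight contrast (eta large
drives the weights toward uniform). The fit alternates three block
minimizations, each of which cannot increase J_H:

* assignment: point i goes to argmin_j sum_v w_v^p ||x_i^(v) - z_j^(v)||^2;
* centers: z_j^(v) is the per-view mean of the points assigned to cluster j
  (independent of the weights);
* weights: the simplex-constrained Lagrangian solution
  w_v = (D_v + eta)^(-1/(p-1)) / sum_u (D_u + eta)^(-1/(p-1)),
  strictly decreasing in D_v — a high-dispersion (low-quality) view gets
  less weight.

With V = 1 (or weight_mode="fixed_uniform" and V views of equal scale) the
procedure reduces to classical K-means; initialization, tie-breaking, empty
cluster repair and convergence rules are shared with
:mod:`mvkmeans.baselines` so the reduction holds trajectory-for-trajectory.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .baselines import (
    init_rows,
    repair_empty_clusters,
    restart_rngs,
    squared_distances,
    update_centers,
)
from .data import MultiViewDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ViewWeights",
    "MvKMeansModel",
    "mvk_objective",
    "mvk_assign",
    "mvk_update_centers",
    "mvk_update_weights",
    "view_dispersions",
    "mvk_fit",
    "mvk_predict",
]

_SIMPLEX_TOL = 1e-8


@dataclass
class ViewWeights:
    """View weight vector on the probability simplex, with its hyperparameters.

    ``w`` sums to 1 with entries in [0, 1]; ``p`` > 1 is the weight exponent
    (p -> 1+ concentrates mass on the best view, large p flattens); ``eta``
    >= 0 regularizes toward uniform weights.
    """

    w: np.ndarray
    p: float = 2.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or self.w.size < 1:
            raise ValueError("w must be a non-empty vector")
        if self.p <= 1:
            raise ValueError("weight exponent p must exceed 1")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if (self.w < -_SIMPLEX_TOL).any() or (self.w > 1 + _SIMPLEX_TOL).any():
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.w.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")

    @classmethod
    def uniform(cls, n_views: int, p: float = 2.0, eta: float = 0.0) -> "ViewWeights":
        return cls(w=np.full(n_views, 1.0 / n_views), p=p, eta=eta)


@dataclass
class MvKMeansModel:
    """Fitted MvK-means state.

    ``centers[v]`` is the C x d_v center matrix of view v; ``weights`` the
    final view weights; ``assignment`` the hard partition (indicator rows sum
    to 1); ``objective_trajectory`` the non-increasing J_H values per
    iteration of the best restart.
    """

    centers: list[np.ndarray]
    weights: ViewWeights
    assignment: np.ndarray
    objective_trajectory: list[float]
    n_iter: int
    converged: bool
    n_clusters: int
    weight_mode: str = "learned"
    seed: object = None
    assignment_trajectory: list[np.ndarray] = field(default_factory=list, repr=False)
    weight_trajectory: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def objective(self) -> float:
        return self.objective_trajectory[-1]

    def to_json_dict(self) -> dict:
        return {
            "algo": "mvk",
            "centers": [c.tolist() for c in self.centers],
            "weights": self.weights.w.tolist(),
            "p": self.weights.p,
            "eta": self.weights.eta,
            "weight_mode": self.weight_mode,
            "assignment": self.assignment.tolist(),
            "objective_trajectory": list(map(float, self.objective_trajectory)),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_clusters": self.n_clusters,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def from_json_dict(cls, d: dict) -> "MvKMeansModel":
        return cls(
            centers=[np.asarray(c, float) for c in d["centers"]],
            weights=ViewWeights(np.asarray(d["weights"], float), d["p"], d["eta"]),
            assignment=np.asarray(d["assignment"], int),
            objective_trajectory=list(d["objective_trajectory"]),
            n_iter=d["n_iter"],
            converged=d["converged"],
            n_clusters=d["n_clusters"],
            weight_mode=d.get("weight_mode", "learned"),
            seed=d.get("seed"),
        )


# ---------------------------------------------------------------------------
# Block updates
# ---------------------------------------------------------------------------

def _weighted_d2(views, centers, weights: ViewWeights) -> np.ndarray:
    """N x C matrix of sum_v w_v^p ||x_i^(v) - z_j^(v)||^2."""
    wp = weights.w ** weights.p
    total = None
    for wv, X, Z in zip(wp, views, centers):
        d2 = squared_distances(np.asarray(X, float), np.asarray(Z, float))
        total = wv * d2 if total is None else total + wv * d2
    return total


def mvk_assign(dataset: MultiViewDataset, centers, weights: ViewWeights) -> np.ndarray:
    """Assign each respondent to the cluster minimizing the weighted distance.

    Ties break toward the lowest cluster index. A zero-weight view has no
    influence on the assignment.
    """
    return np.argmin(_weighted_d2(dataset.views, centers, weights), axis=1)


def mvk_update_centers(
    dataset: MultiViewDataset, assignment: np.ndarray, n_clusters: int | None = None
) -> list[np.ndarray]:
    """Per-view means of the assigned points (independent of the weights)."""
    if n_clusters is None:
        n_clusters = int(np.max(assignment)) + 1
    return [update_centers(X, assignment, n_clusters) for X in dataset.views]


def view_dispersions(views, centers, assignment: np.ndarray) -> np.ndarray:
    """D_v = within-cluster sum of squared distances of each view."""
    assignment = np.asarray(assignment)
    out = np.empty(len(views))
    for v, (X, Z) in enumerate(zip(views, centers)):
        diff = np.asarray(X, float) - np.asarray(Z, float)[assignment]
        out[v] = (diff * diff).sum()
    return out


def mvk_update_weights(dispersions, p: float = 2.0, eta: float = 0.0) -> ViewWeights:
    """Closed-form simplex-constrained weight update.

    ``w_v = (D_v + eta)^(-1/(p-1)) / sum_u (D_u + eta)^(-1/(p-1))`` — the
    Lagrangian minimizer of J_H over the simplex with dispersions fixed.
    If some ``D_v + eta`` are exactly zero while others are positive, the
    limit puts all mass uniformly on the zero-dispersion views.
    """
    D = np.asarray(dispersions, dtype=float)
    if p <= 1:
        raise ValueError("weight exponent p must exceed 1")
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    z = D + eta
    if (z < 0).any():
        raise ValueError("dispersions must be nonnegative")
    if (z == 0).any():
        logger.info("zero-dispersion view(s): weight mass split uniformly over them")
        w = (z == 0).astype(float)
    else:
        w = z ** (-1.0 / (p - 1.0))
    return ViewWeights(w=w / w.sum(), p=p, eta=eta)


def mvk_objective(dataset: MultiViewDataset, model: MvKMeansModel) -> float:
    """J_H = sum_v w_v^p D_v + eta sum_v w_v^p for the model's partition."""
    return _objective(
        dataset.views,
        model.centers,
        model.assignment,
        model.weights.w,
        model.weights.p,
        model.weights.eta,
    )


def _objective(views, centers, assignment, w, p, eta) -> float:
    D = view_dispersions(views, centers, assignment)
    wp = np.asarray(w, float) ** p
    return float((wp * D).sum() + eta * wp.sum())


# ---------------------------------------------------------------------------
# Fit / predict
# ---------------------------------------------------------------------------

def _alternate(views, centers, n_clusters, w0, p, eta, max_iter, tol, learn_weights):
    """One alternating-minimization run from given initial centers/weights."""
    w = w0.copy()
    trajectory: list[float] = []
    assignments: list[np.ndarray] = []
    weight_trail: list[np.ndarray] = []
    prev_assignment = None
    converged = False
    for _ in range(max_iter):
        wd2 = None
        wp = w ** p
        for wv, X, Z in zip(wp, views, centers):
            d2 = squared_distances(X, Z)
            wd2 = wv * d2 if wd2 is None else wd2 + wv * d2
        assignment = np.argmin(wd2, axis=1)
        assignment, _ = repair_empty_clusters(
            wd2[np.arange(len(assignment)), assignment], assignment, n_clusters
        )
        centers = [update_centers(X, assignment, n_clusters) for X in views]
        D = view_dispersions(views, centers, assignment)
        if learn_weights:
            w = mvk_update_weights(D, p, eta).w
        trajectory.append(float(((w ** p) * D).sum() + eta * (w ** p).sum()))
        assignments.append(assignment)
        weight_trail.append(w.copy())
        if prev_assignment is not None and np.array_equal(assignment, prev_assignment):
            converged = True
            break
        if len(trajectory) >= 2 and abs(trajectory[-2] - trajectory[-1]) <= tol:
            converged = True
            break
        prev_assignment = assignment
    return centers, w, assignment, trajectory, assignments, weight_trail, converged


def mvk_fit(
    dataset: MultiViewDataset,
    n_clusters: int = 5,
    p: float = 2.0,
    eta: float = 0.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed=None,
    n_restarts: int = 10,
    weight_mode: str = "learned",
    init_rows_idx: np.ndarray | None = None,
) -> MvKMeansModel:
    """Alternating minimization of J_H, best of ``n_restarts`` restarts.

    Each restart initializes the centers from ``n_clusters`` randomly chosen
    respondents (the same rows in every view, keeping views aligned) and the
    weights at 1/V. ``weight_mode="fixed_uniform"`` skips the weight update,
    the traditional equal-weight multi-view scheme. ``init_rows_idx`` pins
    the initial rows explicitly (single run).
    """
    if weight_mode not in ("learned", "fixed_uniform"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    if p <= 1:
        raise ValueError("weight exponent p must exceed 1")
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    n = dataset.n_samples
    if n_clusters < 1 or n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} must satisfy 1 <= C <= N={n}")

    views = [np.asarray(X, float) for X in dataset.views]
    V = len(views)
    w0 = np.full(V, 1.0 / V)
    if init_rows_idx is not None:
        row_sets = [np.asarray(init_rows_idx)]
    else:
        row_sets = [init_rows(rng, n, n_clusters) for rng in restart_rngs(seed, n_restarts)]

    best = None
    for rows in row_sets:
        centers0 = [X[rows].copy() for X in views]
        result = _alternate(
            views, centers0, n_clusters, w0, p, eta, max_iter, tol,
            learn_weights=(weight_mode == "learned"),
        )
        if best is None or result[3][-1] < best[3][-1]:
            best = result

    centers, w, assignment, trajectory, assignments, weight_trail, converged = best
    return MvKMeansModel(
        centers=centers,
        weights=ViewWeights(w=w, p=p, eta=eta),
        assignment=assignment,
        objective_trajectory=trajectory,
        n_iter=len(trajectory),
        converged=converged,
        n_clusters=n_clusters,
        weight_mode=weight_mode,
        seed=seed,
        assignment_trajectory=assignments,
        weight_trajectory=weight_trail,
    )


def mvk_predict(model: MvKMeansModel, dataset: MultiViewDataset) -> np.ndarray:
    """Assign new respondents with frozen centers and weights."""
    if dataset.n_views != len(model.centers):
        raise ValueError(
            f"model has {len(model.centers)} views, data has {dataset.n_views}"
        )
    for v, (X, Z) in enumerate(zip(dataset.views, model.centers)):
        if X.shape[1] != Z.shape[1]:
            raise ValueError(
                f"view {v} dimension mismatch: data {X.shape[1]}, model {Z.shape[1]}"
            )
    return mvk_assign(dataset, model.centers, model.weights)


def eta_heuristic(dataset: MultiViewDataset, n_clusters: int = 5, seed=None) -> float:
    """Documented default heuristic: 0.1 x mean per-view dispersion at a
    random-row initialization. Softens weight contrast on the data's scale."""
    n = dataset.n_samples
    rng = np.random.default_rng(seed)
    rows = init_rows(rng, n, n_clusters)
    views = [np.asarray(X, float) for X in dataset.views]
    centers = [X[rows] for X in views]
    w = ViewWeights.uniform(dataset.n_views)
    assignment = np.argmin(_weighted_d2(views, centers, w), axis=1)
    D = view_dispersions(views, centers, assignment)
    return float(0.1 * D.mean())
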