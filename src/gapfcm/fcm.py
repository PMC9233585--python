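"""Plain fuzzy C-means clustering.

Fuzzy C-means (FCM) assigns every data point a graded membership
``u_ik`` in each of ``x`` clusters instead of a hard label, minimising

    J(U, V) = sum_i sum_k u_ik**w * d_ik**2,

where ``d_ik**2`` is the squared Euclidean distance from point ``k`` to
center ``v_i`` and ``w > 1`` is the fuzzifier.  Alternating the two
stationarity updates (memberships for fixed centers, centers for fixed
memberships) decreases J monotonically.

Conventions used throughout the package: the membership matrix ``u``
has shape ``(n_clusters, n_points)`` with columns summing to 1; data is
``(n_points, n_features)``; centers are ``(n_clusters, n_features)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DegenerateClusterWarning",
    "squared_distances",
    "update_memberships_fcm",
    "update_centers",
    "fcm_objective",
    "run_fcm",
    "FcmResult",
]


class DegenerateClusterWarning(UserWarning):
    """A cluster lost all membership mass and its center was re-seeded."""


def _check_data(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"data must be 2-D (n_points, n_features), got shape {data.shape}")
    if data.size == 0:
        raise ValueError("data is empty")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains non-finite values")
    return data


def squared_distances(data: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between points and cluster centers.

    Parameters
    ----------
    data : (m, b) array
    centers : (x, b) array

    Returns
    -------
    (x, m) array with entry (i, k) = ||data[k] - centers[i]||**2.
    """
    data = _check_data(data)
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2:
        raise ValueError("centers must be 2-D (n_clusters, n_features)")
    if centers.shape[1] != data.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {data.shape[1]} features, "
            f"centers have {centers.shape[1]}"
        )
    d2 = cdist(centers, data, metric="sqeuclidean")
    # cdist can return tiny negatives from cancellation; clamp
    np.maximum(d2, 0.0, out=d2)
    return d2


def _memberships_from_weights(g: np.ndarray, w: float) -> np.ndarray:
    """Column-stochastic memberships u_ik ∝ g_ik**(-1/(w-1)).

    Columns containing an exact zero weight split mass equally among the
    zero entries (the limit of the update formula).
    """
    if w <= 1:
        raise ValueError("fuzzifier w must be > 1")
    g = np.asarray(g, dtype=float)
    zero = g == 0.0
    zero_cols = zero.any(axis=0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = g ** (-1.0 / (w - 1.0))
    u = np.empty_like(inv)
    ok = ~zero_cols
    u[:, ok] = inv[:, ok] / inv[:, ok].sum(axis=0)
    if zero_cols.any():
        zc = zero[:, zero_cols]
        u[:, zero_cols] = zc / zc.sum(axis=0)
    return u


def update_memberships_fcm(d2: np.ndarray, w: float) -> np.ndarray:
    """FCM membership update u_ik = 1 / sum_j (d_ik^2 / d_jk^2)^(1/(w-1)).

    Points coincident with one or more centers get their unit mass split
    equally among the zero-distance clusters.
    """
    d2 = np.asarray(d2, dtype=float)
    if np.any(d2 < 0):
        raise ValueError("squared distances must be non-negative")
    return _memberships_from_weights(d2, w)


def update_centers(data: np.ndarray, u: np.ndarray, w: float) -> np.ndarray:
    """Center update v_i = sum_k u_ik**w a_k / sum_k u_ik**w.

    Raises if a cluster carries no membership mass at all; `run_fcm`
    re-seeds such clusters instead.
    """
    data = _check_data(data)
    u = np.asarray(u, dtype=float)
    if u.shape[1] != data.shape[0]:
        raise ValueError("membership matrix and data disagree on the number of points")
    uw = u**w
    denom = uw.sum(axis=1)
    if np.any(denom == 0.0):
        raise ZeroDivisionError("cluster with all-zero membership; re-seed its center")
    return (uw @ data) / denom[:, None]


def fcm_objective(d2: np.ndarray, u: np.ndarray, w: float) -> float:
    """The FCM objective sum_i sum_k u_ik**w d_ik**2."""
    d2 = np.asarray(d2, dtype=float)
    u = np.asarray(u, dtype=float)
    if d2.shape != u.shape:
        raise ValueError("d2 and u must share shape (n_clusters, n_points)")
    return float((u**w * d2).sum())


@dataclass
class FcmResult:
    """Outcome of an FCM (or penalized FCM) run."""

    memberships: np.ndarray  # (x, m)
    centers: np.ndarray  # (x, b)
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def labels(self) -> np.ndarray:
        """Hard labels by maximum membership; ties go to the lowest index."""
        return np.argmax(self.memberships, axis=0)


def _random_distinct_centers(data: np.ndarray, x: int, rng: np.random.Generator) -> np.ndarray:
    # distinct points in feature space where possible; coincident centers
    # would collapse into one another and can never separate again
    uniq = np.unique(data, axis=0)
    if uniq.shape[0] >= x:
        idx = rng.choice(uniq.shape[0], size=x, replace=False)
        return uniq[idx].copy()
    idx = rng.choice(data.shape[0], size=x, replace=False)
    return data[idx].copy()


def _reseed_degenerate(
    data: np.ndarray, u: np.ndarray, centers: np.ndarray, w: float
) -> np.ndarray:
    """Center update with empty clusters re-seeded at the worst-covered point."""
    uw = u**w
    denom = uw.sum(axis=1)
    dead = denom == 0.0
    if not dead.any():
        return (uw @ data) / denom[:, None]
    warnings.warn(
        f"{int(dead.sum())} cluster(s) lost all membership; re-seeding",
        DegenerateClusterWarning,
        stacklevel=3,
    )
    new = np.empty_like(centers)
    alive = ~dead
    new[alive] = (uw[alive] @ data) / denom[alive, None]
    d2 = squared_distances(data, new[alive]) if alive.any() else None
    for i in np.flatnonzero(dead):
        if d2 is None:
            k = 0
        else:
            k = int(np.argmax(d2.min(axis=0)))
        new[i] = data[k]
    return new


def run_fcm(
    data: np.ndarray,
    n_clusters: int,
    *,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    init_centers: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> FcmResult:
    """Run plain fuzzy C-means to convergence.

    Alternates membership and center updates starting from
    ``init_centers`` (or ``n_clusters`` distinct data points drawn with
    ``seed``) and stops when the maximum center shift drops below
    ``tol`` or ``max_iter`` is reached.  The recorded objective trace is
    non-increasing up to floating-point slack.
    """
    data = _check_data(data)
    m = data.shape[0]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if m < n_clusters:
        raise ValueError(f"need at least n_clusters={n_clusters} points, got {m}")
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=float).copy()
        if centers.shape != (n_clusters, data.shape[1]):
            raise ValueError("init_centers has wrong shape")
    else:
        rng = np.random.default_rng(seed)
        centers = _random_distinct_centers(data, n_clusters, rng)

    trace: list[float] = []
    n_iter = 0
    # stationarity is judged jointly on centers and memberships
    u_prev = update_memberships_fcm(squared_distances(data, centers), fuzzifier)
    for n_iter in range(1, max_iter + 1):
        d2 = squared_distances(data, centers)
        u = update_memberships_fcm(d2, fuzzifier)
        trace.append(fcm_objective(d2, u, fuzzifier))
        new_centers = _reseed_degenerate(data, u, centers, fuzzifier)
        shift = float(np.abs(new_centers - centers).max())
        u_shift = float(np.abs(u - u_prev).max())
        centers = new_centers
        u_prev = u
        if shift < tol and u_shift < tol:
            break
    return FcmResult(memberships=u, centers=centers, objective_trace=trace, n_iter=n_iter)
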