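"""Spatially penalized fuzzy C-means (PFCM).

The plain FCM objective is augmented with a Markov-neighborhood penalty

    A(U, V) = sum_ik u_ik**w d_ik**2  +  sigma * sum_ik u_ik**w (1 - P_ik)**w,

where ``P_ik`` is the mean membership of class ``i`` over the spatial
neighbors of pixel ``k`` and ``sigma >= 0`` weights the penalty.  A high
neighborhood consensus for class ``i`` makes ``(1 - P_ik)`` small, so
memberships that agree with their neighborhood are cheap and isolated
noise pixels are pulled toward the local majority.  With ``sigma = 0``
the algorithm reduces exactly to plain FCM.

The prior ``P`` is column-stochastic by construction (it averages
column-stochastic membership columns) and is lagged one iteration so the
membership update stays closed-form.  Each iteration the prior moves as
far toward its refreshed value as possible without increasing the
penalty term at the current memberships (the penalty is convex in P, so
the step length always exists); this line search makes the recorded
objective trace provably non-increasing — the membership update is
optimal for the prior it sees and the center update only shrinks the
distance term — while the prior still converges to the neighborhood
average of the final memberships.  In practice the full refresh is
accepted at almost every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .fcm import (
    FcmResult,
    _check_data,
    _memberships_from_weights,
    _random_distinct_centers,
    _reseed_degenerate,
    fcm_objective,
    squared_distances,
    update_memberships_fcm,
)

__all__ = [
    "neighbor_prior",
    "pfcm_objective",
    "update_memberships_pfcm",
    "run_pfcm",
    "SegmentationResult",
]

_KERNELS = {
    4: np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float),
    8: np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float),
}


def neighbor_prior(
    u: np.ndarray, height: int, width: int, connectivity: int = 8
) -> np.ndarray:
    """Spatial neighborhood prior: per-pixel mean membership of the neighbors.

    Parameters
    ----------
    u : (x, m) membership matrix with m = height * width, pixels in
        row-major order.
    connectivity : 4 or 8 — which pixels count as neighbors.  Border
        pixels average only over their existing neighbors.

    Returns
    -------
    (x, m) column-stochastic prior P.
    """
    if connectivity not in _KERNELS:
        raise ValueError("connectivity must be 4 or 8")
    u = np.asarray(u, dtype=float)
    x, m = u.shape
    if m != height * width:
        raise ValueError(f"membership matrix has {m} columns but image has {height * width} pixels")
    kernel = _KERNELS[connectivity]
    counts = convolve(np.ones((height, width)), kernel, mode="constant", cval=0.0)
    P = np.empty_like(u)
    for i in range(x):
        sums = convolve(u[i].reshape(height, width), kernel, mode="constant", cval=0.0)
        P[i] = (sums / counts).ravel()
    return P


def pfcm_objective(
    d2: np.ndarray,
    u: np.ndarray,
    P: np.ndarray,
    w: float,
    sigma: float,
    penalty_exponent: float | None = None,
) -> float:
    """The penalized objective A(U, V); ``sigma = 0`` recovers the FCM one."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    d2 = np.asarray(d2, dtype=float)
    u = np.asarray(u, dtype=float)
    P = np.asarray(P, dtype=float)
    if not (d2.shape == u.shape == P.shape):
        raise ValueError("d2, u and P must share shape (n_clusters, n_points)")
    pe = w if penalty_exponent is None else penalty_exponent
    uw = u**w
    return float((uw * d2).sum()) + sigma * float((uw * (1.0 - P) ** pe).sum())


def update_memberships_pfcm(
    d2: np.ndarray,
    P: np.ndarray,
    w: float,
    sigma: float,
    penalty_exponent: float | None = None,
) -> np.ndarray:
    """Minimizer of the penalized objective over column-stochastic U.

    With g_ik = d_ik**2 + sigma (1 - P_ik)**pe the update is
    u_ik = g_ik**(-1/(w-1)) / sum_j g_jk**(-1/(w-1)); zero weights get
    the same equal-split treatment as in plain FCM.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    d2 = np.asarray(d2, dtype=float)
    P = np.asarray(P, dtype=float)
    pe = w if penalty_exponent is None else penalty_exponent
    g = d2 + sigma * (1.0 - P) ** pe
    return _memberships_from_weights(g, w)


@dataclass
class SegmentationResult:
    """Label map plus the full clustering state behind it."""

    labels: np.ndarray  # (H, W) int label map
    memberships: np.ndarray  # (x, m)
    centers: np.ndarray  # (x, b)
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


def run_pfcm(
    image: np.ndarray,
    n_clusters: int,
    *,
    fuzzifier: float = 2.0,
    sigma: float = 1.0,
    connectivity: int = 8,
    penalty_exponent: float | None = None,
    tol: float = 1e-5,
    max_iter: int = 300,
    init_centers: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> SegmentationResult:
    """Segment a 2-D grayscale image with spatially penalized FCM.

    The pixel intensities form a 1-feature data matrix in row-major
    order.  Each iteration recomputes distances from the current
    centers, refreshes the neighbor prior from the previous memberships
    (the very first prior comes from a plain-FCM membership pass at
    ``init_centers``; later refreshes are kept only if they do not
    increase the penalty term, which guarantees a non-increasing
    objective trace), updates memberships with the penalized rule, then
    updates centers.  Stops on center shift < ``tol`` or ``max_iter``.
    Hard labels are per-pixel argmax of membership, ties to the lowest
    class index.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    H, W = image.shape
    data = image.reshape(-1, 1)
    _check_data(data)
    if data.shape[0] < n_clusters:
        raise ValueError("fewer pixels than clusters")
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=float).copy()
        if centers.shape != (n_clusters, 1):
            raise ValueError("init_centers must have shape (n_clusters, 1)")
    else:
        rng = np.random.default_rng(seed)
        centers = _random_distinct_centers(data, n_clusters, rng)

    pe = fuzzifier if penalty_exponent is None else penalty_exponent
    u_prev = update_memberships_fcm(squared_distances(data, centers), fuzzifier)
    P = neighbor_prior(u_prev, H, W, connectivity)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = squared_distances(data, centers)
        P_cand = neighbor_prior(u_prev, H, W, connectivity)
        # monotone prior refresh: take the largest dyadic step toward the
        # candidate that does not raise the penalty at the current
        # memberships (always possible; the penalty is convex in P)
        uw_prev = u_prev**fuzzifier
        pen_old = (uw_prev * (1.0 - P) ** pe).sum()
        step = 1.0
        for _ in range(20):
            P_try = P + step * (P_cand - P)
            if (uw_prev * (1.0 - P_try) ** pe).sum() <= pen_old:
                P = P_try
                break
            step *= 0.5
        u = update_memberships_pfcm(d2, P, fuzzifier, sigma, penalty_exponent)
        trace.append(pfcm_objective(d2, u, P, fuzzifier, sigma, penalty_exponent))
        new_centers = _reseed_degenerate(data, u, centers, fuzzifier)
        shift = float(np.abs(new_centers - centers).max())
        u_shift = float(np.abs(u - u_prev).max())
        centers = new_centers
        u_prev = u
        if shift < tol and u_shift < tol:
            break
    labels = np.argmax(u, axis=0).reshape(H, W)
    return SegmentationResult(
        labels=labels,
        memberships=u,
        centers=centers,
        objective_trace=trace,
        n_iter=n_iter,
    )
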