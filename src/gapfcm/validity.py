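"""Cluster validity indices for fuzzy partitions.

Three classical indices quantify how crisp and well-separated a fuzzy
partition is, for a membership matrix U of k clusters over n points:

* partition coefficient  F(U, k) = (1/n) sum_q sum_w U_qw^2, in
  [1/k, 1]; 1 means a crisp partition, 1/k a maximally fuzzy one;
* partition entropy      H(U, k) = -(1/n) sum_q sum_w U_qw log U_qw
  (natural log, 0·log 0 := 0), in [0, log k]; 0 means crisp;
* compactness/separation S(U, k) = (1/n) sum_q sum_w U_qw^2 ||a_q - v_w||^2
  divided by min_{q,w} ||a_q - v_w||^2 — fuzzy within-cluster scatter
  over the smallest point-to-center distance; lower is better.

The S denominator as defined above degenerates to zero whenever a point
coincides with a center, so it is floored at 1e-12 (with a warning); a
``denominator="centers"`` mode substitutes the Xie–Beni-style minimum
squared distance between center pairs instead.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .fcm import run_fcm, squared_distances
from .ga import GaConfig, run_ga
from .spatial import run_pfcm

__all__ = [
    "partition_coefficient",
    "partition_entropy",
    "compactness_separation",
    "compare_algorithms",
]

_EPS = 1e-12


def _check_u(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError("membership matrix must be 2-D (n_clusters, n_points)")
    if np.any(u < -1e-9) or np.any(u > 1 + 1e-9):
        raise ValueError("memberships must lie in [0, 1]")
    return u


def partition_coefficient(u: np.ndarray) -> float:
    """Mean sum of squared memberships; 1 = crisp, 1/k = uniform."""
    u = _check_u(u)
    n = u.shape[1]
    return float((u**2).sum() / n)


def partition_entropy(u: np.ndarray) -> float:
    """Mean membership entropy (nats); 0 = crisp, log k = uniform."""
    u = _check_u(u)
    n = u.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u > 0.0, u * np.log(u), 0.0)
    return float(-terms.sum() / n)


def compactness_separation(
    u: np.ndarray,
    data: np.ndarray,
    centers: np.ndarray,
    denominator: str = "pointwise",
) -> float:
    """Fuzzy scatter over minimum separation; lower is better.

    ``denominator="pointwise"`` (default) uses min over point-center
    squared distances, floored at 1e-12 when a point sits on a center;
    ``denominator="centers"`` uses the minimum squared distance between
    distinct cluster centers (requires >= 2 centers).
    """
    u = _check_u(u)
    d2 = squared_distances(data, centers)
    if d2.shape != u.shape:
        raise ValueError("u, data and centers disagree on shape")
    n = u.shape[1]
    num = float((u**2 * d2).sum() / n)
    if denominator == "pointwise":
        den = float(d2.min())
        if den < _EPS:
            warnings.warn(
                "a point coincides with a center; flooring the separation "
                "denominator at 1e-12",
                stacklevel=2,
            )
            den = _EPS
    elif denominator == "centers":
        centers = np.asarray(centers, dtype=float)
        if centers.shape[0] < 2:
            raise ValueError("center-pair denominator needs at least 2 centers")
        den = min(
            float(((a - b) ** 2).sum())
            for a, b in itertools.combinations(centers, 2)
        )
        if den < _EPS:
            warnings.warn("coincident cluster centers; flooring at 1e-12", stacklevel=2)
            den = _EPS
    else:
        raise ValueError("denominator must be 'pointwise' or 'centers'")
    return num / den


def compare_algorithms(
    image: np.ndarray,
    n_clusters: int,
    seeds: list[int],
    *,
    fuzzifier: float = 2.0,
    sigma: float = 1.0,
    connectivity: int = 8,
    tol: float = 1e-5,
    max_iter: int = 300,
    ga_config: GaConfig | None = None,
) -> pd.DataFrame:
    """Validity-index comparison of plain FCM vs GA-initialized PFCM.

    For every seed, runs randomly initialized FCM and GA-initialized
    penalized FCM on the same image and computes F, H and S on the final
    memberships and centers.  Returns a tidy frame with one row per
    (seed, algorithm) plus a "mean" row per algorithm.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    image = np.asarray(image, dtype=float)
    data = image.reshape(-1, 1)
    rows = []
    for seed in seeds:
        fcm_res = run_fcm(
            data, n_clusters, fuzzifier=fuzzifier, tol=tol, max_iter=max_iter, seed=seed
        )
        cfg = GaConfig(**{**(ga_config.__dict__ if ga_config else {}), "seed": seed})
        init = run_ga(
            data,
            n_clusters,
            image.shape,
            cfg,
            fuzzifier=fuzzifier,
            sigma=sigma,
            connectivity=connectivity,
        )
        pfcm_res = run_pfcm(
            image,
            n_clusters,
            fuzzifier=fuzzifier,
            sigma=sigma,
            connectivity=connectivity,
            tol=tol,
            max_iter=max_iter,
            init_centers=init,
        )
        for name, res in (("fcm", fcm_res), ("ga-pfcm", pfcm_res)):
            rows.append(
                {
                    "seed": seed,
                    "algorithm": name,
                    "F": partition_coefficient(res.memberships),
                    "H": partition_entropy(res.memberships),
                    "S": compactness_separation(res.memberships, data, res.centers),
                }
            )
    df = pd.DataFrame(rows)
    means = df.groupby("algorithm", as_index=False)[["F", "H", "S"]].mean()
    means.insert(0, "seed", "mean")
    return pd.concat([df, means], ignore_index=True)
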