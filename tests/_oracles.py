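"""Naive loop-based reimplementations used as independent oracles.

Deliberately slow and literal: plain Python loops over points, clusters
and neighbors, kept independent of the vectorized library code they
cross-check.
"""

import math

import numpy as np


def naive_squared_distances(data, centers):
    x, m = len(centers), len(data)
    d2 = np.zeros((x, m))
    for i in range(x):
        for k in range(m):
            d2[i, k] = sum((data[k][j] - centers[i][j]) ** 2 for j in range(len(data[k])))
    return d2


def naive_fcm_objective(d2, u, w):
    total = 0.0
    for i in range(d2.shape[0]):
        for k in range(d2.shape[1]):
            total += u[i, k] ** w * d2[i, k]
    return total


def naive_pfcm_objective(d2, u, P, w, sigma):
    total = naive_fcm_objective(d2, u, w)
    for i in range(d2.shape[0]):
        for k in range(d2.shape[1]):
            total += sigma * u[i, k] ** w * (1.0 - P[i, k]) ** w
    return total


def naive_neighbor_prior(u, H, W, connectivity=8):
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    x = u.shape[0]
    P = np.zeros_like(u)
    for r in range(H):
        for c in range(W):
            k = r * W + c
            neigh = [
                (r + dr) * W + (c + dc)
                for dr, dc in offsets
                if 0 <= r + dr < H and 0 <= c + dc < W
            ]
            for i in range(x):
                P[i, k] = sum(u[i, j] for j in neigh) / len(neigh)
    return P


def naive_partition_coefficient(u):
    x, n = u.shape
    return sum(u[w, q] ** 2 for q in range(n) for w in range(x)) / n


def naive_partition_entropy(u):
    x, n = u.shape
    total = 0.0
    for q in range(n):
        for w in range(x):
            if u[w, q] > 0:
                total += u[w, q] * math.log(u[w, q])
    return -total / n


def naive_compactness_separation(u, data, centers, floor=1e-12):
    d2 = naive_squared_distances(data, centers)
    x, n = u.shape
    num = sum(u[w, q] ** 2 * d2[w, q] for q in range(n) for w in range(x)) / n
    den = max(d2.min(), floor)
    return num / den


def random_membership(rng, x, m):
    """Random column-stochastic (x, m) matrix."""
    u = rng.random((x, m)) + 1e-3
    return u / u.sum(axis=0)
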