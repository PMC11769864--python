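"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the plane-fit oracle
grid-searches normal directions instead of using linear algebra
decompositions; the rank tests are computed from first principles
(explicit rank formula, exhaustive enumeration of rank assignments).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import chi2


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Roughly uniform unit directions on the sphere."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _orthogonal_cost(centered: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Sum of squared perpendicular distances for each candidate normal
    (the optimal plane offset for a given normal passes the centroid)."""
    return np.sum((centered @ normals.T) ** 2, axis=0)


def grid_search_plane_normal(points, seed: int = 0) -> np.ndarray:
    """Brute-force orthogonal-least-squares normal: coarse direction grid
    followed by shrinking-cone refinement (final cone 0.02 deg)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    cands = _fibonacci_sphere(4000)
    best = cands[np.argmin(_orthogonal_cost(centered, cands))]
    rng = np.random.default_rng(seed)
    for cone_deg in (4.0, 0.4, 0.04):
        sigma = math.radians(cone_deg)
        perturb = best[None, :] + sigma * rng.standard_normal((600, 3))
        perturb /= np.linalg.norm(perturb, axis=1, keepdims=True)
        cands = np.vstack([best[None, :], perturb])
        best = cands[np.argmin(_orthogonal_cost(centered, cands))]
    return best


def angle_between_deg(a, b) -> float:
    """Unsigned angle between two directions, ignoring sign (0..90 deg)."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    c = abs(float(a @ b))
    return math.degrees(math.acos(min(1.0, c)))


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Average ranks, written out longhand."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kruskal_wallis_oracle(samples: list[np.ndarray]) -> tuple[float, float]:
    """H from the explicit rank formula with tie correction; p from the
    chi-square approximation with k-1 df."""
    samples = [np.asarray(s, float) for s in samples]
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = _rankdata(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start:start + len(s)]
        h += len(s) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(s)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    if tie > 0:
        h /= tie
    return h, float(chi2.sf(h, len(samples) - 1))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j
    (+0.5 per tie)."""
    return float(np.sum(a[:, None] > b[None, :])
                 + 0.5 * np.sum(a[:, None] == b[None, :]))


def mann_whitney_exact_oracle(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by exhaustive enumeration of all
    C(n1+n2, n1) assignments of the pooled observations to group a."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    u_obs = _u_statistic(a, b)
    u_lo = min(u_obs, len(a) * len(b) - u_obs)
    u_hi = len(a) * len(b) - u_lo
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= u_lo or u >= u_hi:
            count += 1
        total += 1
    return u_obs, min(1.0, count / total)
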