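"""Distance-based community analysis: Bray-Curtis, PAM, CH, NMDS, Procrustes.

These underpin the medoid-based cross-check of the model-based
metacommunity count: PAM clustering with the Calinski-Harabasz index on
one hand, non-metric multidimensional scaling with Procrustes
comparison of ordinations on the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import calinski_harabasz_score

from .data_model import RelAbundanceTable

__all__ = [
    "bray_curtis",
    "pam_cluster",
    "PAMResult",
    "calinski_harabasz",
    "nmds",
    "Ordination",
    "procrustes_r",
]


def bray_curtis(table_or_values) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix between samples.

    Accepts a :class:`RelAbundanceTable` (samples are columns) or an
    (n_samples x n_features) array.  d(a, b) = sum|a-b| / sum(a+b).
    """
    if isinstance(table_or_values, RelAbundanceTable):
        V = table_or_values.values.T
    else:
        V = np.asarray(table_or_values, dtype=float)
    if np.any(V.sum(axis=1) <= 0):
        raise ValueError("zero-sum sample")
    return squareform(pdist(V, metric="braycurtis"))


class PAMResult(NamedTuple):
    labels: np.ndarray
    medoids: np.ndarray  # indices into the distance matrix


def pam_cluster(dist: np.ndarray, k: int, *, seed: int | None = None,
                max_swaps: int = 200) -> PAMResult:
    """Partitioning around medoids (BUILD + SWAP) on a distance matrix.

    Greedy BUILD selects k medoids minimizing total distance to the
    nearest medoid; SWAP exchanges (medoid, non-medoid) pairs while any
    exchange lowers the objective.  ``seed`` only breaks cost ties.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} outside [1, {n}]")
    rng = np.random.default_rng(seed)

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[np.newaxis, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        best = np.flatnonzero(gains == gains.max())
        medoids.append(int(rng.choice(best)))

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    # SWAP
    current = cost(medoids)
    for _ in range(max_swaps):
        improved = False
        for mi in range(k):
            others = [j for j in range(n) if j not in medoids]
            for j in others:
                cand = medoids.copy()
                cand[mi] = j
                c = cost(cand)
                if c < current - 1e-12:
                    medoids, current, improved = cand, c, True
        if not improved:
            break
    medoids_arr = np.array(sorted(medoids))
    labels = np.argmin(D[:, medoids_arr], axis=1)
    return PAMResult(labels=labels, medoids=medoids_arr)


def calinski_harabasz(coords: np.ndarray, labels) -> float:
    """Calinski-Harabasz index [B/(k-1)] / [W/(n-k)] on ordination coordinates."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("Calinski-Harabasz requires at least 2 clusters")
    return float(calinski_harabasz_score(np.asarray(coords, dtype=float), labels))


@dataclass
class Ordination:
    coordinates: np.ndarray  # (n_samples, n_dims)
    stress: float  # Kruskal stress-1
    converged: bool

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be non-negative")


def _classical_mds(D: np.ndarray, n_dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:n_dims]
    return vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))


def _stress_and_disparities(dhat_c: np.ndarray, iso: IsotonicRegression,
                            order: np.ndarray):
    disp = iso.fit_transform(np.arange(order.size), dhat_c[order])
    disparities = np.empty_like(dhat_c)
    disparities[order] = disp
    denom = float(np.sum(dhat_c**2))
    stress = np.sqrt(np.sum((dhat_c - disparities) ** 2) / denom) if denom > 0 else 0.0
    return float(stress), disparities


def nmds(dist: np.ndarray, n_dims: int = 2, *, seed: int | None = None,
         n_restarts: int = 4, tol: float = 1e-7, max_iter: int = 300) -> Ordination:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Alternates isotonic (monotone) regression of configuration distances
    on dissimilarity ranks with Guttman configuration updates.  Restart 0
    starts from classical (metric) MDS, further restarts from random
    configurations; the best final stress wins.  Stress depends on the
    dissimilarities only through their ranks.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    rng = np.random.default_rng(seed)
    triu = np.triu_indices(n, 1)
    delta = D[triu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression()

    best: Ordination | None = None
    for restart in range(max(1, n_restarts)):
        X = (_classical_mds(D, n_dims) if restart == 0
             else rng.normal(size=(n, n_dims)) * delta.mean())
        prev = np.inf
        converged = False
        stress = np.inf
        for _ in range(max_iter):
            dhat = squareform(pdist(X))
            stress, disparities = _stress_and_disparities(dhat[triu], iso, order)
            if stress < 1e-12:
                converged = True
                break
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform
            Dfull = np.zeros((n, n))
            Dfull[triu] = disparities
            Dfull += Dfull.T
            dh = np.maximum(dhat, 1e-12)
            B = -Dfull / dh
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        cand = Ordination(coordinates=X, stress=stress, converged=converged)
        if best is None or cand.stress < best.stress:
            best = cand
    return best


def procrustes_r(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Symmetric Procrustes similarity of two ordinations.

    Both configurations are centred, scaled to unit sum of squares and
    optimally rotated; returns R = sqrt(1 - residual SS), in [0, 1],
    with R = 1 for configurations identical up to
    translation/scaling/rotation.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"configuration shapes differ: {A.shape} vs {B.shape}")
    _, _, disparity = _scipy_procrustes(A, B)
    return float(np.sqrt(max(0.0, 1.0 - disparity)))
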