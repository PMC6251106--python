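"""Non-metric multidimensional scaling (Kruskal stress-1, SMACOF updates).

Configurations are found by iterative majorization: monotone (isotonic)
regression of configuration distances on dissimilarity ranks (primary
treatment of ties) alternating with a Guttman transform.  The first start is
a deterministic classical-scaling (PCoA) configuration and the remaining
``n_starts - 1`` are random; the best final stress wins.  Stress is tracked
per iteration and
an update that would increase stress is rejected, so the accepted stress
sequence is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import isotonic_regression

from .metrics import DistanceMatrix


@dataclass
class OrdinationResult:
    ids: list
    coordinates: np.ndarray  # n x k
    stress: float  # Kruskal stress-1
    n_starts: int
    seed: int
    converged: bool
    stress_history: list  # per-iteration stress of the winning start

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson/PCoA coordinates; the deterministic first NMDS start."""
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(g)
    idx = np.argsort(vals)[::-1][:k]
    comp = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
    if comp.shape[1] < k:
        comp = np.hstack([comp, np.zeros((n, k - comp.shape[1]))])
    return comp


def _one_start(dvec, x0, max_iter, tol):
    x = x0.copy()
    n_pts = x.shape[0]
    history = []
    best_x, best_stress = x, np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(x)
        # primary ties: within equal-dissimilarity blocks, order follows the
        # current configuration distances, so ties impose no constraint
        order = np.lexsort((d, dvec))
        dhat = np.empty_like(d)
        dhat[order] = isotonic_regression(d[order])
        # scale-match disparities to distances (stress-1 normalisation)
        ss_d, ss_dhat = (d**2).sum(), (dhat**2).sum()
        if ss_dhat > 0:
            dhat = dhat * np.sqrt(ss_d / ss_dhat)
        stress = _stress1(d, dhat)
        if stress > best_stress + 1e-12:
            break  # reject the update; keep the previous configuration
        history.append(stress)
        improvement = best_stress - stress
        best_x, best_stress = x, stress
        if improvement < tol or stress < 1e-12:
            converged = True
            break
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n_pts
    return best_x, best_stress, history, converged


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """NMDS embedding of a distance matrix; best of ``n_starts`` starts."""
    n = len(dist.ids)
    if n < 3:
        raise ValueError("NMDS needs at least 3 points")
    if k >= n:
        raise ValueError("embedding dimension must be below the number of points")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("non-finite distances")
    dvec = squareform(dist.values, checks=False)
    rng = np.random.default_rng(seed)
    scale = dvec.max() if dvec.max() > 0 else 1.0
    starts = [_classical_scaling(dist.values, k)]
    starts += [rng.normal(0.0, scale, size=(n, k)) for _ in range(max(0, n_starts - 1))]
    best = None
    for x0 in starts:
        x, stress, history, converged = _one_start(dvec, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, history, converged)
    x, stress, history, converged = best
    x = x - x.mean(axis=0)
    return OrdinationResult(list(dist.ids), x, stress, n_starts, seed, converged, history)


def group_centroids(ord_result: OrdinationResult, grouping: dict) -> pd.DataFrame:
    """Arithmetic mean of member coordinates per group."""
    coords = ord_result.to_frame()
    missing = [i for i in coords.index if i not in grouping]
    if missing:
        raise ValueError(f"ungrouped ids: {missing}")
    labels = pd.Series({i: grouping[i] for i in coords.index})
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("empty group")
    return coords.groupby(labels).mean()


def ordination_distance(ord_result: OrdinationResult) -> DistanceMatrix:
    """Euclidean distances between embedded points (metric nmds_euclidean)."""
    vals = squareform(pdist(ord_result.coordinates))
    return DistanceMatrix(list(ord_result.ids), vals, "nmds_euclidean")
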