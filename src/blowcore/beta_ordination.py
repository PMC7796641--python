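"""Bray-Curtis dissimilarity on unrarefied counts and non-metric MDS.

NMDS minimizes Kruskal stress-1,

    stress1 = sqrt( sum (dhat_ij - d*_ij)^2 / sum dhat_ij^2 ),

where dhat are configuration distances and d* the monotone (isotonic,
pool-adjacent-violators, ties averaged) transform of the input
dissimilarities. Optimization is SMACOF with disparity updates (via
scikit-learn), best of ``n_restarts`` random starts plus one classical
metric-MDS start so exactly embeddable inputs converge without luck.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .tables_io import CountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DissimilarityMatrix:
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("dissimilarity matrix shape does not match sample_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    sample_ids: tuple
    coordinates: np.ndarray  # n x k, centered at the origin
    stress1: float
    n_restarts: int
    converged: bool


def bray_curtis(table: CountTable) -> DissimilarityMatrix:
    """BC(x, y) = sum |x_j - y_j| / sum (x_j + y_j) on raw counts."""
    depths = table.depths
    if np.any(depths == 0):
        bad = table.sample_ids[int(np.argmax(depths == 0))]
        raise ValueError(f"sample {bad!r} has zero depth; Bray-Curtis undefined")
    d = pdist(table.counts.astype(float), metric="braycurtis")
    return DissimilarityMatrix(table.sample_ids, squareform(d))


def stress1(dm_values: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    d = squareform(np.asarray(dm_values, dtype=float), checks=False)
    dhat = pdist(coords)
    denom = float((dhat**2).sum())
    if denom == 0:
        return np.inf
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    dstar = iso.fit_transform(d, dhat)
    return float(np.sqrt(((dhat - dstar) ** 2).sum() / denom))


def _classical_mds(dm: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric MDS: eigendecomposition of the double-centered matrix."""
    n = dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dm**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    w_pos = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_pos)[None, :]


def nmds(
    dm: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS; returns centered coordinates and the best stress-1."""
    n = len(dm.sample_ids)
    if n < 3:
        raise ValueError("NMDS needs at least 3 samples")
    D = dm.values
    if np.allclose(dm.condensed, dm.condensed[0]):
        logger.warning("all dissimilarities equal; NMDS configuration is degenerate")
    candidates = []
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # metric start
        init = _classical_mds(D, k)
        coords, _, n_it = smacof(
            D, metric=False, n_components=k, init=init, n_init=1,
            max_iter=max_iter, eps=tol, normalized_stress=True,
            random_state=int(rng.integers(2**31)), return_n_iter=True,
        )
        candidates.append((stress1(D, coords), coords, n_it))
        for _ in range(n_restarts):
            coords, _, n_it = smacof(
                D, metric=False, n_components=k, init=None, n_init=1,
                max_iter=max_iter, eps=tol, normalized_stress=True,
                random_state=int(rng.integers(2**31)), return_n_iter=True,
            )
            candidates.append((stress1(D, coords), coords, n_it))
    best_stress, best_coords, best_nit = min(candidates, key=lambda c: c[0])
    best_coords = best_coords - best_coords.mean(axis=0, keepdims=True)
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=best_coords,
        stress1=float(best_stress),
        n_restarts=n_restarts,
        converged=bool(best_nit < max_iter),
    )
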