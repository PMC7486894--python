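"""Fold construction for random and spatially blocked cross-validation.

Random K-fold assigns samples to folds uniformly at random — the standard
practice whose optimism this package audits.  Spatial K-fold instead cuts
a complete-linkage dendrogram of the pairwise coordinate distances at a
height H, producing geographically compact folds whose internal diameter
never exceeds H; with H chosen beyond the autocorrelation range of the
response, held-out folds are approximately independent of the training
folds.  The number of spatial folds emerges from the data rather than
being chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .variogram import pairwise_distances


@dataclass(frozen=True)
class SpatialFolds:
    """Fold assignment with provenance.

    ``fold_id`` maps each sample to one fold, labelled 0..K−1.  For
    clustered folds, ``clustering_height_km`` records H and every
    ``fold_diameters_km`` entry is ≤ H.
    """

    fold_id: np.ndarray
    K: int
    method: str
    clustering_height_km: float | None = None
    fold_diameters_km: np.ndarray | None = None

    def __post_init__(self):
        labels = np.unique(self.fold_id)
        if len(labels) != self.K or labels.min() != 0 or labels.max() != self.K - 1:
            raise ValueError("fold ids must be a relabelled 0..K-1 partition")

    def fold_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == k)

    def split(self):
        """sklearn-style iterator of (train_indices, test_indices) pairs."""
        all_idx = np.arange(len(self.fold_id))
        for k in range(self.K):
            test = self.fold_indices(k)
            yield np.setdiff1d(all_idx, test), test


def random_kfold_split(n: int, K: int = 10, seed: int | None = None) -> SpatialFolds:
    """Uniform random partition into K folds with sizes differing by ≤ 1."""
    if not 2 <= K <= n:
        raise ValueError(f"K must satisfy 2 <= K <= n (got K={K}, n={n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(order, K)):
        fold_id[chunk] = k
    return SpatialFolds(fold_id=fold_id, K=K, method="random")


def fold_diameters(coords, fold_id: np.ndarray) -> np.ndarray:
    """Maximum intra-fold pairwise distance, one value per fold label."""
    xy = np.asarray(coords, dtype=float)
    diameters = []
    for k in np.unique(fold_id):
        members = xy[fold_id == k]
        diameters.append(float(pdist(members).max()) if len(members) > 1 else 0.0)
    return np.asarray(diameters)


def spatial_kfold_split(coords, clustering_height_km: float = 150.0) -> SpatialFolds:
    """Complete-linkage spatial clustering cut at height H.

    Complete linkage merges clusters by their *maximum* inter-point
    distance, so cutting the tree at H guarantees every resulting fold has
    diameter ≤ H.  Scipy's ordering rules make the cut deterministic.  A
    degenerate single-fold outcome (e.g. all-identical coordinates) is
    returned as K = 1 and is unusable for CV; callers must check K ≥ 2.
    """
    d = pairwise_distances(coords)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 samples to build spatial folds")
    if clustering_height_km <= 0:
        raise ValueError("clustering height must be positive")
    condensed = d[np.triu_indices(n, k=1)]
    tree = linkage(condensed, method="complete")
    raw = fcluster(tree, t=clustering_height_km, criterion="distance")
    # relabel 0..K-1 in order of first appearance for determinism
    _, fold_id = np.unique(raw, return_inverse=True)
    K = int(fold_id.max()) + 1
    diams = fold_diameters(coords, fold_id)
    if np.any(diams > clustering_height_km * (1 + 1e-9)):
        raise AssertionError("complete-linkage cut produced a fold wider than H")
    return SpatialFolds(
        fold_id=fold_id,
        K=K,
        method="clustered",
        clustering_height_km=float(clustering_height_km),
        fold_diameters_km=diams,
    )
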