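"""Nonlinear dimensionality reduction on a precomputed distance matrix.

Both algorithms operate directly on the pairwise distance matrix D(l, m)
— images are never re-featurized. IsoMap builds a k-nearest-neighbor
graph on D, computes shortest-path geodesics and applies classical MDS;
t-SNE runs in precomputed-distance mode with a fixed seed so the mapped
coordinates (w, v) are reproducible.

The residual variance 1 - r^2 — where r is the Pearson correlation
between the upper-triangle reference distances (graph geodesics for
IsoMap, D itself for t-SNE) and the embedded Euclidean distances —
diagnoses how much of the distance structure the 2-D map fails to
capture.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.manifold import TSNE, Isomap
from sklearn.neighbors import kneighbors_graph

from .types import DistanceMatrix, Embedding2D


def _as_matrix(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, DistanceMatrix):
        D.validate()
        return D.values, list(D.ids)
    d = np.asarray(D, dtype=float)
    return d, [f"img_{k:04d}" for k in range(d.shape[0])]


def _check_connected(d: np.ndarray, k: int) -> None:
    graph = kneighbors_graph(d, n_neighbors=k, metric="precomputed",
                             mode="distance")
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"k-NN graph (k={k}) is disconnected: {n_comp} components of "
            f"sizes {sizes}; increase k")


class IsomapEmbedding(BaseEstimator):
    """Classical IsoMap on a precomputed distance matrix.

    Parameters
    ----------
    n_neighbors : int, default 12
        Neighborhood size of the geodesic graph.
    n_components : int, default 2

    Attributes
    ----------
    embedding_ : ndarray (n, n_components)
    geodesic_distances_ : ndarray (n, n)
        Graph shortest-path distances actually embedded by the MDS step.
    residual_variance_ : float
    """

    def __init__(self, n_neighbors: int = 12, n_components: int = 2):
        self.n_neighbors = n_neighbors
        self.n_components = n_components

    def fit(self, X, y=None):
        d, ids = _as_matrix(X)
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        _check_connected(d, self.n_neighbors)
        iso = Isomap(n_neighbors=self.n_neighbors,
                     n_components=self.n_components, metric="precomputed")
        self.embedding_ = iso.fit_transform(d)
        self.geodesic_distances_ = iso.dist_matrix_
        self.ids_ = ids
        self.residual_variance_ = residual_variance_from_matrices(
            self.geodesic_distances_, self.embedding_)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


class TSNEEmbedding(BaseEstimator):
    """Seeded t-SNE on a precomputed distance matrix.

    Parameters
    ----------
    perplexity : float, default 30
        Must satisfy 1 < perplexity < (n - 1) / 3.
    random_state : int, default 0
        Fixed seed; identical (D, params, seed) give identical coordinates.

    Attributes
    ----------
    embedding_ : ndarray (n, 2), centered at the origin
    residual_variance_ : float (computed against D itself)
    """

    def __init__(self, perplexity: float = 30.0, random_state: int = 0,
                 n_components: int = 2):
        self.perplexity = perplexity
        self.random_state = random_state
        self.n_components = n_components

    def fit(self, X, y=None):
        d, ids = _as_matrix(X)
        n = d.shape[0]
        if not 1.0 < self.perplexity < (n - 1) / 3.0:
            raise ValueError(
                f"perplexity must lie in (1, (n-1)/3) = (1, {(n - 1) / 3:.2f}) "
                f"for n={n}; got {self.perplexity}")
        tsne = TSNE(n_components=self.n_components, perplexity=self.perplexity,
                    metric="precomputed", init="random",
                    random_state=self.random_state)
        coords = tsne.fit_transform(d).astype(float)
        coords = coords - coords.mean(axis=0)
        self.embedding_ = coords
        self.ids_ = ids
        self.residual_variance_ = residual_variance_from_matrices(d, coords)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def isomap_embed(D, k: int = 12, dims: int = 2) -> Embedding2D:
    """IsoMap the distance matrix; returns mapped coordinates (w, v)."""
    est = IsomapEmbedding(n_neighbors=k, n_components=dims).fit(D)
    return Embedding2D(coords=est.embedding_, method="isomap",
                       params={"k": k, "dims": dims}, ids=est.ids_,
                       geodesic_distances=est.geodesic_distances_)


def tsne_embed(D, perplexity: float = 30.0, seed: int = 0) -> Embedding2D:
    """t-SNE the distance matrix with a fixed seed; coordinates centered."""
    est = TSNEEmbedding(perplexity=perplexity, random_state=seed).fit(D)
    return Embedding2D(coords=est.embedding_, method="tsne",
                       params={"perplexity": perplexity, "seed": seed},
                       ids=est.ids_)


def residual_variance_from_matrices(ref: np.ndarray,
                                    coords: np.ndarray) -> float:
    """1 - r^2 between upper-triangle reference and embedded distances."""
    n = ref.shape[0]
    if n < 3:
        raise ValueError("residual variance needs at least 3 points")
    iu = np.triu_indices(n, k=1)
    emb = pdist(coords)
    if np.ptp(ref[iu]) == 0 or np.ptp(emb) == 0:
        return float("nan")   # correlation undefined on constant distances
    r = np.corrcoef(ref[iu], emb)[0, 1]
    return float(1.0 - r * r)


def residual_variance(D, emb: Embedding2D) -> float:
    """Residual variance of an embedding against its reference distances.

    For IsoMap embeddings the stored graph geodesic distances are the
    reference; otherwise D itself.
    """
    d, _ = _as_matrix(D)
    if emb.n != d.shape[0]:
        raise ValueError("embedding and distance matrix sizes differ")
    ref = emb.geodesic_distances if emb.geodesic_distances is not None else d
    return residual_variance_from_matrices(ref, emb.coords)
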