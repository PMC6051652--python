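"""Density clustering and 2-D embedding of the SPOTDis matrix.

Clustering is hierarchical density-based (HDBSCAN) run in precomputed-distance
mode with a single hyperparameter ``n_pts`` that serves both as the minimum
cluster size and the core-distance neighbour count; visualization is t-SNE
computed directly on the pairwise dissimilarity matrix.  Both are delegated to
scikit-learn; this module owns only parameter plumbing and validation (the
dissimilarity may be mildly non-metric — silent neuron pairs can break the
triangle inequality — which the density clustering tolerates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN
from sklearn.manifold import TSNE

from .spike_data import EpochSet
from .spotdis import DissimilarityMatrix, spotdis_matrix

__all__ = ["ClusterConfig", "cluster_hdbscan", "embed_tsne", "SPOTDisClust"]

NOISE = -1  # noise label in cluster outputs

_SELECTION = {"excess_of_mass": "eom", "leaf": "leaf"}


@dataclass(frozen=True)
class ClusterConfig:
    """Clustering/embedding parameters.

    ``n_pts`` (default 10) is the single density hyperparameter: minimum
    cluster size and min-samples at once.  ``selection`` picks the cluster
    extraction rule from the condensed tree.  ``perplexity`` (default 30) and
    ``embed_seed`` control the t-SNE embedding only.
    """

    n_pts: int = 10
    selection: str = "excess_of_mass"
    perplexity: float = 30.0
    embed_seed: int = 0

    def __post_init__(self):
        if self.n_pts < 2:
            raise ValueError("n_pts must be >= 2")
        if self.selection not in _SELECTION:
            raise ValueError(
                f"selection must be one of {sorted(_SELECTION)}, got {self.selection!r}")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be > 0")


def _matrix_values(D) -> np.ndarray:
    vals = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(vals, vals.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    return vals


def cluster_hdbscan(D, cfg: ClusterConfig = ClusterConfig()) -> np.ndarray:
    """HDBSCAN labels (noise = -1) for a precomputed dissimilarity matrix."""
    vals = _matrix_values(D)
    if cfg.n_pts >= vals.shape[0]:
        raise ValueError("n_pts must be smaller than the number of epochs")
    model = HDBSCAN(
        min_cluster_size=cfg.n_pts,
        min_samples=cfg.n_pts,
        metric="precomputed",
        cluster_selection_method=_SELECTION[cfg.selection],
        copy=True,  # keep the caller's matrix intact
    )
    return model.fit_predict(vals).astype(int)


def embed_tsne(D, cfg: ClusterConfig = ClusterConfig()) -> np.ndarray:
    """Deterministic (seeded) M x 2 t-SNE embedding of the dissimilarity matrix."""
    vals = _matrix_values(D)
    if cfg.perplexity >= vals.shape[0]:
        raise ValueError("perplexity must be smaller than the number of epochs")
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=cfg.perplexity,
        random_state=cfg.embed_seed,
    )
    return tsne.fit_transform(vals)


class SPOTDisClust(ClusterMixin, BaseEstimator):
    """End-to-end spike-pattern clustering: SPOTDis + HDBSCAN (+ t-SNE).

    ``fit(X)`` with ``X`` an :class:`~spotdisclust.spike_data.EpochSet` (or a
    precomputed square dissimilarity matrix) computes the pairwise SPOTDis,
    clusters it density-wise and optionally embeds it in 2-D.

    Parameters
    ----------
    n_pts : int, default 10
        Minimum cluster size = core neighbour count (the single density
        hyperparameter).
    selection : {"excess_of_mass", "leaf"}, default "excess_of_mass"
    perplexity : float, default 30
        t-SNE perplexity (used only when ``compute_embedding``).
    embed_seed : int, default 0
    compute_embedding : bool, default False
    exclude_same_electrode : bool, default False
        Drop neuron pairs recorded on the same electrode from the SPOTDis sum.
    n_workers : int, default 1

    Attributes
    ----------
    dissimilarity_ : DissimilarityMatrix or ndarray
    labels_ : ndarray of int, noise encoded as -1
    embedding_ : ndarray (M, 2), present when ``compute_embedding``
    """

    def __init__(self, n_pts: int = 10, selection: str = "excess_of_mass",
                 perplexity: float = 30.0, embed_seed: int = 0,
                 compute_embedding: bool = False,
                 exclude_same_electrode: bool = False, n_workers: int = 1):
        self.n_pts = n_pts
        self.selection = selection
        self.perplexity = perplexity
        self.embed_seed = embed_seed
        self.compute_embedding = compute_embedding
        self.exclude_same_electrode = exclude_same_electrode
        self.n_workers = n_workers

    def _cluster_config(self) -> ClusterConfig:
        return ClusterConfig(n_pts=self.n_pts, selection=self.selection,
                             perplexity=self.perplexity,
                             embed_seed=self.embed_seed)

    def fit(self, X, y=None):
        if isinstance(X, EpochSet):
            self.dissimilarity_ = spotdis_matrix(
                X, exclude_same_electrode=self.exclude_same_electrode,
                n_workers=self.n_workers)
            values = self.dissimilarity_.values
        else:
            values = _matrix_values(X)
            self.dissimilarity_ = values
        cfg = self._cluster_config()
        self.labels_ = cluster_hdbscan(values, cfg)
        if self.compute_embedding:
            self.embedding_ = embed_tsne(values, cfg)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
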