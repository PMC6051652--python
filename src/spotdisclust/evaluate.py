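"""Cluster-quality evaluation: noise-aware ARI, Silhouette on dissimilarities,
the unsupervised window-length sweep, and the population rate-vector baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from .cluster_embed import NOISE, ClusterConfig, cluster_hdbscan
from .spike_data import EpochSet, extract_windows
from .spotdis import DissimilarityMatrix, spotdis_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "ari_noise_rule",
    "silhouette_from_dissimilarity",
    "window_sweep",
    "sweep_rank_correlation",
    "rate_vector_baseline",
]


@dataclass
class EvaluationReport:
    """Scores of one clustering run (and, when sweeping, per-window curves)."""

    ari: float | None = None
    silhouette: float | None = None
    per_window: dict = field(default_factory=dict)
    selected_t_w: int | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            if self.ari is not None:
                fh.write(f"ari\t{self.ari:.6f}\n")
            if self.silhouette is not None:
                fh.write(f"silhouette\t{self.silhouette:.6f}\n")
            if self.selected_t_w is not None:
                fh.write(f"selected_t_w\t{self.selected_t_w}\n")
            for t_w, scores in sorted(self.per_window.items()):
                fh.write(f"window\t{t_w}\t" + "\t".join(
                    f"{k}={v}" for k, v in scores.items()) + "\n")


def _as_int_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    # map arbitrary (e.g. string) labels to dense integers
    _, inv = np.unique(arr, return_inverse=True)
    return inv.astype(int)


def ari_noise_rule(true_labels, pred_labels) -> float:
    """Adjusted Rand Index after assigning predicted noise to its own cluster.

    Points labeled noise (-1) by the density clustering are remapped to one
    fresh cluster id before the standard chance-corrected ARI is computed, so
    a correctly isolated noise population counts as agreement.
    """
    t = _as_int_labels(true_labels)
    p = np.asarray(pred_labels, dtype=int).copy()
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    p[p == NOISE] = (p.max() + 1) if p.size else 0
    return float(adjusted_rand_score(t, p))


def silhouette_from_dissimilarity(D, labels) -> float:
    """Silhouette score computed directly on a dissimilarity matrix.

    Per epoch k: ``d_same`` is the mean dissimilarity to the other members of
    its cluster and ``d_nearest`` the smallest mean dissimilarity to any other
    cluster; the epoch contributes ``(d_nearest - d_same)/max(d_nearest,
    d_same)``.  Noise epochs form one ordinary cluster, both as a home and as
    a candidate nearest cluster.  Singleton members (and degenerate terms with
    ``d_nearest = d_same = 0``) contribute 0 and are counted.
    """
    vals = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    lab = _as_int_labels(labels)
    if lab.shape[0] != vals.shape[0]:
        raise ValueError("labels must match the matrix size")
    clusters = np.unique(lab)
    if clusters.size < 2:
        raise ValueError("silhouette requires at least two clusters "
                         "(counting the noise cluster)")
    m = vals.shape[0]
    s = np.zeros(m)
    members = {c: np.flatnonzero(lab == c) for c in clusters}
    for k in range(m):
        own = members[lab[k]]
        if own.size == 1:
            continue  # singleton: contributes 0
        d_same = vals[k, own[own != k]].mean()
        d_nearest = min(vals[k, members[c]].mean()
                        for c in clusters if c != lab[k])
        denom = max(d_nearest, d_same)
        if denom == 0:
            logger.warning("silhouette: degenerate term at epoch %d "
                           "(d_nearest = d_same = 0); contributes 0", k)
            continue
        s[k] = (d_nearest - d_same) / denom
    return float(s.mean())


def window_sweep(
    spikes,
    events,
    lengths,
    cfg: ClusterConfig = ClusterConfig(),
    true_labels=None,
    exclude_same_electrode: bool = False,
    n_workers: int = 1,
) -> EvaluationReport:
    """Select the epoch window length unsupervised via the Silhouette score.

    For each candidate length: window the continuous data around the events,
    compute the SPOTDis matrix, cluster it and score the partition.  The
    returned report carries per-length Silhouette (and ARI when ground truth
    is given) and the Silhouette-argmax length.
    """
    lengths = list(lengths)
    report = EvaluationReport()
    best = (-np.inf, None)
    for t_w in lengths:
        try:
            es = extract_windows(spikes, events, t_w)
            D = spotdis_matrix(es, exclude_same_electrode=exclude_same_electrode,
                               n_workers=n_workers)
            labels = cluster_hdbscan(D, cfg)
            if np.unique(labels).size < 2:
                # clustering found no structure at this length: minimal quality
                logger.warning("window_sweep: length %d yields a single "
                               "(noise) cluster; silhouette set to -1", t_w)
                sil = -1.0
            else:
                sil = silhouette_from_dissimilarity(D, labels)
        except Exception as exc:  # record and move on, per-length
            logger.warning("window_sweep: length %d failed: %s", t_w, exc)
            report.per_window[t_w] = {"error": str(exc)}
            continue
        scores = {"silhouette": sil}
        if true_labels is not None:
            scores["ari"] = ari_noise_rule(true_labels, labels)
        report.per_window[t_w] = scores
        if sil > best[0]:
            best = (sil, t_w)
    report.selected_t_w = best[1]
    if best[1] is not None:
        report.silhouette = best[0]
        report.ari = report.per_window[best[1]].get("ari")
    return report


def sweep_rank_correlation(report: EvaluationReport) -> float:
    """Spearman rank correlation between Silhouette and ARI over a sweep."""
    pairs = [(v["silhouette"], v["ari"]) for v in report.per_window.values()
             if "silhouette" in v and "ari" in v]
    sil, ari = zip(*pairs)
    rho = spearmanr(sil, ari).statistic
    return float(rho)


def rate_vector_baseline(es: EpochSet, normalized: bool = True) -> DissimilarityMatrix:
    """L1 distances between per-epoch population rate vectors (baseline).

    Per epoch the spike count of each neuron is taken; in normalized mode each
    count vector is divided by its epoch total (all-silent epochs stay at the
    zero vector and are flagged in the mask), and the distance between two
    epochs is the mean absolute difference over neurons.
    """
    if es.n_epochs < 2:
        raise ValueError("at least two epochs are required")
    counts = np.array([[tr.n_spikes for tr in ep.trains] for ep in es.epochs],
                      dtype=float)
    defined = np.ones((es.n_epochs, es.n_epochs), dtype=bool)
    if normalized:
        totals = counts.sum(axis=1)
        zero = totals == 0
        if zero.any():
            logger.warning("rate_vector_baseline: %d all-silent epochs "
                           "use the zero vector", int(zero.sum()))
            defined[zero, :] = False
            defined[:, zero] = False
            np.fill_diagonal(defined, True)
        totals[zero] = 1.0
        counts = counts / totals[:, None]
    diff = np.abs(counts[:, None, :] - counts[None, :, :]).mean(axis=2)
    return DissimilarityMatrix(diff, defined, es.epoch_ids, es.labels)
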