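"""Assembly of the M x M SPOTDis dissimilarity matrix.

SPOTDis between two epochs is the average, over neuron pairs, of the EMD
between the pairs' normalized cross-correlograms, where a pair contributes
only if both neurons fired in both epochs (weight 1, else 0).  Per-pair EMDs
are reduced on the fly into the running mean; the full (neuron-pair x
epoch-pair) EMD tensor is never materialized.  Computational cost is
O(N^2 M^2 n^2) for n spikes per train.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .spike_data import Epoch, EpochSet
from .transport import _emd_cost_int

logger = logging.getLogger(__name__)

__all__ = ["DissimilarityMatrix", "spotdis_pair", "spotdis_matrix", "SPOTDis"]

#: value given to epoch pairs with no co-active neuron pair (then masked):
#: maximal dissimilarity keeps such epochs isolated rather than spuriously close.
SENTINEL = 1.0


@njit(cache=True, nogil=True)
def _build_delays(times, t_off, pair_i, pair_j):  # pragma: no cover
    """Concatenated sorted delay multisets for all neuron pairs of one epoch."""
    npairs = pair_i.shape[0]
    offsets = np.zeros(npairs + 1, np.int64)
    for p in range(npairs):
        ni = t_off[pair_i[p] + 1] - t_off[pair_i[p]]
        nj = t_off[pair_j[p] + 1] - t_off[pair_j[p]]
        offsets[p + 1] = offsets[p] + ni * nj
    out = np.empty(offsets[npairs], np.int64)
    for p in range(npairs):
        i0, i1 = t_off[pair_i[p]], t_off[pair_i[p] + 1]
        j0, j1 = t_off[pair_j[p]], t_off[pair_j[p] + 1]
        k = offsets[p]
        for a in range(i0, i1):
            for b in range(j0, j1):
                out[k] = times[b] - times[a]
                k += 1
        out[offsets[p]:offsets[p + 1]].sort()
    return out, offsets


@njit(cache=True, nogil=True)
def _pair_dissim(dk, offk, dm, offm, keep, inv_denom):  # pragma: no cover
    """Weighted-average EMD between two epochs' delay structures."""
    npairs = offk.shape[0] - 1
    total = 0.0
    w = 0
    for p in range(npairs):
        if not keep[p]:
            continue
        qa = offk[p + 1] - offk[p]
        qb = offm[p + 1] - offm[p]
        if qa == 0 or qb == 0:
            continue
        cost = _emd_cost_int(dk[offk[p]:offk[p + 1]], dm[offm[p]:offm[p + 1]])
        total += cost / (qa * qb)
        w += 1
    if w == 0:
        return 0.0, 0
    return total * inv_denom / w, w


def _pair_index(n_neurons: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n_neurons, k=1)
    return i.astype(np.int64), j.astype(np.int64)


def _epoch_structure(epoch: Epoch, pair_i, pair_j):
    counts = np.array([tr.n_spikes for tr in epoch.trains], dtype=np.int64)
    t_off = np.concatenate(([0], np.cumsum(counts)))
    if t_off[-1]:
        times = np.concatenate([tr.times for tr in epoch.trains]).astype(np.int64)
    else:
        times = np.empty(0, dtype=np.int64)
    return _build_delays(times, t_off, pair_i, pair_j)


def _keep_mask(es: EpochSet, pair_i, pair_j, exclude_same_electrode: bool) -> np.ndarray:
    keep = np.ones(pair_i.shape[0], dtype=np.bool_)
    if exclude_same_electrode:
        if es.electrode_of is None:
            raise ValueError(
                "exclude_same_electrode requires EpochSet.electrode_of")
        nid = es.neuron_ids
        elec = np.array([es.electrode_of[n] for n in nid], dtype=np.int64)
        keep = elec[pair_i] != elec[pair_j]
    return keep


def spotdis_pair(
    epoch_k: Epoch,
    epoch_m: Epoch,
    t_epoch: int,
    exclude_same_electrode: bool = False,
    electrode_of=None,
) -> tuple[float, int]:
    """SPOTDis between two epochs plus the count of contributing neuron pairs.

    Returns ``(value, weight_sum)``; when no neuron pair is co-active in both
    epochs the value is the sentinel (1.0) and the weight sum 0.
    """
    if epoch_k.neuron_ids != epoch_m.neuron_ids:
        raise ValueError("epochs must share an identical neuron set")
    es = EpochSet((epoch_k, epoch_m), t_epoch=t_epoch, electrode_of=electrode_of)
    n = len(epoch_k.trains)
    pair_i, pair_j = _pair_index(n)
    keep = _keep_mask(es, pair_i, pair_j, exclude_same_electrode)
    dk, offk = _epoch_structure(epoch_k, pair_i, pair_j)
    dm, offm = _epoch_structure(epoch_m, pair_i, pair_j)
    value, w = _pair_dissim(dk, offk, dm, offm, keep, 1.0 / (2 * t_epoch + 1))
    if w == 0:
        return SENTINEL, 0
    return float(value), int(w)


@dataclass
class DissimilarityMatrix:
    """Symmetric M x M SPOTDis matrix with a per-entry defined mask.

    ``defined_mask[k, m]`` is False where no neuron pair was co-active in
    epochs k and m; such entries hold the sentinel value 1.0.
    """

    values: np.ndarray
    defined_mask: np.ndarray
    epoch_ids: tuple[int, ...]
    labels: tuple[str | None, ...] | None = None

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def save(self, path) -> None:
        """Plain CSV with an epoch-id header row; mask in a `.mask.csv` sidecar."""
        header = ",".join(str(e) for e in self.epoch_ids)
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")
        np.savetxt(self._mask_path(path), self.defined_mask.astype(int),
                   delimiter=",", header=header, comments="", fmt="%d")

    @classmethod
    def load(cls, path) -> "DissimilarityMatrix":
        with open(path) as fh:
            epoch_ids = tuple(int(x) for x in fh.readline().strip().split(","))
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        try:
            mask = np.loadtxt(cls._mask_path(path), delimiter=",",
                              skiprows=1, ndmin=2).astype(bool)
        except OSError:
            mask = np.ones_like(values, dtype=bool)
        return cls(values, mask, epoch_ids)

    @staticmethod
    def _mask_path(path):
        return f"{path}.mask.csv"


def spotdis_matrix(
    es: EpochSet,
    exclude_same_electrode: bool = False,
    n_workers: int = 1,
) -> DissimilarityMatrix:
    """All-pairs SPOTDis over an EpochSet (symmetric, zero diagonal).

    Epoch pairs are partitioned into row chunks whose results land in disjoint
    entries, so the values are identical for any ``n_workers``.
    """
    m = es.n_epochs
    if m < 2:
        raise ValueError("at least two epochs are required")
    pair_i, pair_j = _pair_index(es.n_neurons)
    keep = _keep_mask(es, pair_i, pair_j, exclude_same_electrode)
    structures = [_epoch_structure(ep, pair_i, pair_j) for ep in es.epochs]
    inv_denom = 1.0 / (2 * es.t_epoch + 1)

    values = np.zeros((m, m), dtype=np.float64)
    weights = np.zeros((m, m), dtype=np.int64)

    def _row(k: int):
        dk, offk = structures[k]
        out = np.empty(m - k - 1, dtype=np.float64)
        wout = np.empty(m - k - 1, dtype=np.int64)
        for idx, mm in enumerate(range(k + 1, m)):
            dm, offm = structures[mm]
            out[idx], wout[idx] = _pair_dissim(dk, offk, dm, offm, keep, inv_denom)
        return k, out, wout

    if n_workers > 1:
        rows = Parallel(n_jobs=n_workers, backend="threading")(
            delayed(_row)(k) for k in range(m - 1))
    else:
        rows = [_row(k) for k in range(m - 1)]
    for k, out, wout in rows:
        values[k, k + 1:] = out
        weights[k, k + 1:] = wout

    defined = weights > 0
    values[~defined] = SENTINEL
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(defined, True)
    values = np.triu(values, 1)
    values = values + values.T
    defined = np.triu(defined) | np.triu(defined).T
    undef = np.argwhere(np.triu(~defined, 1))
    for k, mm in undef:
        logger.warning("SPOTDis undefined for epoch pair (%d, %d): no co-active "
                       "neuron pair; sentinel %.1f used", k, mm, SENTINEL)
    return DissimilarityMatrix(values, defined, es.epoch_ids, es.labels)


class SPOTDis(TransformerMixin, BaseEstimator):
    """Pairwise spike-pattern optimal-transport dissimilarity transformer.

    ``fit_transform(X)`` with ``X`` an :class:`EpochSet` returns the M x M
    SPOTDis matrix (suitable for precomputed-metric clustering/embedding).

    Parameters
    ----------
    exclude_same_electrode : bool, default False
        Skip neuron pairs recorded on the same electrode (requires
        ``EpochSet.electrode_of``).
    n_workers : int, default 1
        Thread count for epoch-pair chunks; values are worker-count invariant.

    Attributes
    ----------
    dissimilarity_ : DissimilarityMatrix
    """

    def __init__(self, exclude_same_electrode: bool = False, n_workers: int = 1):
        self.exclude_same_electrode = exclude_same_electrode
        self.n_workers = n_workers

    def fit(self, X: EpochSet, y=None):
        self.dissimilarity_ = spotdis_matrix(
            X, exclude_same_electrode=self.exclude_same_electrode,
            n_workers=self.n_workers)
        self.n_epochs_ = self.dissimilarity_.n_epochs
        return self

    def transform(self, X: EpochSet) -> np.ndarray:
        # pairwise transformer: transform is defined on the fitted set only
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "dissimilarity_")
        return self.dissimilarity_.values

    def fit_transform(self, X: EpochSet, y=None) -> np.ndarray:
        return self.fit(X).dissimilarity_.values
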