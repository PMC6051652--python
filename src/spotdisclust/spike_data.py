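"""Domain types for epoched multi-neuron spike data, CSV I/O and windowing.

Spike times are integer sample indices, 0-based; an epoch is the half-open
interval ``[0, T_epoch)``.  A caller holding continuous-time data converts to
samples with its own sampling rate before constructing these types.  Times
outside the epoch are tolerated (jitter-perturbed simulations deliberately
produce them) but simulators emit in-epoch times only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "Epoch",
    "EpochSet",
    "read_epochs_csv",
    "write_epochs_csv",
    "extract_windows",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one neuron within one epoch.

    Parameters
    ----------
    neuron_id : int
        Non-negative unit/channel identifier.
    times : ndarray of int
        Sample indices, sorted non-decreasing; duplicates allowed (more than
        one spike can land in the same sample).
    """

    neuron_id: int
    times: np.ndarray

    def __post_init__(self):
        if self.neuron_id < 0:
            raise ValueError(f"neuron_id must be >= 0, got {self.neuron_id}")
        t = np.asarray(self.times, dtype=np.int64)
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size and np.any(np.diff(t) < 0):
            t = np.sort(t)
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Epoch:
    """One fixed-length observation window across all neurons."""

    epoch_id: int
    trains: tuple[SpikeTrain, ...]
    label: str | None = None

    def __post_init__(self):
        trains = tuple(self.trains)
        ids = [tr.neuron_id for tr in trains]
        if len(set(ids)) != len(ids):
            raise ValueError("exactly one SpikeTrain per neuron_id required")
        object.__setattr__(self, "trains", trains)

    @property
    def neuron_ids(self) -> tuple[int, ...]:
        return tuple(tr.neuron_id for tr in self.trains)

    def train(self, neuron_id: int) -> SpikeTrain:
        for tr in self.trains:
            if tr.neuron_id == neuron_id:
                return tr
        raise KeyError(neuron_id)

    @property
    def n_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains)


@dataclass(frozen=True)
class EpochSet:
    """M epochs of length ``t_epoch`` samples over a common neuron set."""

    epochs: tuple[Epoch, ...]
    t_epoch: int
    electrode_of: Mapping[int, int] | None = None

    def __post_init__(self):
        if self.t_epoch <= 0:
            raise ValueError("t_epoch must be a positive number of samples")
        epochs = tuple(self.epochs)
        if epochs:
            ref = epochs[0].neuron_ids
            for ep in epochs[1:]:
                if ep.neuron_ids != ref:
                    raise ValueError(
                        "all epochs must share an identical, ordered neuron set"
                    )
        object.__setattr__(self, "epochs", epochs)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_neurons(self) -> int:
        return len(self.epochs[0].trains) if self.epochs else 0

    @property
    def neuron_ids(self) -> tuple[int, ...]:
        return self.epochs[0].neuron_ids if self.epochs else ()

    @property
    def labels(self) -> tuple[str | None, ...]:
        return tuple(ep.label for ep in self.epochs)

    @property
    def epoch_ids(self) -> tuple[int, ...]:
        return tuple(ep.epoch_id for ep in self.epochs)


def _sniff_header(path) -> bool:
    """True when the first CSV row is a header (non-numeric leading fields)."""
    with open(path, newline="") as fh:
        row = next(csv.reader(fh), None)
    if row is None:
        raise ValueError(f"{path}: empty file")
    try:
        float(row[0]), float(row[1]), float(row[2])
        return False
    except (ValueError, IndexError):
        return True


def read_epochs_csv(path, t_epoch: int) -> EpochSet:
    """Load an EpochSet from a 4-column CSV (time, channel, epoch, condition).

    The dialect is the one used for epoched multi-unit exports: spike times in
    column 1, unit/channel ids in column 2, epoch ids in column 3 and a free-form
    condition label in column 4.  A header row is optional and auto-detected.
    Neurons silent in some epoch are filled in with empty trains; duplicate rows
    are kept (spike multisets).  Time units are whatever the caller recorded;
    ``t_epoch`` must be supplied in the same units.
    """
    has_header = _sniff_header(path)
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=["time", "channel", "epoch", "condition"],
        dtype={"condition": str},
    )
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    for col in ("time", "channel", "epoch"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value in column '{col}' at data row {bad}"
            )
        df[col] = coerced
    df["time"] = df["time"].round().astype(np.int64)
    df["channel"] = df["channel"].astype(np.int64)
    df["epoch"] = df["epoch"].astype(np.int64)

    neuron_ids = sorted(df["channel"].unique().tolist())
    epochs = []
    for eid, grp in df.groupby("epoch", sort=True):
        label_vals = grp["condition"].dropna().unique()
        label = str(label_vals[0]) if len(label_vals) else None
        by_chan = {c: g["time"].to_numpy() for c, g in grp.groupby("channel")}
        trains = tuple(
            SpikeTrain(nid, by_chan.get(nid, np.empty(0, dtype=np.int64)))
            for nid in neuron_ids
        )
        epochs.append(Epoch(int(eid), trains, label))
    return EpochSet(tuple(epochs), t_epoch=int(t_epoch))


def write_epochs_csv(es: EpochSet, path) -> None:
    """Write an EpochSet in the same 4-column dialect (with header row).

    Round-trips exactly through :func:`read_epochs_csv` for in-range labels;
    an empty EpochSet yields a header-only file.
    """
    rows = []
    for ep in es.epochs:
        for tr in ep.trains:
            for t in tr.times:
                rows.append((int(t), tr.neuron_id, ep.epoch_id, ep.label or ""))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "channel", "epoch", "condition"])
        writer.writerows(rows)


def extract_windows(
    spikes: Mapping[int, Sequence[int]],
    events: Iterable[int],
    t_w: int,
    labels: Sequence[str | None] | None = None,
) -> EpochSet:
    """Cut event-centered windows out of continuous per-neuron spike streams.

    Each event defines one epoch covering ``[event - t_w//2, event + t_w//2)``
    (half-open); retained spikes are re-referenced to the window start, so the
    resulting EpochSet has ``t_epoch == t_w``.  Overlapping windows are allowed
    and merely logged.
    """
    if t_w < 2:
        raise ValueError(f"t_w must be >= 2 samples, got {t_w}")
    events = np.asarray(list(events), dtype=np.int64)
    if events.size > 1 and np.any(np.diff(events) < t_w):
        logger.info("extract_windows: some windows of length %d overlap", t_w)
    neuron_ids = sorted(spikes)
    arrays = {nid: np.sort(np.asarray(spikes[nid], dtype=np.int64)) for nid in neuron_ids}
    half = t_w // 2
    epochs = []
    for e_idx, ev in enumerate(events):
        start = ev - half
        stop = start + t_w
        trains = []
        for nid in neuron_ids:
            t = arrays[nid]
            sel = t[(t >= start) & (t < stop)] - start
            trains.append(SpikeTrain(nid, sel))
        label = labels[e_idx] if labels is not None else None
        epochs.append(Epoch(e_idx, tuple(trains), label))
    return EpochSet(tuple(epochs), t_epoch=int(t_w))
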