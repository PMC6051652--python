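"""Ground-truth spike-pattern simulators.

Patterns are per-neuron piecewise-constant rate profiles (spikes/sample) over
an epoch of ``t_epoch`` samples: a baseline rate ``lam_out`` with an elevated
activation pulse of ``lam_in`` over ``t_pulse`` samples whose position, drawn
per neuron, defines the pattern.  Spiking output is an inhomogeneous Poisson
process discretized as independent per-sample Poisson counts (so more than one
spike can land in the same sample, matching the multiset semantics of the
delay representation downstream).

Noise epochs come in two flavours: "homogeneous" (constant rate matched to
the expected spike count of a pattern epoch) and "patterned" (each noise epoch
is a single realization of a unique, never-repeated random pattern with the
same pulse statistics).

All generators are exactly reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .spike_data import Epoch, EpochSet, SpikeTrain

__all__ = [
    "RateProfile",
    "PatternSpec",
    "SimulationConfig",
    "build_patterns",
    "expected_spike_count",
    "realize_epochs",
    "make_noise_epochs",
    "constant_pattern",
    "concat_epoch_sets",
    "simulate",
    "apply_rate_scaling",
    "inject_sorting_errors",
    "make_precise_sequences",
    "embed_with_onset_jitter",
]

NOISE_LABEL = "noise"

PATTERN_KINDS = (
    "pulse",
    "bimodal",
    "deactivation",
    "coarse_fine",
    "synchronous",
    "precise_sequence",
)


@dataclass(frozen=True)
class RateProfile:
    """One neuron's piecewise-constant rate function over [0, t_epoch)."""

    rates: np.ndarray  # (t_epoch,) spikes/sample

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=np.float64)
        if r.ndim != 1 or np.any(r < 0):
            raise ValueError("rates must be a 1-D non-negative array")
        object.__setattr__(self, "rates", r)

    @property
    def t_epoch(self) -> int:
        return self.rates.size


@dataclass(frozen=True)
class PatternSpec:
    """A pattern: one rate profile per neuron plus bookkeeping."""

    pattern_id: int
    kind: str
    profiles: np.ndarray  # (n_neurons, t_epoch) spikes/sample
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in PATTERN_KINDS and self.kind != "constant":
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        p = np.asarray(self.profiles, dtype=np.float64)
        if p.ndim != 2 or np.any(p < 0):
            raise ValueError("profiles must be (n_neurons, t_epoch) and >= 0")
        object.__setattr__(self, "profiles", p)

    @property
    def n_neurons(self) -> int:
        return self.profiles.shape[0]

    @property
    def t_epoch(self) -> int:
        return self.profiles.shape[1]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation scenario.

    Rates are in spikes/sample, durations in samples.  ``noise_kind`` selects
    between count-matched homogeneous Poisson noise epochs and "patterned"
    noise epochs (unique single-shot patterns).
    """

    p: int = 5                      # number of recurring patterns
    n_neurons: int = 50
    t_epoch: int = 300
    t_pulse: int = 30
    lam_in: float = 0.2
    lam_out: float = 0.02
    reps: int = 30                  # realizations per pattern
    n_noise: int = 150
    noise_kind: str = "homogeneous"
    kind: str = "pulse"
    seed: int = 0
    # kind-specific extras
    t_deactivation: int | None = None      # deactivation
    lam_in_fine: float | None = None       # coarse_fine
    t_pulse_fine: int | None = None        # coarse_fine
    sync_frac: float = 0.5                 # synchronous: active subset fraction

    def __post_init__(self):
        if min(self.p, self.n_neurons, self.reps, self.n_noise) < 0:
            raise ValueError("counts must be >= 0")
        if self.lam_in < 0 or self.lam_out < 0:
            raise ValueError("rates must be >= 0")
        if self.noise_kind not in ("homogeneous", "patterned"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")


def expected_spike_count(profile) -> float:
    """Integral of the rate function over the epoch (expected spikes/epoch)."""
    if isinstance(profile, RateProfile):
        return float(profile.rates.sum())
    if isinstance(profile, PatternSpec):
        return float(profile.profiles.sum(axis=1).mean())
    return float(np.asarray(profile, dtype=float).sum())


def _place_pulse(rng, t_epoch: int, t_pulse: int) -> int:
    return int(rng.integers(0, t_epoch - t_pulse + 1))


def _pattern_profiles(cfg: SimulationConfig, rng, coarse_starts=None) -> np.ndarray:
    n, t = cfg.n_neurons, cfg.t_epoch
    prof = np.full((n, t), cfg.lam_out)
    if cfg.kind == "pulse":
        for i in range(n):
            s = _place_pulse(rng, t, cfg.t_pulse)
            prof[i, s:s + cfg.t_pulse] = cfg.lam_in
    elif cfg.kind == "bimodal":
        for i in range(n):
            s1 = _place_pulse(rng, t, cfg.t_pulse)
            while True:  # second pulse disjoint from the first
                s2 = _place_pulse(rng, t, cfg.t_pulse)
                if s2 + cfg.t_pulse <= s1 or s2 >= s1 + cfg.t_pulse:
                    break
            prof[i, s1:s1 + cfg.t_pulse] = cfg.lam_in
            prof[i, s2:s2 + cfg.t_pulse] = cfg.lam_in
    elif cfg.kind == "deactivation":
        t_deact = cfg.t_deactivation if cfg.t_deactivation is not None else cfg.t_pulse
        prof[:] = cfg.lam_in
        for i in range(n):
            s = _place_pulse(rng, t, t_deact)
            prof[i, s:s + t_deact] = cfg.lam_out
    elif cfg.kind == "coarse_fine":
        if cfg.lam_in_fine is None or cfg.t_pulse_fine is None:
            raise ValueError("coarse_fine requires lam_in_fine and t_pulse_fine")
        for i in range(n):
            s = coarse_starts[i] if coarse_starts is not None else _place_pulse(
                rng, t, cfg.t_pulse)
            prof[i, s:s + cfg.t_pulse] = cfg.lam_in
            f = s + int(rng.integers(0, cfg.t_pulse - cfg.t_pulse_fine + 1))
            prof[i, f:f + cfg.t_pulse_fine] = cfg.lam_in_fine
    elif cfg.kind == "synchronous":
        k = max(1, int(round(cfg.sync_frac * n)))
        subset = rng.choice(n, size=k, replace=False)
        s = _place_pulse(rng, t, cfg.t_pulse)
        for i in subset:
            prof[i, s:s + cfg.t_pulse] = cfg.lam_in
    else:
        raise ValueError(f"build_patterns does not handle kind {cfg.kind!r}")
    return prof


def build_patterns(cfg: SimulationConfig) -> list[PatternSpec]:
    """Draw ``cfg.p`` ground-truth patterns of the configured kind.

    Pulse positions are integers drawn uniformly from [0, t_epoch - t_pulse].
    For ``coarse_fine``, consecutive pattern pairs (0,1), (2,3), ... share one
    coarse layout and differ in the nested fine pulse.
    """
    if cfg.t_pulse > cfg.t_epoch:
        raise ValueError("t_pulse must not exceed t_epoch")
    if cfg.kind == "coarse_fine" and (cfg.t_pulse_fine or 0) > cfg.t_pulse:
        raise ValueError("t_pulse_fine must not exceed t_pulse")
    rng = np.random.default_rng(cfg.seed)
    patterns = []
    coarse_starts = None
    for pid in range(cfg.p):
        if cfg.kind == "coarse_fine" and pid % 2 == 0:
            coarse_starts = [
                _place_pulse(rng, cfg.t_epoch, cfg.t_pulse)
                for _ in range(cfg.n_neurons)
            ]
        prof = _pattern_profiles(cfg, rng, coarse_starts)
        patterns.append(PatternSpec(pid, cfg.kind, prof, seed=cfg.seed))
    return patterns


def constant_pattern(pattern_id: int, n_neurons: int, t_epoch: int,
                     rate: float, kind: str = "constant") -> PatternSpec:
    """A flat-rate pattern (used for homogeneous-noise epochs)."""
    return PatternSpec(pattern_id, kind,
                       np.full((n_neurons, t_epoch), float(rate)))


def _realize_one(rng, profiles: np.ndarray) -> list[np.ndarray]:
    counts = rng.poisson(profiles)  # (n_neurons, t_epoch)
    t = np.arange(profiles.shape[1], dtype=np.int64)
    return [np.repeat(t, counts[i]) for i in range(profiles.shape[0])]


def realize_epochs(
    patterns: Sequence[PatternSpec],
    reps: int,
    seed: int,
    labels: Sequence[str] | None = None,
    epoch_id_start: int = 0,
) -> EpochSet:
    """Realize ``reps`` inhomogeneous-Poisson epochs per pattern.

    Each sample's spike count is Poisson with the profile's rate at that
    sample.  Epochs carry ground-truth labels (``pattern<k>`` by default).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    t_epoch = patterns[0].t_epoch
    epochs = []
    eid = epoch_id_start
    for idx, pat in enumerate(patterns):
        label = labels[idx] if labels is not None else f"pattern{pat.pattern_id}"
        for _ in range(reps):
            times = _realize_one(rng, pat.profiles)
            trains = tuple(SpikeTrain(i, times[i]) for i in range(pat.n_neurons))
            epochs.append(Epoch(eid, trains, label))
            eid += 1
    return EpochSet(tuple(epochs), t_epoch=t_epoch)


def noise_rate(cfg: SimulationConfig) -> float:
    """Constant rate matching a pattern epoch's expected spike count."""
    t = cfg.t_epoch
    return (cfg.lam_in * cfg.t_pulse + cfg.lam_out * (t - cfg.t_pulse)) / t


def make_noise_epochs(cfg: SimulationConfig, n: int, seed: int | None = None) -> EpochSet:
    """Generate ``n`` noise epochs of the configured kind.

    Homogeneous: every neuron fires at the count-matched constant rate.
    Patterned: each epoch is a single realization of a fresh unique pattern
    with the same lam_in/lam_out/t_pulse (independent sub-seeds; accidental
    near-duplicates are not rejected — vanishing probability at these sizes).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    seed = cfg.seed + 1 if seed is None else seed
    if n == 0:
        return EpochSet((), t_epoch=cfg.t_epoch)
    if cfg.noise_kind == "homogeneous":
        pat = constant_pattern(-1, cfg.n_neurons, cfg.t_epoch, noise_rate(cfg))
        return realize_epochs([pat], reps=n, seed=seed, labels=[NOISE_LABEL])
    # patterned noise: one unique single-shot pattern per epoch
    rng = np.random.default_rng(seed)
    base = replace(cfg, kind=cfg.kind if cfg.kind in PATTERN_KINDS else "pulse")
    epochs = []
    for e in range(n):
        sub = int(rng.integers(0, 2**31 - 1))
        prof = _pattern_profiles(base, np.random.default_rng(sub))
        es = realize_epochs(
            [PatternSpec(-1, base.kind, prof, seed=sub)],
            reps=1, seed=sub + 1, labels=[NOISE_LABEL], epoch_id_start=e)
        epochs.append(es.epochs[0])
    return EpochSet(tuple(epochs), t_epoch=cfg.t_epoch)


def concat_epoch_sets(*sets: EpochSet) -> EpochSet:
    """Concatenate EpochSets over the same neuron set, re-numbering epoch ids."""
    sets = [s for s in sets if s.n_epochs]
    t_epoch = sets[0].t_epoch
    if any(s.t_epoch != t_epoch for s in sets):
        raise ValueError("all EpochSets must share t_epoch")
    epochs = []
    eid = 0
    for s in sets:
        for ep in s.epochs:
            epochs.append(Epoch(eid, ep.trains, ep.label))
            eid += 1
    return EpochSet(tuple(epochs), t_epoch=t_epoch,
                    electrode_of=sets[0].electrode_of)


def simulate(cfg: SimulationConfig) -> tuple[EpochSet, list[PatternSpec]]:
    """Patterns + realizations + noise epochs in one call."""
    patterns = build_patterns(cfg)
    parts = []
    if cfg.p and cfg.reps:
        parts.append(realize_epochs(patterns, cfg.reps, seed=cfg.seed + 101))
    if cfg.n_noise:
        parts.append(make_noise_epochs(cfg, cfg.n_noise, seed=cfg.seed + 202))
    return concat_epoch_sets(*parts), patterns


def apply_rate_scaling(
    patterns: Sequence[PatternSpec],
    reps: int,
    states: Sequence,
    seed: int,
    subset: np.ndarray | None = None,
) -> EpochSet:
    """Realize each pattern under each rate-scaling state.

    ``states`` entries are either a scalar (global scaling of all rates,
    keeping lam_in/lam_out constant) or a pair ``(f_subset, f_complement)``
    applied to the neuron ``subset`` and its complement respectively (the
    reversed pair models the swapped rate state).  Labels are
    ``"p<pid>|s<state>"`` so that pattern and rate-state partitions can both
    be recovered.
    """
    sets = []
    eid = 0
    for sid, state in enumerate(states):
        for pat in patterns:
            prof = pat.profiles.copy()
            if np.isscalar(state):
                if state <= 0:
                    raise ValueError("scale factors must be > 0")
                prof *= float(state)
            else:
                fa, fb = state
                if fa <= 0 or fb <= 0:
                    raise ValueError("scale factors must be > 0")
                if subset is None:
                    raise ValueError("subset scaling requires a neuron subset")
                mask = np.zeros(prof.shape[0], dtype=bool)
                mask[np.asarray(subset)] = True
                prof[mask] *= float(fa)
                prof[~mask] *= float(fb)
            scaled = PatternSpec(pat.pattern_id, pat.kind, prof)
            es = realize_epochs(
                [scaled], reps=reps, seed=seed + 1000 * sid + pat.pattern_id,
                labels=[f"p{pat.pattern_id}|s{sid}"], epoch_id_start=eid)
            eid += es.n_epochs
            sets.append(es)
    return concat_epoch_sets(*sets)


def _groups(n_neurons: int, group_size: int) -> np.ndarray:
    if group_size < 2 or n_neurons % group_size:
        raise ValueError(
            f"group size {group_size} incompatible with N={n_neurons}")
    return np.arange(n_neurons) // group_size


def inject_sorting_errors(
    es: EpochSet,
    mode: str,
    seed: int,
    group_size: int = 5,
    fraction: float = 0.0,
    n_contaminating: int | None = None,
) -> EpochSet:
    """Perturb an EpochSet with simulated spike-sorting errors.

    Neurons are grouped into virtual electrodes of ``group_size`` consecutive
    ids.  Modes:

    - ``contaminate_hidden``: only the first neuron of each group is observed;
      each of ``n_contaminating`` hidden group members adds each of its spikes
      independently with probability ``fraction``.  The output has one neuron
      per group.
    - ``exchange_within_group``: each spike moves to another uniformly chosen
      neuron of its group with probability ``fraction``.
    - ``collide``: spikes of distinct neurons of a group landing in the same
      sample are paired up; each pair is removed with probability ``fraction``.
    """
    grp = _groups(es.n_neurons, group_size)
    rng = np.random.default_rng(seed)
    n_groups = es.n_neurons // group_size
    new_epochs = []
    for ep in es.epochs:
        if mode == "contaminate_hidden":
            k = group_size - 1 if n_contaminating is None else n_contaminating
            trains = []
            for g in range(n_groups):
                members = [ep.trains[i] for i in range(es.n_neurons) if grp[i] == g]
                obs = [members[0].times]
                for hidden in members[1:1 + k]:
                    take = rng.random(hidden.n_spikes) < fraction
                    obs.append(hidden.times[take])
                trains.append(SpikeTrain(g, np.concatenate(obs)))
            new_epochs.append(Epoch(ep.epoch_id, tuple(trains), ep.label))
        elif mode == "exchange_within_group":
            dest = [list(tr.times) for tr in ep.trains]
            moved = [[] for _ in range(es.n_neurons)]
            for i, tr in enumerate(ep.trains):
                keep = []
                for t in tr.times:
                    if rng.random() < fraction:
                        others = [j for j in range(es.n_neurons)
                                  if grp[j] == grp[i] and j != i]
                        moved[others[int(rng.integers(len(others)))]].append(t)
                    else:
                        keep.append(t)
                dest[i] = keep
            trains = tuple(
                SpikeTrain(i, np.array(sorted(dest[i] + moved[i]), dtype=np.int64))
                for i in range(es.n_neurons))
            new_epochs.append(Epoch(ep.epoch_id, trains, ep.label))
        elif mode == "collide":
            remove = [np.zeros(tr.n_spikes, dtype=bool) for tr in ep.trains]
            for g in range(n_groups):
                members = [i for i in range(es.n_neurons) if grp[i] == g]
                samples = {}
                for i in members:
                    for s_idx, t in enumerate(ep.trains[i].times):
                        samples.setdefault(int(t), []).append((i, s_idx))
                for _, hits in samples.items():
                    # pair spikes from distinct neurons greedily
                    while len(hits) >= 2 and len({i for i, _ in hits}) >= 2:
                        a = hits.pop(0)
                        b_idx = next(idx for idx, h in enumerate(hits)
                                     if h[0] != a[0])
                        b = hits.pop(b_idx)
                        if rng.random() < fraction:
                            remove[a[0]][a[1]] = True
                            remove[b[0]][b[1]] = True
            trains = tuple(
                SpikeTrain(i, ep.trains[i].times[~remove[i]])
                for i in range(es.n_neurons))
            new_epochs.append(Epoch(ep.epoch_id, trains, ep.label))
        else:
            raise ValueError(f"unknown sorting-error mode {mode!r}")
    n_out = n_groups if mode == "contaminate_hidden" else es.n_neurons
    electrode_of = ({i: 0 for i in range(n_groups)}
                    if mode == "contaminate_hidden"
                    else {i: int(grp[i]) for i in range(es.n_neurons)})
    return EpochSet(tuple(new_epochs), t_epoch=es.t_epoch,
                    electrode_of=electrode_of)


def make_precise_sequences(
    p: int,
    n_neurons: int,
    t_epoch: int,
    jitter_frac: float,
    n_noise_spikes: float,
    reps: int,
    seed: int,
) -> EpochSet:
    """Patterns of one precisely timed spike per neuron, with jitter and noise.

    Each pattern fixes one spike time per neuron (uniform in the epoch).  Per
    realization every pattern spike is perturbed by an integer jitter uniform
    on [-jitter_frac*T, jitter_frac*T], and Poisson(``n_noise_spikes``) noise
    spikes per neuron are added at uniform positions.  Jittered spikes falling
    outside [0, T) are retained at their perturbed times — they still belong
    to the epoch.
    """
    if not 0 <= jitter_frac <= 1:
        raise ValueError("jitter_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    jmax = int(round(jitter_frac * t_epoch))
    base = [rng.integers(0, t_epoch, size=n_neurons) for _ in range(p)]
    epochs = []
    eid = 0
    for pid in range(p):
        for _ in range(reps):
            trains = []
            for i in range(n_neurons):
                t0 = int(base[pid][i])
                jit = int(rng.integers(-jmax, jmax + 1)) if jmax else 0
                times = [t0 + jit]
                n_noise = rng.poisson(n_noise_spikes)
                times.extend(int(x) for x in rng.integers(0, t_epoch, size=n_noise))
                trains.append(SpikeTrain(i, np.array(sorted(times), dtype=np.int64)))
            epochs.append(Epoch(eid, tuple(trains), f"pattern{pid}"))
            eid += 1
    return EpochSet(tuple(epochs), t_epoch=t_epoch)


def embed_with_onset_jitter(
    patterns: Sequence[PatternSpec],
    reps: int,
    max_offset: int,
    flank_rate: float,
    seed: int,
):
    """Embed pattern realizations in longer windows with jittered onsets.

    Each epoch is an embedding window of ``2 * t_epoch`` samples around an
    event; the pattern (length ``t_epoch``) starts at ``-t_epoch/2 + dt``
    relative to the event with ``dt`` uniform on [-max_offset, max_offset],
    and homogeneous noise at ``flank_rate`` fills the flanks.  Returns
    ``(spikes, events, labels)`` as continuous per-neuron spike streams plus
    event times, ready for :func:`spotdisclust.spike_data.extract_windows`.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    t_pat = patterns[0].t_epoch
    if max_offset > t_pat // 2:
        raise ValueError("pattern would extend beyond the embedding window")
    rng = np.random.default_rng(seed)
    n_neurons = patterns[0].n_neurons
    stride = 2 * t_pat  # disjoint embedding windows
    spikes = {i: [] for i in range(n_neurons)}
    events, labels = [], []
    e = 0
    for pat in patterns:
        for _ in range(reps):
            event = t_pat + e * stride  # window covers [event - T, event + T)
            dt = int(rng.integers(-max_offset, max_offset + 1)) if max_offset else 0
            onset = event - t_pat // 2 + dt
            times = _realize_one(rng, pat.profiles)
            for i in range(n_neurons):
                spikes[i].extend(onset + times[i])
                # homogeneous flanks before and after the embedded pattern
                for lo, hi in ((event - t_pat, onset), (onset + t_pat, event + t_pat)):
                    width = hi - lo
                    if width > 0 and flank_rate > 0:
                        cnt = rng.poisson(flank_rate * width)
                        spikes[i].extend(lo + rng.integers(0, width, size=cnt))
            events.append(event)
            labels.append(f"pattern{pat.pattern_id}" if pat.kind != "constant"
                          else NOISE_LABEL)
            e += 1
    spikes = {i: np.array(sorted(v), dtype=np.int64) for i, v in spikes.items()}
    return spikes, np.array(events, dtype=np.int64), labels
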