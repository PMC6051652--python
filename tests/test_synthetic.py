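import numpy as np
import pytest

from spotdisclust import (EpochSet, PatternSpec, SimulationConfig,
                          apply_rate_scaling, build_patterns,
                          embed_with_onset_jitter, expected_spike_count,
                          inject_sorting_errors, make_noise_epochs,
                          make_precise_sequences, realize_epochs)
from spotdisclust.synthetic import constant_pattern, noise_rate


def pulse_cfg(**kw):
    base = dict(p=3, n_neurons=10, t_epoch=300, t_pulse=30,
                lam_in=0.2, lam_out=0.02, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestBuildPatterns:
    def test_seeded_determinism(self):
        a = build_patterns(pulse_cfg(p=5, n_neurons=50))
        b = build_patterns(pulse_cfg(p=5, n_neurons=50))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.profiles, pb.profiles)

    def test_pulse_integral_closed_form(self):
        cfg = pulse_cfg()
        for pat in build_patterns(cfg):
            expected = cfg.lam_in * cfg.t_pulse + cfg.lam_out * (
                cfg.t_epoch - cfg.t_pulse)
            np.testing.assert_allclose(pat.profiles.sum(axis=1), expected)

    def test_deactivation_profile(self):
        cfg = pulse_cfg(kind="deactivation", lam_in=0.3, lam_out=0.02,
                        t_deactivation=150)
        for pat in build_patterns(cfg):
            for row in pat.profiles:
                assert np.sum(row == 0.02) == 150
                assert np.sum(row == 0.3) == 150

    def test_bimodal_two_disjoint_pulses(self):
        cfg = pulse_cfg(kind="bimodal", t_pulse=20)
        for pat in build_patterns(cfg):
            assert np.all(pat.profiles.sum(axis=1) == pytest.approx(
                2 * 20 * cfg.lam_in + (300 - 40) * cfg.lam_out))

    def test_coarse_fine_shares_coarse_layout(self):
        cfg = pulse_cfg(kind="coarse_fine", p=4, t_pulse=90,
                        t_pulse_fine=30, lam_in_fine=0.8)
        pats = build_patterns(cfg)
        # patterns (0,1) and (2,3) share the coarse (lam_in-level) support
        for a, b in ((0, 1), (2, 3)):
            coarse_a = pats[a].profiles >= cfg.lam_in
            coarse_b = pats[b].profiles >= cfg.lam_in
            np.testing.assert_array_equal(coarse_a, coarse_b)
        assert np.any((pats[0].profiles == 0.8) != (pats[1].profiles == 0.8))

    def test_synchronous_common_interval(self):
        cfg = pulse_cfg(kind="synchronous", sync_frac=0.5)
        for pat in build_patterns(cfg):
            active = np.flatnonzero((pat.profiles == cfg.lam_in).any(axis=1))
            assert len(active) == 5
            ref = pat.profiles[active[0]]
            for i in active[1:]:
                np.testing.assert_array_equal(pat.profiles[i], ref)

    def test_pulse_longer_than_epoch_errors(self):
        with pytest.raises(ValueError):
            build_patterns(pulse_cfg(t_pulse=301))


class TestExpectedCount:
    def test_sparse_firing_value(self):
        prof = np.full(300, 0.0001)
        prof[100:130] = 0.015
        assert expected_spike_count(prof) == pytest.approx(0.477)
        assert round(expected_spike_count(prof), 2) == 0.48

    def test_zero_rate(self):
        assert expected_spike_count(np.zeros(300)) == 0.0

    def test_standard_pulse(self):
        prof = np.full(300, 0.02)
        prof[0:30] = 0.2
        assert expected_spike_count(prof) == pytest.approx(11.4)


class TestRealize:
    def test_zero_rate_silent(self):
        pat = PatternSpec(0, "pulse", np.zeros((3, 100)))
        es = realize_epochs([pat], reps=5, seed=0)
        assert all(ep.n_spikes == 0 for ep in es.epochs)

    def test_seeded_reproducibility(self):
        pats = build_patterns(pulse_cfg())
        a = realize_epochs(pats, reps=3, seed=5)
        b = realize_epochs(pats, reps=3, seed=5)
        for ea, eb in zip(a.epochs, b.epochs):
            for ta, tb in zip(ea.trains, eb.trains):
                np.testing.assert_array_equal(ta.times, tb.times)

    def test_monte_carlo_mean_matches_expectation(self):
        # CLT check on the per-sample Poisson generator, 10^4 realizations
        prof = np.full(300, 0.02)
        prof[50:80] = 0.2
        pat = PatternSpec(0, "pulse", prof[None, :])
        es = realize_epochs([pat], reps=10_000, seed=123)
        counts = np.array([ep.n_spikes for ep in es.epochs])
        mu = expected_spike_count(prof)
        se = np.sqrt(mu / len(counts))  # Poisson variance = mean
        assert abs(counts.mean() - mu) < 4 * se


class TestNoiseEpochs:
    def test_homogeneous_rate_matching(self):
        cfg = pulse_cfg()
        assert noise_rate(cfg) == pytest.approx(11.4 / 300)
        es = make_noise_epochs(cfg, n=200, seed=3)
        counts = [ep.n_spikes for ep in es.epochs]
        mu = 11.4 * cfg.n_neurons
        assert np.mean(counts) == pytest.approx(mu, rel=0.05)
        assert all(ep.label == "noise" for ep in es.epochs)

    def test_patterned_noise_unique(self):
        cfg = pulse_cfg(noise_kind="patterned", n_neurons=30)
        es = make_noise_epochs(cfg, n=6, seed=3)
        assert es.n_epochs == 6
        # distinct realizations (unique patterns) with high probability
        sigs = {tuple(np.concatenate([tr.times for tr in ep.trains]))
                for ep in es.epochs}
        assert len(sigs) == 6


class TestRateScaling:
    def test_unit_factor_matches_plain_realization(self):
        pats = build_patterns(pulse_cfg(p=1))
        scaled = apply_rate_scaling(pats, reps=4, states=[1.0], seed=21)
        plain = realize_epochs(pats, reps=4, seed=21 + 1000 * 0 + 0)
        for ea, eb in zip(scaled.epochs, plain.epochs):
            for ta, tb in zip(ea.trains, eb.trains):
                np.testing.assert_array_equal(ta.times, tb.times)

    def test_global_states_preserve_ratio(self):
        pats = build_patterns(pulse_cfg(p=1))
        es = apply_rate_scaling(pats, reps=50, states=[1.0, 2.0, 3.5], seed=2)
        counts = {}
        for ep in es.epochs:
            counts.setdefault(ep.label.split("|")[1], []).append(ep.n_spikes)
        base = np.mean(counts["s0"])
        assert np.mean(counts["s1"]) / base == pytest.approx(2.0, rel=0.15)
        assert np.mean(counts["s2"]) / base == pytest.approx(3.5, rel=0.15)

    def test_subset_scaling_swaps(self):
        pats = build_patterns(pulse_cfg(p=1, n_neurons=10))
        subset = np.arange(5)
        es = apply_rate_scaling(pats, reps=80, states=[(1.0, 3.0), (3.0, 1.0)],
                                seed=4, subset=subset)
        first = np.zeros(2)
        last = np.zeros(2)
        for ep in es.epochs:
            s = int(ep.label.split("|s")[1])
            first[s] += sum(ep.trains[i].n_spikes for i in range(5))
            last[s] += sum(ep.trains[i].n_spikes for i in range(5, 10))
        assert first[0] < last[0] and first[1] > last[1]

    def test_nonpositive_factor_rejected(self):
        pats = build_patterns(pulse_cfg(p=1))
        with pytest.raises(ValueError):
            apply_rate_scaling(pats, reps=1, states=[0.0], seed=0)


class TestSortingErrors:
    def _es(self, spike_lists):
        from conftest import make_epoch
        return EpochSet((make_epoch(0, spike_lists),), t_epoch=50)

    def test_zero_probability_identity(self):
        es = self._es([[1, 2], [3], [4], [5, 6], [7], [8]])
        for mode in ("exchange_within_group", "collide"):
            out = inject_sorting_errors(es, mode, seed=0, group_size=3,
                                        fraction=0.0)
            for ta, tb in zip(es.epochs[0].trains, out.epochs[0].trains):
                np.testing.assert_array_equal(ta.times, tb.times)

    def test_collision_removes_simultaneous_pair(self):
        es = self._es([[10], [10], [20], [1], [2], [3]])
        out = inject_sorting_errors(es, "collide", seed=0, group_size=3,
                                    fraction=1.0)
        assert out.epochs[0].trains[0].n_spikes == 0
        assert out.epochs[0].trains[1].n_spikes == 0
        assert list(out.epochs[0].trains[2].times) == [20]

    def test_full_contamination_is_union(self):
        es = self._es([[1, 5], [2, 5]])
        out = inject_sorting_errors(es, "contaminate_hidden", seed=0,
                                    group_size=2, fraction=1.0)
        assert out.n_neurons == 1
        assert list(out.epochs[0].trains[0].times) == [1, 2, 5, 5]

    def test_exchange_preserves_total_count(self):
        es = self._es([[1, 2, 3], [4, 5], [6], [7], [8, 9], [10]])
        out = inject_sorting_errors(es, "exchange_within_group", seed=1,
                                    group_size=3, fraction=0.5)
        assert out.epochs[0].n_spikes == es.epochs[0].n_spikes

    def test_incompatible_group_size_errors(self):
        es = self._es([[1], [2], [3]])
        with pytest.raises(ValueError):
            inject_sorting_errors(es, "collide", seed=0, group_size=2)


class TestPreciseSequences:
    def test_zero_jitter_identical_realizations(self):
        es = make_precise_sequences(p=2, n_neurons=5, t_epoch=300,
                                    jitter_frac=0.0, n_noise_spikes=0.0,
                                    reps=3, seed=8)
        by_label = {}
        for ep in es.epochs:
            sig = tuple(tuple(tr.times) for tr in ep.trains)
            by_label.setdefault(ep.label, set()).add(sig)
        assert all(len(s) == 1 for s in by_label.values())

    def test_jitter_bounded(self):
        base = make_precise_sequences(2, 20, 300, 0.0, 0.0, reps=1, seed=9)
        jit = make_precise_sequences(2, 20, 300, 0.2, 0.0, reps=5, seed=9)
        # same seed draws the same base times first; jitter <= 0.2*300 = 60
        for ep in jit.epochs:
            pid = int(ep.label.replace("pattern", ""))
            ref = base.epochs[pid].trains
            for tr, tr0 in zip(ep.trains, ref):
                assert abs(int(tr.times[0]) - int(tr0.times[0])) <= 60

    def test_out_of_epoch_spikes_retained(self):
        es = make_precise_sequences(3, 30, 300, 1.0, 0.0, reps=5, seed=10)
        allt = np.concatenate(
            [tr.times for ep in es.epochs for tr in ep.trains])
        assert (allt < 0).any() or (allt >= 300).any()
        assert allt.size == 3 * 30 * 5  # nothing clamped or dropped


class TestOnsetJitterEmbedding:
    def test_zero_offset_fixed_onset(self):
        pats = build_patterns(pulse_cfg(p=2, n_neurons=5, lam_out=0.1))
        spikes, events, labels = embed_with_onset_jitter(
            pats, reps=3, max_offset=0, flank_rate=0.0, seed=1)
        assert len(events) == 6
        for i, ev in enumerate(events):
            lo, hi = ev - 150, ev + 150
            for nid in spikes:
                t = spikes[nid]
                local = t[(t >= ev - 300) & (t < ev + 300)]
                assert np.all((local >= lo) & (local < hi))

    def test_offset_bounds_respected(self):
        pats = build_patterns(pulse_cfg(p=1, n_neurons=5, lam_out=0.1))
        spikes, events, _ = embed_with_onset_jitter(
            pats, reps=20, max_offset=50, flank_rate=0.0, seed=2)
        for ev in events:
            for nid in spikes:
                t = spikes[nid]
                local = t[(t >= ev - 300) & (t < ev + 300)]
                if local.size:
                    assert local.min() >= ev - 200 and local.max() < ev + 200

    def test_excessive_offset_errors(self):
        pats = build_patterns(pulse_cfg(p=1, n_neurons=2))
        with pytest.raises(ValueError):
            embed_with_onset_jitter(pats, reps=1, max_offset=200,
                                    flank_rate=0.0, seed=0)
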