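import numpy as np
import pytest

from spotdisclust import (Epoch, EpochSet, SimulationConfig, SpikeTrain,
                          simulate)


def make_epoch(epoch_id, spike_lists, label=None):
    """Epoch from a list of per-neuron spike-time lists."""
    trains = tuple(
        SpikeTrain(i, np.asarray(t, dtype=np.int64))
        for i, t in enumerate(spike_lists)
    )
    return Epoch(epoch_id, trains, label)


@pytest.fixture
def tiny_epochs():
    """Three 2-neuron epochs with hand-placed spikes (t_epoch = 50)."""
    e0 = make_epoch(0, [[10, 11, 20, 23], [14, 15, 20]], "A")
    e1 = make_epoch(1, [[10, 11, 20, 23], [14, 15, 20]], "A")
    e2 = make_epoch(2, [[1, 2], [40, 45]], "B")
    return EpochSet((e0, e1, e2), t_epoch=50)


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded pattern simulation shared across tests.

    3 pulse patterns x 6 reps + 12 homogeneous-noise epochs, 20 neurons.
    """
    cfg = SimulationConfig(p=3, n_neurons=20, t_epoch=300, t_pulse=30,
                           lam_in=0.3, lam_out=0.02, reps=6, n_noise=12,
                           seed=42)
    es, patterns = simulate(cfg)
    return cfg, es, patterns


@pytest.fixture
def two_block_matrix():
    """40x40 dissimilarity: two 20-epoch blocks, within 0.1, between 0.9."""
    m = np.full((40, 40), 0.9)
    m[:20, :20] = 0.1
    m[20:, 20:] = 0.1
    np.fill_diagonal(m, 0.0)
    labels = np.repeat([0, 1], 20)
    return m, labels
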