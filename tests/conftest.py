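import numpy as np
import pytest

import retromem as rm


@pytest.fixture(scope="session")
def chain_network():
    """The worked-example chain: stripe→tiger→lion→king."""
    return rm.AssociationNetwork(
        [("stripe", "tiger", 0.034), ("tiger", "lion", 0.308), ("lion", "king", 0.021)]
    )


@pytest.fixture(scope="session")
def narrow_stimuli():
    return rm.simulate.default_stimulus_set("narrow", seed=3)


@pytest.fixture(scope="session")
def small_dataset(narrow_stimuli):
    """A 20-subject simulated experiment under the stylized preset."""
    params = rm.SimulationParams(n_subjects=20, seed=5)
    return rm.simulate_experiment(params, narrow_stimuli)


def random_network(rng, n_nodes, p_edge=0.5):
    """Random association network with per-node strength budget < 1."""
    words = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for src in words:
        targets = [w for w in words if w != src and rng.random() < p_edge]
        if not targets:
            continue
        raw = rng.random(len(targets)) + 0.05
        scale = rng.uniform(0.3, 0.95) / raw.sum()
        edges.extend((src, dst, r * scale) for dst, r in zip(targets, raw))
    # guarantee at least one edge so the network is non-trivial
    if not edges:
        edges = [(words[0], words[1], 0.5)]
    return rm.AssociationNetwork(edges)
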