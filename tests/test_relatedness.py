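"""Relatedness metrics against hand values and brute-force path/walk oracles."""

import itertools
import math

import numpy as np
import pytest

import retromem as rm
from retromem.relatedness import MissingWordError

from conftest import random_network


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def adjacency(net):
    adj = {w: {} for w in net.nodes}
    for u, v, w in net.edges:
        adj[u][v] = w
    return adj


def brute_path_length(net, src, dst, cap=6.0):
    """Minimum Σ(1−AS) over all simple paths, by exhaustive enumeration."""
    adj = adjacency(net)
    best = math.inf
    stack = [(src, 0.0, {src})]
    while stack:
        node, cost, seen = stack.pop()
        if node == dst:
            best = min(best, cost)
            continue
        for v, w in adj[node].items():
            if v not in seen:
                stack.append((v, cost + (1.0 - w), seen | {v}))
    return cap if (math.isinf(best) or best > cap) else best


def brute_spreading(net, src, dst, max_steps=3):
    """Sum of renormalized weight products over all walks of length <= max_steps."""
    adj = adjacency(net)
    norm = {
        u: {v: w / sum(nb.values()) for v, w in nb.items()}
        for u, nb in adj.items()
        if nb
    }
    total = 0.0
    walks = [[src]]
    for _ in range(max_steps):
        nxt = []
        for walk in walks:
            for v, p in norm.get(walk[-1], {}).items():
                nxt.append(walk + [v])
        for walk in nxt:
            if walk[-1] == dst:
                prod = 1.0
                for a, b in zip(walk[:-1], walk[1:]):
                    prod *= norm[a][b]
                total += prod
        walks = nxt
    return total


def brute_mediator(net, base, new):
    adj = adjacency(net)
    return sum(
        w1 * adj.get(m, {}).get(base, 0.0)
        for m, w1 in adj.get(new, {}).items()
        if m not in (base, new)
    )


# ---------------------------------------------------------------------------
# direct lookups
# ---------------------------------------------------------------------------

class TestAsLookup:
    def test_backward_reads_reverse_edge(self):
        net = rm.AssociationNetwork([("moo", "cow", 0.96)])
        assert rm.as_lookup(net, "cow", "moo", "backward") == pytest.approx(0.96)
        assert rm.as_lookup(net, "moo", "cow", "forward") == pytest.approx(0.96)

    def test_absent_edge_is_zero(self, chain_network):
        assert rm.as_lookup(chain_network, "stripe", "king", "forward") == 0.0

    def test_exhaustive_queries_match_edge_list(self):
        rng = np.random.default_rng(11)
        net = random_network(rng, 5)
        adj = adjacency(net)
        for a, b in itertools.permutations(net.nodes, 2):
            assert rm.as_lookup(net, a, b, "forward") == adj[a].get(b, 0.0)
            assert rm.as_lookup(net, a, b, "backward") == adj[b].get(a, 0.0)

    def test_unknown_word_raises(self, chain_network):
        with pytest.raises(MissingWordError, match="zebra"):
            rm.as_lookup(chain_network, "zebra", "tiger")


class TestNetworkInvariants:
    def test_rejects_self_loop_and_bad_strength(self):
        with pytest.raises(ValueError):
            rm.AssociationNetwork([("a", "a", 0.5)])
        with pytest.raises(ValueError):
            rm.AssociationNetwork([("a", "b", 0.0)])
        with pytest.raises(ValueError):
            rm.AssociationNetwork([("a", "b", 1.2)])

    def test_rejects_outgoing_sum_over_one(self):
        with pytest.raises(ValueError, match="sum"):
            rm.AssociationNetwork([("a", "b", 0.7), ("a", "c", 0.5)])


# ---------------------------------------------------------------------------
# mediator strength
# ---------------------------------------------------------------------------

class TestMediatorStrength:
    def test_single_chain_product(self):
        net = rm.AssociationNetwork(
            [("tiger", "lion", 0.5), ("lion", "mane", 0.2), ("lion", "cat", 0.1)]
        )
        assert rm.backward_mediator_strength(net, "mane", "tiger") == pytest.approx(0.10)

    def test_no_two_step_path_is_zero(self, chain_network):
        assert rm.backward_mediator_strength(chain_network, "stripe", "king") == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            net = random_network(rng, 6)
            nodes = net.nodes
            a, b = nodes[0], nodes[-1]
            assert rm.backward_mediator_strength(net, a, b) == pytest.approx(
                brute_mediator(net, a, b), abs=1e-12
            )

    def test_ignores_edges_off_two_step_paths(self):
        base = [("x", "m", 0.4), ("m", "y", 0.3)]
        extra = base + [("q", "r", 0.9), ("y", "q", 0.2)]
        n1 = rm.AssociationNetwork(base)
        n2 = rm.AssociationNetwork(extra)
        assert rm.backward_mediator_strength(
            n1, "y", "x"
        ) == rm.backward_mediator_strength(n2, "y", "x")

    def test_max_aggregate_flag(self):
        net = rm.AssociationNetwork(
            [("n", "m1", 0.5), ("n", "m2", 0.3), ("m1", "b", 0.2), ("m2", "b", 0.6)]
        )
        assert rm.backward_mediator_strength(net, "b", "n") == pytest.approx(0.28)
        assert rm.backward_mediator_strength(
            net, "b", "n", aggregate="max"
        ) == pytest.approx(0.18)


# ---------------------------------------------------------------------------
# weighted path length
# ---------------------------------------------------------------------------

class TestWeightedPathLength:
    def test_worked_chain_value(self, chain_network):
        assert rm.weighted_path_length(
            chain_network, "stripe", "king"
        ) == pytest.approx(2.637)

    def test_unreachable_is_cap(self, chain_network):
        assert rm.weighted_path_length(chain_network, "king", "stripe") == 6.0

    def test_matches_exhaustive_simple_paths(self):
        rng = np.random.default_rng(3)
        for trial in range(40):
            net = random_network(rng, 7)
            nodes = net.nodes
            src, dst = nodes[0], nodes[-1]
            assert rm.weighted_path_length(net, src, dst) == pytest.approx(
                brute_path_length(net, src, dst), abs=1e-12
            )

    def test_finite_lengths_clamped_to_cap(self):
        # a 1-step path of weight ~0.999 exceeds a cap of 0.5
        net = rm.AssociationNetwork([("a", "b", 0.001), ("b", "c", 0.1)])
        assert rm.weighted_path_length(net, "a", "b", cap=0.5) == 0.5
        assert rm.weighted_path_length(
            net, "a", "b", cap=0.5, clamp_finite=False
        ) == pytest.approx(0.999)


# ---------------------------------------------------------------------------
# spreading activation
# ---------------------------------------------------------------------------

class TestSpreadingActivation:
    def test_single_edge_renormalizes_to_one(self):
        net = rm.AssociationNetwork([("src", "dst", 0.2)])
        assert rm.spreading_activation(net, "src", "dst") == pytest.approx(1.0)

    def test_two_step_hand_value(self):
        net = rm.AssociationNetwork(
            [("src", "a", 0.3), ("a", "dst", 0.1), ("a", "z", 0.3)]
        )
        # renormalized a→dst weight is 0.1/0.4 = 0.25
        assert rm.spreading_activation(net, "src", "dst") == pytest.approx(0.25)

    def test_matches_walk_enumeration(self):
        rng = np.random.default_rng(19)
        for trial in range(40):
            net = random_network(rng, 6)
            nodes = net.nodes
            src, dst = nodes[0], nodes[-1]
            assert rm.spreading_activation(net, src, dst, 3) == pytest.approx(
                brute_spreading(net, src, dst, 3), abs=1e-12
            )

    def test_per_step_conservation(self):
        """Renormalized out-weights of every node sum to 1 (or 0 for sinks)."""
        rng = np.random.default_rng(23)
        net = random_network(rng, 8)
        for node in net.nodes:
            succ = net.successors(node)
            total = sum(w for _, w in succ)
            if total > 0:
                renorm = sum(w / total for _, w in succ)
                assert renorm == pytest.approx(1.0, abs=1e-12)

    def test_exceeds_direct_one_step_contribution(self):
        rng = np.random.default_rng(31)
        for trial in range(10):
            net = random_network(rng, 6)
            adj = adjacency(net)
            src = net.nodes[0]
            if not adj[src]:
                continue
            total_out = sum(adj[src].values())
            for dst, w in adj[src].items():
                assert rm.spreading_activation(net, src, dst, 3) >= w / total_out - 1e-12


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

class TestCosine:
    def test_identity_orthogonal_and_hand_value(self):
        vecs = rm.EmbeddingTable(
            {"e1": [1.0, 0.0], "e2": [0.0, 1.0], "same": [2.0, 1.0]}
        )
        assert rm.cosine_similarity(vecs, "same", "same") == pytest.approx(1.0)
        assert rm.cosine_similarity(vecs, "e1", "e2") == pytest.approx(0.0)
        v3 = rm.EmbeddingTable({"a": [1, 2, 3], "b": [4, 5, 6]})
        expected = 32 / (np.sqrt(14) * np.sqrt(77))
        assert rm.cosine_similarity(v3, "a", "b") == pytest.approx(expected)
        assert rm.cosine_similarity(v3, "a", "b") == rm.cosine_similarity(v3, "b", "a")

    def test_zero_vector_rejected(self):
        vecs = rm.EmbeddingTable({"z": [0.0, 0.0], "a": [1.0, 0.0]})
        with pytest.raises(ValueError, match="zero-norm"):
            rm.cosine_similarity(vecs, "z", "a")


# ---------------------------------------------------------------------------
# profiles and loaders
# ---------------------------------------------------------------------------

class TestProfile:
    def test_fields_match_individual_ops(self, chain_network):
        vecs = rm.EmbeddingTable({"stripe": [1.0, 2.0], "tiger": [2.0, 1.0]})
        rng = np.random.default_rng(5)
        net = random_network(rng, 6)
        nodes = net.nodes
        for trial in range(10):
            a, b = rng.choice(nodes, 2, replace=False)
            p = rm.profile(net, None, (a, b))
            assert p.as_backward == rm.as_lookup(net, a, b, "backward")
            assert p.as_forward == rm.as_lookup(net, a, b, "forward")
            assert p.mediator_strength == rm.backward_mediator_strength(net, a, b)
            assert p.weighted_path_length == rm.weighted_path_length(net, b, a)
            assert p.spreading_activation == rm.spreading_activation(net, b, a)
            assert p.cosine is None  # no embedding resource given

    def test_partial_resources_flag_missing_not_zero(self, chain_network):
        vecs = rm.EmbeddingTable({"stripe": [1.0, 2.0], "tiger": [2.0, 1.0]})
        p = rm.profile(chain_network, vecs, ("stripe", "tiger"))
        assert p.cosine is not None and p.as_forward == pytest.approx(0.034)
        p2 = rm.profile(chain_network, vecs, ("lion", "king"))
        assert p2.cosine is None  # absent from embeddings, not 0
        assert p2.as_backward is not None


class TestLoaders:
    def test_tsv_roundtrip(self, tmp_path):
        f = tmp_path / "norms.tsv"
        f.write_text("# free association norms\nMoo\tCow\t0.96\nstripe\ttiger\t0.034\n")
        net = rm.load_association_tsv(f)
        assert rm.as_lookup(net, "cow", "moo", "backward") == pytest.approx(0.96)

    def test_embedding_text_with_and_without_header(self, tmp_path):
        body = "apple 1.0 2.0\npear 3.0 4.0\n"
        f1 = tmp_path / "plain.txt"
        f1.write_text(body)
        f2 = tmp_path / "header.txt"
        f2.write_text("2 2\n" + body)
        for f in (f1, f2):
            vecs = rm.load_embeddings(f)
            assert len(vecs) == 2 and vecs.dim == 2
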