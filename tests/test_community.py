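"""Modularity, null networks, Louvain and the exhaustive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kincomm import (
    KinaseNetwork,
    NullModel,
    Partition,
    brute_force_partition,
    louvain_partition,
    modularity,
    null_matrix,
)
from kincomm.exceptions import CoverageError, SizeError, ValidationError

from conftest import random_network


def eq1_oracle(network, partition, null):
    """Independent term-by-term evaluation of the quality function:
    sum over all ordered pairs (i, j) of (A_ij - P_ij) * delta(c_i, c_j)."""
    a = network.weights
    p = null_matrix(network, null)
    labels = partition.labels(network.nodes)
    total = 0.0
    for i in range(network.n):
        for j in range(network.n):
            if labels[i] == labels[j]:
                total += a[i, j] - p[i, j]
    return total


class TestNullMatrix:
    def test_two_node_newman_girvan(self):
        w = 3.0
        net = KinaseNetwork.from_edges({("A", "B"): w})
        p = null_matrix(net, NullModel("newman-girvan"))
        # s_A = s_B = w, 2m = 2w: off-diagonal w*w/(2w) = w/2, diagonal kept
        assert p[0, 1] == pytest.approx(w / 2)
        assert p[0, 0] == pytest.approx(w / 2)

    def test_uniform_on_constant_complete_network(self):
        c = 0.7
        net = KinaseNetwork.from_edges(
            {("A", "B"): c, ("A", "C"): c, ("B", "C"): c}
        )
        p = null_matrix(net, NullModel("uniform"))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(p[off], c)
        assert np.all(np.diag(p) == 0)

    def test_linear_in_resolution(self):
        net = random_network(np.random.default_rng(0), 6)
        for kind in ("uniform", "newman-girvan"):
            p1 = null_matrix(net, NullModel(kind, resolution=1.0))
            p2 = null_matrix(net, NullModel(kind, resolution=2.0))
            assert np.allclose(p2, 2 * p1)

    def test_invalid_resolution(self):
        with pytest.raises(ValidationError):
            NullModel("uniform", resolution=0.0)

    def test_unknown_kind(self):
        with pytest.raises(ValidationError):
            NullModel("configuration")


class TestModularity:
    def test_one_community_ng_is_zero(self):
        for seed in range(5):
            net = random_network(np.random.default_rng(seed), 7)
            one = Partition({v: 0 for v in net.nodes})
            assert modularity(net, one, NullModel("ng")) == pytest.approx(0.0, abs=1e-9)

    def test_constant_complete_uniform_any_partition_zero(self):
        c = 1.3
        net = KinaseNetwork.from_edges(
            {("A", "B"): c, ("A", "C"): c, ("B", "C"): c, ("A", "D"): c,
             ("B", "D"): c, ("C", "D"): c}
        )
        null = NullModel("uniform")
        for assign in ({"A": 0, "B": 0, "C": 1, "D": 1}, {"A": 0, "B": 1, "C": 2, "D": 3}):
            assert modularity(net, Partition(assign), null) == pytest.approx(0.0, abs=1e-12)

    def test_four_node_hand_example(self):
        """Two heavy edges + one weak bridge, split at the bridge (NG, gamma 1)."""
        net = KinaseNetwork.from_edges(
            {("K1", "K2"): 3.0, ("K3", "K4"): 3.0, ("K2", "K3"): 1.0}
        )
        part = Partition({"K1": 0, "K2": 0, "K3": 1, "K4": 1})
        null = NullModel("ng")
        q = modularity(net, part, null)
        assert q == pytest.approx(eq1_oracle(net, part, null))
        assert q == pytest.approx(5.0)  # hand evaluation: (6 - 49/14) per block, 2 blocks

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            net = random_network(rng, int(rng.integers(3, 8)))
            labels = rng.integers(0, 3, size=net.n)
            part = Partition.from_labels(net.nodes, labels)
            for kind in ("uniform", "ng"):
                null = NullModel(kind)
                assert modularity(net, part, null) == pytest.approx(
                    eq1_oracle(net, part, null)
                )

    def test_relabel_and_permutation_invariance(self):
        rng = np.random.default_rng(3)
        net = random_network(rng, 6)
        part = Partition.from_labels(net.nodes, [0, 0, 1, 1, 2, 2])
        relabeled = Partition({v: {0: "x", 1: "y", 2: "z"}[l] for v, l in part.assignment.items()})
        perm = rng.permutation(6)
        permuted_net = KinaseNetwork(
            [net.nodes[i] for i in perm], net.weights[np.ix_(perm, perm)], "rand", "negative"
        )
        null = NullModel("ng")
        q = modularity(net, part, null)
        assert modularity(net, relabeled, null) == pytest.approx(q)
        assert modularity(permuted_net, part, null) == pytest.approx(q)

    def test_coverage_error(self, two_clique_network):
        with pytest.raises(CoverageError):
            modularity(two_clique_network, Partition({"K0": 0}), NullModel("ng"))


class TestLouvain:
    @pytest.mark.parametrize("kind", ["uniform", "ng"])
    def test_recovers_two_cliques(self, two_clique_network, planted_partition, kind):
        null = NullModel(kind)
        part = louvain_partition(two_clique_network, null, seed=0)
        assert part.equivalent(planted_partition)
        bf = brute_force_partition(two_clique_network, null)
        assert modularity(two_clique_network, part, null) == pytest.approx(
            modularity(two_clique_network, bf, null)
        )

    def test_disconnected_edges_each_their_own_community(self):
        net = KinaseNetwork.from_edges({("A", "B"): 1.0, ("C", "D"): 1.0})
        part = louvain_partition(net, NullModel("ng"), seed=1)
        assert part.equivalent(Partition({"A": 0, "B": 0, "C": 1, "D": 1}))

    def test_never_worse_than_singletons(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            net = random_network(rng, 10)
            for kind in ("uniform", "ng"):
                null = NullModel(kind)
                part = louvain_partition(net, null, seed=seed)
                singles = Partition({v: i for i, v in enumerate(net.nodes)})
                assert modularity(net, part, null) >= modularity(net, singles, null) - 1e-9

    def test_seed_reproducibility(self):
        net = random_network(np.random.default_rng(7), 12)
        null = NullModel("uniform")
        a = louvain_partition(net, null, seed=123)
        b = louvain_partition(net, null, seed=123)
        assert a.assignment == b.assignment

    def test_local_optimum_no_single_move_improves(self):
        net = random_network(np.random.default_rng(9), 9)
        null = NullModel("ng")
        part = louvain_partition(net, null, seed=2)
        q = modularity(net, part, null)
        labels = dict(part.assignment)
        targets = set(labels.values()) | {max(labels.values()) + 1}
        for node in net.nodes:
            for lab in targets:
                if lab == labels[node]:
                    continue
                moved = Partition({**labels, node: lab})
                assert modularity(net, moved, null) <= q + 1e-9


class TestBruteForce:
    def test_two_node_tie_broken_to_one_community(self):
        net = KinaseNetwork.from_edges({("A", "B"): 2.0})
        part = brute_force_partition(net, NullModel("uniform"))
        assert part.communities == [frozenset({"A", "B"})]

    def test_matches_louvain_on_planted(self, two_clique_network, planted_partition):
        part = brute_force_partition(two_clique_network, NullModel("ng"))
        assert part.equivalent(planted_partition)

    def test_upper_bounds_louvain_on_random_five_node_networks(self):
        rng = np.random.default_rng(21)
        net = random_network(rng, 5)
        for kind in ("uniform", "ng"):
            null = NullModel(kind)
            q_bf = modularity(net, brute_force_partition(net, null), null)
            for seed in range(50):
                q_lv = modularity(net, louvain_partition(net, null, seed=seed), null)
                assert q_lv <= q_bf + 1e-9

    def test_refuses_large_networks(self):
        net = random_network(np.random.default_rng(0), 13)
        with pytest.raises(SizeError):
            brute_force_partition(net, NullModel("ng"))


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10_000))
def test_louvain_upper_bounded_by_oracle_property(seed):
    """For random small networks, the heuristic never beats the oracle."""
    rng = np.random.default_rng(seed)
    net = random_network(rng, int(rng.integers(3, 7)))
    null = NullModel("ng" if seed % 2 else "uniform")
    q_bf = modularity(net, brute_force_partition(net, null), null)
    q_lv = modularity(net, louvain_partition(net, null, seed=seed), null)
    assert q_lv <= q_bf + 1e-9
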