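"""Modularity maximisation with pluggable null networks.

The quality function is the unnormalised modularity

    Q(c) = sum_{i,j} (A_ij - P_ij) * delta(c_i, c_j)

summed over all ordered node pairs, including i = j.  A is the weighted
adjacency matrix and P the expected adjacency under a null model:

* ``newman-girvan``: P_ij = gamma * s_i s_j / (2m), where s_i is the strength
  of node i and 2m the total weight.  The diagonal term gamma * s_i^2 / (2m)
  is kept (the sum runs over i = j too); this is what makes Q of the
  one-community partition exactly zero at gamma = 1, because the null then
  preserves total strength.
* ``uniform``: constant expected weight P_ij = gamma * <w> off the diagonal,
  with <w> = total_weight / (n (n - 1)), and P_ii = 0.  On a complete network
  with equal weights every partition scores zero at gamma = 1.

The resolution parameter gamma (default 1, a single scale) multiplies the
null and controls the size of communities.

Maximisation uses the Louvain heuristic: greedy local moving of single nodes
in a seed-determined random order (re-randomised at the start of every pass),
followed by aggregation of communities into super-nodes, repeated until no
move improves Q.  Because the null matrix is arbitrary, the aggregation
carries B = A - gamma * P through (summing blocks of B), not just the
weights.  A final local-moving pass on the flat network guarantees the
returned partition is a genuine single-node-move local optimum.  An
exhaustive oracle over all set partitions is provided for n <= 12.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import CoverageError, DegenerateNetworkError, SizeError, ValidationError
from .network import KinaseNetwork

__all__ = [
    "NullModel",
    "Partition",
    "null_matrix",
    "modularity",
    "louvain_partition",
    "brute_force_partition",
    "enumerate_partition_labels",
]

#: Minimal strict improvement for accepting a move (guards against cycling on
#: floating-point noise).
MIN_GAIN = 1e-12

_NULL_KINDS = {"uniform": "uniform", "newman-girvan": "newman-girvan", "ng": "newman-girvan"}


@dataclass(frozen=True)
class NullModel:
    """Null-network specification: kind and resolution gamma > 0."""

    kind: str = "newman-girvan"
    resolution: float = 1.0

    def __post_init__(self) -> None:
        kind = _NULL_KINDS.get(self.kind)
        if kind is None:
            raise ValidationError(f"unknown null model kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        if not self.resolution > 0:
            raise ValidationError("resolution must be positive")


@dataclass
class Partition:
    """Assignment of each node to a community label.

    Labels are arbitrary; two partitions are equivalent when they induce the
    same grouping.  ``communities`` lists the node sets sorted by their
    smallest member for reproducible iteration order.
    """

    assignment: dict[str, int | str]

    @property
    def nodes(self) -> set[str]:
        return set(self.assignment)

    @property
    def communities(self) -> list[frozenset[str]]:
        groups: dict[int | str, set[str]] = {}
        for node, label in self.assignment.items():
            groups.setdefault(label, set()).add(node)
        return [frozenset(g) for g in sorted(groups.values(), key=lambda g: min(g))]

    def labels(self, nodes: Sequence[str]) -> np.ndarray:
        """Integer label array aligned to ``nodes`` (coverage-checked)."""
        missing = [v for v in nodes if v not in self.assignment]
        if missing:
            raise CoverageError(f"nodes missing from partition: {missing}")
        uniq: dict[int | str, int] = {}
        out = np.empty(len(nodes), dtype=np.int64)
        for i, v in enumerate(nodes):
            out[i] = uniq.setdefault(self.assignment[v], len(uniq))
        return out

    def community_of(self, node: str) -> frozenset[str]:
        if node not in self.assignment:
            raise CoverageError(f"node {node!r} not in partition")
        label = self.assignment[node]
        return frozenset(v for v, l in self.assignment.items() if l == label)

    def equivalent(self, other: "Partition") -> bool:
        return set(self.communities) == set(other.communities)

    @classmethod
    def from_labels(cls, nodes: Sequence[str], labels: Iterable[int]) -> "Partition":
        return cls({v: int(l) for v, l in zip(nodes, labels)})


def null_matrix(network: KinaseNetwork, null: NullModel) -> np.ndarray:
    """Expected adjacency P under the null model (see module docstring)."""
    if network.n == 0:
        raise DegenerateNetworkError("empty network")
    two_m = network.total_weight
    if two_m == 0:
        raise DegenerateNetworkError("network has zero total weight")
    return _null_from_matrix(network.weights, null)


def _null_from_matrix(weights: np.ndarray, null: NullModel) -> np.ndarray:
    """Null matrix from a raw symmetric weight matrix (consensus iterations
    re-run community detection on co-classification matrices that are not
    KinaseNetwork instances)."""
    n = weights.shape[0]
    two_m = float(weights.sum())
    gamma = null.resolution
    if null.kind == "newman-girvan":
        s = weights.sum(axis=1)
        return gamma * np.outer(s, s) / two_m
    mean_w = two_m / (n * (n - 1)) if n > 1 else 0.0
    p = np.full((n, n), gamma * mean_w)
    np.fill_diagonal(p, 0.0)
    return p


def _modularity_from_labels(b: np.ndarray, labels: np.ndarray) -> float:
    """Q = sum of B over within-community ordered pairs (diagonal included)."""
    q = 0.0
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        q += b[np.ix_(members, members)].sum()
    return float(q)


def modularity(network: KinaseNetwork, partition: Partition, null: NullModel) -> float:
    """Evaluate the quality function for a partition of the network."""
    extra = partition.nodes - set(network.nodes)
    if extra:
        raise CoverageError(f"partition has nodes outside the network: {sorted(extra)}")
    labels = partition.labels(network.nodes)
    b = network.weights - null_matrix(network, null)
    return _modularity_from_labels(b, labels)


def _compress(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _local_moving(
    b: np.ndarray,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy single-node moves until a full pass makes no move.

    Each node is offered every currently occupied community plus isolation;
    the first-encountered best (in community-label order) wins, and a move is
    accepted only for a strict gain above :data:`MIN_GAIN`.
    """
    n = b.shape[0]
    labels = np.arange(n) if init is None else _compress(init)
    moved = True
    while moved:
        moved = False
        order = rng.permutation(n)
        for i in order:
            row = b[i].copy()
            row[i] = 0.0
            k = int(labels.max()) + 1
            gains = np.bincount(labels, weights=row, minlength=k + 1)
            cur = labels[i]
            # slot k stays 0-weight: moving i into a fresh singleton community
            gains[k] = 0.0
            delta = gains - gains[cur]
            best = int(np.argmax(delta))
            if best != cur and delta[best] > MIN_GAIN:
                labels[i] = best
                moved = True
        labels = _compress(labels)
    return labels


def _louvain_labels(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Full Louvain on a modularity matrix B = A - gamma*P."""
    n = b.shape[0]
    flat = np.arange(n)
    b_level = b
    while True:
        labels = _local_moving(b_level, rng)
        k = int(labels.max()) + 1
        if k == b_level.shape[0]:
            break
        flat = labels[flat]
        # aggregate B into super-node blocks (diagonal keeps within-community mass)
        sel = np.zeros((b_level.shape[0], k))
        sel[np.arange(b_level.shape[0]), labels] = 1.0
        b_level = sel.T @ b_level @ sel
    # flat refinement: guarantee no single original node can improve Q
    return _local_moving(b, rng, init=flat)


def louvain_partition(
    network: KinaseNetwork, null: NullModel, seed: int | np.random.SeedSequence = 0
) -> Partition:
    """One nondeterministic Louvain run; identical seed -> identical result."""
    b = network.weights - null_matrix(network, null)
    rng = np.random.default_rng(seed)
    labels = _louvain_labels(b, rng)
    return Partition.from_labels(network.nodes, labels)


def enumerate_partition_labels(n: int) -> Iterator[np.ndarray]:
    """Yield every set partition of ``range(n)`` as a restricted-growth
    label array (first occurrence of each label is in increasing order)."""
    labels = np.zeros(n, dtype=np.int64)
    maxes = np.zeros(n, dtype=np.int64)  # max label among positions < i

    def rec(i: int) -> Iterator[np.ndarray]:
        if i == n:
            yield labels.copy()
            return
        top = maxes[i - 1] if i else -1
        for lab in range(top + 2):
            labels[i] = lab
            if i + 1 < n:
                maxes[i] = max(top, lab)
            yield from rec(i + 1)

    return rec(0)


def _canonical_form(nodes: Sequence[str], labels: np.ndarray) -> tuple:
    groups: dict[int, list[str]] = {}
    for v, lab in zip(nodes, labels):
        groups.setdefault(int(lab), []).append(v)
    return tuple(sorted(tuple(sorted(g)) for g in groups.values()))


def brute_force_partition(network: KinaseNetwork, null: NullModel) -> Partition:
    """Exhaustive global maximiser of the quality function (oracle, n <= 12).

    Ties are broken by fewest communities, then by lexicographically smallest
    canonical form of the grouping.
    """
    n = network.n
    if n > 12:
        raise SizeError(f"brute force limited to n <= 12, got {n}")
    b = network.weights - null_matrix(network, null)
    best: tuple | None = None
    best_labels: np.ndarray | None = None
    for labels in enumerate_partition_labels(n):
        q = _modularity_from_labels(b, labels)
        k = int(labels.max()) + 1
        key = (-q, k, _canonical_form(network.nodes, labels))
        if best is None or key < best:
            best = key
            best_labels = labels
    assert best_labels is not None
    return Partition.from_labels(network.nodes, best_labels)
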