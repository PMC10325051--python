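"""Consensus clustering by iterated co-classification.

A single Louvain run is nondeterministic (node order is randomised each
pass), so community assignments can differ between runs.  The consensus
procedure runs an ensemble of Louvain runs, computes the co-classification
matrix (entry (i, j) = fraction of runs placing i and j in the same
community), and re-runs the whole ensemble on that matrix, treated as a
weighted network over the same nodes, until the resulting co-classification
matrix is binary — typically after one or two iterations on well-structured
networks.  The consensus partition is read off the binary matrix's connected
blocks.

Per-run seeds are derived from the master seed with a counter-based scheme
(master, iteration, run), so any individual run can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .community import NullModel, Partition, _louvain_labels, _null_from_matrix
from .exceptions import CoverageError, NonConvergenceError, ValidationError
from .network import KinaseNetwork

__all__ = [
    "CoClassificationMatrix",
    "ConsensusResult",
    "coclassification",
    "consensus_partition",
    "compare_partitions",
    "consensus_robustness",
    "derive_seed",
]


def derive_seed(*path: int) -> int:
    """Deterministic child seed from a counter path (kept below 2**31)."""
    return int(np.random.SeedSequence(list(path)).generate_state(1)[0] % (2**31))


@dataclass
class CoClassificationMatrix:
    """Fraction-of-co-assignment matrix over an ensemble of partitions."""

    nodes: list[str]
    values: np.ndarray
    ensemble_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        if self.values.shape != (n, n):
            raise ValidationError("co-classification matrix shape mismatch")

    @property
    def counts(self) -> np.ndarray:
        """Integer co-assignment counts (values * ensemble_size)."""
        return np.rint(self.values * self.ensemble_size).astype(np.int64)

    def is_binary(self) -> bool:
        """True when every entry is exactly 0 or 1 (as a count fraction)."""
        c = self.counts
        return bool(np.all((c == 0) | (c == self.ensemble_size)))

    def block_partition(self) -> Partition:
        """Partition whose communities are the connected blocks of the
        matrix viewed as a graph (positive entries = edges)."""
        adj = csr_matrix(self.values > 0)
        _, labels = connected_components(adj, directed=False)
        return Partition.from_labels(self.nodes, labels)


@dataclass
class ConsensusResult:
    partition: Partition
    iterations: int
    history: list[CoClassificationMatrix]
    ensemble_size: int = 0
    seed: int = 0


def coclassification(partitions: Sequence[Partition]) -> CoClassificationMatrix:
    """Co-classification matrix of an ensemble of partitions over one node set."""
    if not partitions:
        raise ValidationError("need at least one partition")
    nodes = sorted(partitions[0].nodes)
    values = np.zeros((len(nodes), len(nodes)))
    for p in partitions:
        if p.nodes != set(nodes):
            raise CoverageError("partitions are not over a common node set")
        labels = p.labels(nodes)
        values += (labels[:, None] == labels[None, :]).astype(float)
    values /= len(partitions)
    return CoClassificationMatrix(nodes, values, ensemble_size=len(partitions))


def _run_ensemble(
    weights: np.ndarray,
    nodes: list[str],
    null: NullModel,
    ensemble_size: int,
    seeds: Sequence[int],
) -> CoClassificationMatrix:
    b = weights - _null_from_matrix(weights, null)
    parts = []
    for s in seeds:
        labels = _louvain_labels(b, np.random.default_rng(s))
        parts.append(Partition.from_labels(nodes, labels))
    return coclassification(parts)


def consensus_partition(
    network: KinaseNetwork,
    null: NullModel,
    ensemble_size: int = 100,
    seed: int = 0,
    max_iterations: int = 20,
    threshold: float = 0.0,
) -> ConsensusResult:
    """Iterate ensemble Louvain + co-classification to a binary consensus.

    ``threshold`` optionally zeroes co-classification entries below a cut
    before the next iteration (0 = off, the default: the matrix itself is
    re-clustered).  Raises :class:`NonConvergenceError` (carrying the last
    matrix) if the matrix is not binary after ``max_iterations`` ensembles.
    """
    if ensemble_size < 1:
        raise ValidationError("ensemble_size must be >= 1")
    nodes = list(network.nodes)
    weights = network.weights
    history: list[CoClassificationMatrix] = []
    for iteration in range(1, max_iterations + 1):
        seeds = [derive_seed(seed, iteration, run) for run in range(ensemble_size)]
        cc = _run_ensemble(weights, nodes, null, ensemble_size, seeds)
        history.append(cc)
        if cc.is_binary():
            return ConsensusResult(
                partition=cc.block_partition(),
                iterations=iteration,
                history=history,
                ensemble_size=ensemble_size,
                seed=seed,
            )
        weights = cc.values.copy()
        np.fill_diagonal(weights, 0.0)
        if threshold > 0:
            weights[weights < threshold] = 0.0
    raise NonConvergenceError(
        f"co-classification not binary after {max_iterations} iterations",
        last_matrix=history[-1],
    )


@dataclass
class PartitionSimilarity:
    ari: float
    nmi: float


def compare_partitions(p1: Partition, p2: Partition) -> PartitionSimilarity:
    """Adjusted Rand index and normalised mutual information of two
    partitions over the same node set (1 iff identical up to relabeling)."""
    if p1.nodes != p2.nodes:
        raise CoverageError("partitions are not over the same node set")
    nodes = sorted(p1.nodes)
    a, b = p1.labels(nodes), p2.labels(nodes)
    return PartitionSimilarity(
        ari=float(adjusted_rand_score(a, b)),
        nmi=float(normalized_mutual_info_score(a, b)),
    )


@dataclass
class RobustnessSummary:
    repeats: int
    min_ari: float
    mean_ari: float
    min_nmi: float
    mean_nmi: float
    pairwise: list[tuple[int, int, float, float]] = field(default_factory=list)


def consensus_robustness(
    network: KinaseNetwork,
    null: NullModel,
    repeats: int = 5,
    ensemble_size: int = 100,
    seed: int = 0,
    max_iterations: int = 20,
) -> RobustnessSummary:
    """Repeat the consensus procedure with distinct master seeds and report
    all pairwise partition similarities (robustness check)."""
    if repeats < 2:
        raise ValidationError("repeats must be >= 2")
    results = [
        consensus_partition(
            network,
            null,
            ensemble_size=ensemble_size,
            seed=derive_seed(seed, 0, rep),
            max_iterations=max_iterations,
        )
        for rep in range(repeats)
    ]
    pairwise = []
    aris, nmis = [], []
    for i, j in combinations(range(repeats), 2):
        sim = compare_partitions(results[i].partition, results[j].partition)
        pairwise.append((i, j, sim.ari, sim.nmi))
        aris.append(sim.ari)
        nmis.append(sim.nmi)
    return RobustnessSummary(
        repeats=repeats,
        min_ari=min(aris),
        mean_ari=float(np.mean(aris)),
        min_nmi=min(nmis),
        mean_nmi=float(np.mean(nmis)),
        pairwise=pairwise,
    )
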