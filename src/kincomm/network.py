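"""Kinase network construction from sign-filtered z-scores.

For each treatment, the edges are the kinase pairs whose z-score is strictly
of the requested sign (negative = inhibited interactions, positive =
up-regulated ones) and the edge weight is the absolute z-score.  Networks are
weighted and undirected: the data carry no information about which kinase
acts upstream of the other.  Nodes are exactly the kinases incident to a
retained edge; a kinase appearing only in pairs of the other sign is absent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .exceptions import EmptyNetworkError, FormatError, ValidationError
from .zscore_io import ZScoreTable

__all__ = ["KinaseNetwork", "build_network", "write_network", "read_network"]


@dataclass
class KinaseNetwork:
    """Weighted undirected kinase network for one treatment and one sign.

    ``weights`` is the symmetric adjacency matrix A (zero diagonal,
    non-negative entries) over ``nodes``, which are kept sorted
    lexicographically so the matrix is reproducible across runs.
    """

    nodes: list[str]
    weights: np.ndarray
    treatment: str = ""
    sign: str = "negative"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValidationError("weight matrix shape does not match node list")
        if len(set(self.nodes)) != n:
            raise ValidationError("duplicate node names")
        if not np.allclose(self.weights, self.weights.T):
            raise ValidationError("weight matrix is not symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValidationError("self-loops are not allowed")
        if np.any(self.weights < 0):
            raise ValidationError("negative edge weights are not allowed")
        if n and np.any(self.weights.sum(axis=1) == 0):
            isolated = [self.nodes[i] for i in np.flatnonzero(self.weights.sum(axis=1) == 0)]
            raise ValidationError(f"isolated node(s) not allowed: {isolated}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def total_weight(self) -> float:
        """Sum of all entries of A, i.e. 2m."""
        return float(self.weights.sum())

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths s_i (row sums of A)."""
        return self.weights.sum(axis=1)

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def edge_weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights)))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(treatment=self.treatment, sign=self.sign)
        g.add_nodes_from(self.nodes)
        i, j = np.nonzero(np.triu(self.weights))
        for a, b in zip(i, j):
            g.add_edge(self.nodes[a], self.nodes[b], weight=float(self.weights[a, b]))
        return g

    @classmethod
    def from_edges(
        cls,
        edges: dict[tuple[str, str], float],
        treatment: str = "",
        sign: str = "negative",
    ) -> "KinaseNetwork":
        """Build from an {(a, b): weight} mapping (unordered pairs)."""
        nodes = sorted({k for pair in edges for k in pair})
        idx = {k: i for i, k in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for (a, b), weight in edges.items():
            w[idx[a], idx[b]] = weight
            w[idx[b], idx[a]] = weight
        return cls(nodes, w, treatment, sign)


def build_network(table: ZScoreTable, treatment: str, sign: str = "negative") -> KinaseNetwork:
    """Sign-filter a z-score column into a weighted undirected network.

    An edge is kept for every pair whose z is strictly of the requested sign;
    its weight is |z|.  Raises :class:`EmptyNetworkError` if nothing survives.
    """
    if treatment not in table.treatments:
        raise ValidationError(f"unknown treatment {treatment!r}")
    if sign not in ("negative", "positive"):
        raise ValidationError(f"sign must be 'negative' or 'positive', got {sign!r}")
    col = table.data[treatment]
    keep = (col < 0) if sign == "negative" else (col > 0)
    if not keep.any():
        raise EmptyNetworkError(f"no {sign} z-scores for treatment {treatment!r}")
    edges = {pair: abs(float(z)) for pair, z in col[keep].items()}
    return KinaseNetwork.from_edges(edges, treatment=treatment, sign=sign)


def write_network(network: KinaseNetwork, path: str | Path, format: str = "graphml") -> None:
    """Serialise a network losslessly (GraphML) or as an edge-list CSV.

    The edge list carries the treatment/sign metadata in leading ``#``
    comment lines so both formats round-trip.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif format == "edge-list":
        with open(path, "w", newline="") as fh:
            fh.write(f"# treatment: {network.treatment}\n")
            fh.write(f"# sign: {network.sign}\n")
            writer = csv.writer(fh)
            writer.writerow(["kinase_a", "kinase_b", "weight"])
            i, j = np.nonzero(np.triu(network.weights))
            for a, b in zip(i, j):
                writer.writerow(
                    [network.nodes[a], network.nodes[b], repr(float(network.weights[a, b]))]
                )
    else:
        raise ValidationError(f"unknown format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> KinaseNetwork:
    """Read a network written by :func:`write_network`, validating weights."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing file: {path}")
    if format == "graphml":
        try:
            g = nx.read_graphml(path)
        except Exception as exc:
            raise FormatError(f"could not parse GraphML {path}: {exc}") from exc
        edges = {}
        for a, b, attrs in g.edges(data=True):
            w = float(attrs.get("weight", float("nan")))
            if not np.isfinite(w) or w < 0:
                raise ValidationError(f"invalid weight {w} on edge {a}-{b}")
            edges[(a, b)] = w
        net = KinaseNetwork.from_edges(
            edges,
            treatment=str(g.graph.get("treatment", "")),
            sign=str(g.graph.get("sign", "negative")),
        )
        extra = set(g.nodes) - set(net.nodes)
        if extra:
            raise ValidationError(f"isolated node(s) in file: {sorted(extra)}")
        return net
    if format == "edge-list":
        treatment, sign = "", "negative"
        edges = {}
        with open(path) as fh:
            rows = []
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# treatment:"):
                    treatment = line.split(":", 1)[1].strip()
                elif line.startswith("# sign:"):
                    sign = line.split(":", 1)[1].strip()
                elif line and not line.startswith("#"):
                    rows.append(line)
        if not rows:
            raise FormatError(f"no edges in {path}")
        for row_no, line in enumerate(rows[1:], start=2):
            parts = next(csv.reader([line]))
            if len(parts) != 3:
                raise FormatError(f"row {row_no} of {path}: expected 3 fields")
            a, b, wtext = parts
            try:
                w = float(wtext)
            except ValueError as exc:
                raise FormatError(f"row {row_no} of {path}: bad weight {wtext!r}") from exc
            if w < 0:
                raise ValidationError(f"row {row_no} of {path}: negative weight {w}")
            key = (a, b) if a <= b else (b, a)
            if key in edges and edges[key] != w:
                raise ValidationError(f"conflicting duplicate edge {key} in {path}")
            edges[key] = w
        return KinaseNetwork.from_edges(edges, treatment=treatment, sign=sign)
    raise ValidationError(f"unknown format {format!r}")
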