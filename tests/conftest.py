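import numpy as np
import pandas as pd
import pytest

from kincomm import KinaseNetwork, ZScoreTable


def make_table(rows, treatments=("trt",)):
    """Build a ZScoreTable from (a, b, z...) tuples; None = missing."""
    pairs = []
    cols = {t: [] for t in treatments}
    for row in rows:
        a, b, *zs = row
        pairs.append((a, b) if a <= b else (b, a))
        for t, z in zip(treatments, zs):
            cols[t].append(np.nan if z is None else float(z))
    index = pd.MultiIndex.from_tuples(pairs, names=["kinase_a", "kinase_b"])
    return ZScoreTable(pd.DataFrame(cols, index=index).sort_index())


def random_network(rng, n, density=0.6):
    """Random connected-enough weighted network (every node has an edge)."""
    while True:
        w = np.triu((rng.random((n, n)) + 0.05) * (rng.random((n, n)) < density), 1)
        w = w + w.T
        if not (w.sum(axis=1) == 0).any():
            return KinaseNetwork([f"K{i:02d}" for i in range(n)], w, "rand", "negative")


@pytest.fixture
def toy_table():
    """Three pairs, one treatment: two negative z-scores, one positive."""
    return make_table([("K1", "K2", -2.0), ("K1", "K3", 1.5), ("K2", "K3", -0.5)])


@pytest.fixture
def two_clique_network():
    """Two 4-cliques (weight 1 inside) joined by a single weight-0.1 edge."""
    edges = {}
    for off in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                edges[(f"K{off + i}", f"K{off + j}")] = 1.0
    edges[("K0", "K4")] = 0.1
    return KinaseNetwork.from_edges(edges, treatment="toy", sign="negative")


@pytest.fixture
def planted_partition():
    """The planted two-clique grouping for the fixture above."""
    from kincomm import Partition

    return Partition({f"K{i}": (0 if i < 4 else 1) for i in range(8)})
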