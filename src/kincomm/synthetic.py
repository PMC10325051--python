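"""Synthetic z-score tables with planted community structure.

The generator emulates the statistical shape of inhibitor-perturbation
kinase-pair z-scores: mostly small negative values (inhibited interactions)
with a heavy negative tail reaching magnitudes far below the bulk, a
sprinkling of small positive values (up-regulated interactions), and many
missing pairs.  Community structure is planted: within-community pairs get
an edge more often and with a stronger negative mean than between-community
pairs, reflecting the idea that inhibiting one pathway member depresses the
interactions inside that pathway.

One community is designated the "pathway" community; its first member plays
the role of the inhibitor's main target and its first three members act as
the anchor kinases, so the whole candidate-nomination pipeline can be
exercised and scored against the planted truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import Partition
from .consensus import compare_partitions, derive_seed
from .exceptions import CoverageError, ValidationError
from .zscore_io import ZScoreTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "RecoveryScores",
    "generate_planted_zscores",
    "generate_planted_dataset",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-community z-score generator.

    Defaults describe a clearly recoverable three-community instance whose
    bulk negative statistics sit on the scale of real treatment columns
    (bulk mean about -1, sd below 1) and whose heavy-tail component produces
    occasional extreme negatives an order of magnitude below the bulk.
    """

    n_kinases: int = 60
    community_sizes: tuple[int, ...] = (20, 20, 20)
    p_within: float = 0.6
    p_between: float = 0.1
    mu_within: float = -1.5
    mu_between: float = -0.2
    sigma_within: float = 0.5
    sigma_between: float = 0.2
    heavy_tail_fraction: float = 0.05
    mu_tail: float = -8.0
    sigma_tail: float = 3.0
    positive_noise_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.community_sizes) != self.n_kinases:
            raise ValidationError("community_sizes must sum to n_kinases")
        if any(s <= 0 for s in self.community_sizes):
            raise ValidationError("community sizes must be positive")
        for name in ("p_within", "p_between", "heavy_tail_fraction", "positive_noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_within", "sigma_between", "sigma_tail"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("mu_within", "mu_between", "mu_tail"):
            if not getattr(self, name) < 0:
                raise ValidationError(f"{name} must be negative")
        if not (self.p_within > self.p_between or abs(self.mu_within) > abs(self.mu_between)):
            warnings.warn(
                "neither edge probability nor edge-weight contrast favours "
                "within-community pairs; the planted structure is unrecoverable",
                stacklevel=2,
            )


@dataclass
class GroundTruth:
    """Planted partition plus the designated pathway community.

    ``target`` is the first member of the pathway community (the stand-in
    for the inhibitor's main target) and ``anchors`` its first members (up
    to three), mimicking canonical pathway anchors.
    """

    partition: Partition
    pathway_community: int
    target: str
    anchors: list[str]

    @property
    def pathway_members(self) -> frozenset[str]:
        return self.partition.communities[self.pathway_community]

    def restrict_to(self, nodes: Sequence[str] | set[str]) -> "GroundTruth":
        """Truth over a node subset (a sign-filtered network can drop kinases
        that drew no edge of that sign)."""
        nodes = set(nodes)
        extra = nodes - self.partition.nodes
        if extra:
            raise CoverageError(f"unknown node(s): {sorted(extra)}")
        if self.target not in nodes:
            raise CoverageError("target dropped by restriction")
        part = Partition({v: l for v, l in self.partition.assignment.items() if v in nodes})
        pathway = next(
            i for i, comm in enumerate(part.communities) if self.target in comm
        )
        return GroundTruth(
            partition=part,
            pathway_community=pathway,
            target=self.target,
            anchors=[a for a in self.anchors if a in nodes],
        )


def _kinase_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"KIN{i + 1:0{width}d}" for i in range(n)]


def _draw_negative(rng: np.random.Generator, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Normal draws truncated to be strictly negative by redrawing, so the
    stated means keep their interpretation for the (dominant) negative mass."""
    z = rng.normal(mu, sigma)
    for _ in range(1000):
        bad = z >= 0
        if not bad.any():
            return z
        z[bad] = rng.normal(mu[bad], sigma[bad])
    raise ValidationError("negative truncation failed to converge (means too close to 0?)")


def generate_planted_zscores(
    spec: SyntheticSpec, treatment: str = "synthetic"
) -> tuple[ZScoreTable, GroundTruth]:
    """One-treatment z-score table with planted communities; reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_kinases
    names = _kinase_names(n)
    membership = np.repeat(np.arange(len(spec.community_sizes)), spec.community_sizes)

    iu, ju = np.triu_indices(n, k=1)
    within = membership[iu] == membership[ju]
    p_edge = np.where(within, spec.p_within, spec.p_between)
    has_edge = rng.random(iu.size) < p_edge

    mu = np.where(within, spec.mu_within, spec.mu_between)
    sigma = np.where(within, spec.sigma_within, spec.sigma_between)
    heavy = within & has_edge & (rng.random(iu.size) < spec.heavy_tail_fraction)
    mu = np.where(heavy, spec.mu_tail, mu)
    sigma = np.where(heavy, spec.sigma_tail, sigma)

    z = np.full(iu.size, np.nan)
    if has_edge.any():
        z[has_edge] = _draw_negative(rng, mu[has_edge], sigma[has_edge])
    # small positive z-scores on a fraction of the remaining (absent) pairs
    spare = ~has_edge & (rng.random(iu.size) < spec.positive_noise_fraction)
    z[spare] = np.abs(rng.normal(0.3, 0.2, size=int(spare.sum())))

    keep = ~np.isnan(z)
    pairs = [(names[a], names[b]) for a, b in zip(iu[keep], ju[keep])]
    index = pd.MultiIndex.from_tuples(pairs, names=["kinase_a", "kinase_b"])
    table = ZScoreTable(pd.DataFrame({treatment: z[keep]}, index=index).sort_index())

    truth_partition = Partition.from_labels(names, membership)
    pathway = 0
    members = sorted(truth_partition.communities[pathway])
    truth = GroundTruth(
        partition=truth_partition,
        pathway_community=pathway,
        target=members[0],
        anchors=members[: min(3, len(members))],
    )
    return table, truth


def generate_planted_dataset(
    spec: SyntheticSpec, treatments: Sequence[str] = ("inhibitorA", "inhibitorB")
) -> tuple[ZScoreTable, GroundTruth]:
    """Multi-treatment table: independent draws per treatment over one shared
    planted partition (per-treatment seeds derived from ``spec.seed``)."""
    columns = []
    truth = None
    for k, name in enumerate(treatments):
        sub = SyntheticSpec(
            **{
                **{f: getattr(spec, f) for f in spec.__dataclass_fields__},
                "seed": derive_seed(spec.seed, 7, k),
            }
        )
        tab, t = generate_planted_zscores(sub, treatment=name)
        columns.append(tab.data)
        truth = truth or t
    data = pd.concat(columns, axis=1).sort_index()
    assert truth is not None
    return ZScoreTable(data), truth


@dataclass
class RecoveryScores:
    """Partition-recovery scores plus pathway-community precision/recall."""

    ari: float
    nmi: float
    precision: float
    recall: float


def evaluate_recovery(
    found: Partition, truth: GroundTruth, target: str | None = None
) -> RecoveryScores:
    """Score a detected partition against the planted truth.

    Precision/recall compare the found community containing ``target``
    (default: the planted target) with the planted pathway community.
    """
    if found.nodes != truth.partition.nodes:
        raise CoverageError("found partition is not over the planted node set")
    sim = compare_partitions(found, truth.partition)
    target = target or truth.target
    found_comm = found.community_of(target)
    planted = truth.pathway_members
    overlap = len(found_comm & planted)
    return RecoveryScores(
        ari=sim.ari,
        nmi=sim.nmi,
        precision=overlap / len(found_comm),
        recall=overlap / len(planted),
    )
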