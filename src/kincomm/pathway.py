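"""Pathway-candidate analysis on top of consensus communities.

The analysis mirrors how a perturbation experiment is read: for each
inhibitor-treatment network, select the community containing the inhibitor's
main target; intersect the selected communities across treatments targeting
the same pathway; keep only candidates with a direct edge to every anchor
kinase (the canonical pathway members) in a designated network; and rank the
survivors by community strength (CS), the sum of a node's edge weights to
co-members of its community.  A high CS in every selected community marks a
kinase whose interactions are strongly inhibited by all treatments — a
likely pathway member.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .community import NullModel, Partition, modularity
from .consensus import consensus_partition, derive_seed
from .exceptions import ConfigError, CoverageError, KincommError, PipelineError, ValidationError
from .network import KinaseNetwork, build_network
from .zscore_io import ZScoreTable, merge_aliases

__all__ = [
    "CommunityReport",
    "IntersectionReport",
    "PipelineConfig",
    "select_community",
    "community_strength",
    "community_report",
    "intersect_communities",
    "anchor_filter",
    "rank_candidates",
    "run_pipeline",
]


def select_community(partition: Partition, target: str) -> frozenset[str]:
    """The unique community containing the inhibitor's main target."""
    if target not in partition.nodes:
        raise CoverageError(
            f"target {target!r} is not a node of the partitioned network; "
            "if it is an isoform group (e.g. AKT1/2), merge aliases first"
        )
    return partition.community_of(target)


def community_strength(network: KinaseNetwork, community: Iterable[str], member: str) -> float:
    """CS of ``member``: sum of its edge weights to co-members only.

    Edges leaving the community do not contribute, so CS is local to the
    community subgraph.
    """
    community = set(community)
    if member not in community:
        raise ValidationError(f"{member!r} is not in the community")
    missing = community - set(network.nodes)
    if missing:
        raise CoverageError(f"community members outside the network: {sorted(missing)}")
    i = network.index(member)
    others = [network.index(v) for v in community if v != member]
    return float(network.weights[i, others].sum()) if others else 0.0


@dataclass
class CommunityReport:
    """Selected community of one network with per-member CS and CS ranks.

    Ranks are 1..|members| by |CS| descending; ties share the smaller rank.
    (Weights are absolute z-scores, so CS >= 0 and |CS| = CS.)
    """

    network_id: str
    target: str
    members: frozenset[str]
    strength: dict[str, float]
    strength_rank: dict[str, int]


def _competition_ranks(values: Mapping[str, float]) -> dict[str, int]:
    ordered = sorted(values, key=lambda v: (-abs(values[v]), v))
    ranks: dict[str, int] = {}
    for pos, name in enumerate(ordered, start=1):
        prev = ordered[pos - 2] if pos > 1 else None
        if prev is not None and abs(values[name]) == abs(values[prev]):
            ranks[name] = ranks[prev]
        else:
            ranks[name] = pos
    return ranks


def community_report(
    network: KinaseNetwork, partition: Partition, target: str
) -> CommunityReport:
    members = select_community(partition, target)
    strength = {v: community_strength(network, members, v) for v in sorted(members)}
    return CommunityReport(
        network_id=f"{network.treatment}:{network.sign}",
        target=target,
        members=members,
        strength=strength,
        strength_rank=_competition_ranks(strength),
    )


@dataclass
class IntersectionReport:
    shared: frozenset[str]
    only_first: frozenset[str]
    only_second: frozenset[str]


def intersect_communities(first: Iterable[str], second: Iterable[str]) -> IntersectionReport:
    first, second = set(first), set(second)
    return IntersectionReport(
        shared=frozenset(first & second),
        only_first=frozenset(first - second),
        only_second=frozenset(second - first),
    )


def anchor_filter(
    network: KinaseNetwork, community: Iterable[str], anchors: Iterable[str]
) -> frozenset[str]:
    """Community members (anchors excluded) with a direct positive-weight
    edge to every anchor in the full network.

    Anchor adjacency is looked up in the whole treatment network, not the
    community subgraph; the community only scopes the candidate list.
    """
    anchors = set(anchors)
    missing = anchors - set(network.nodes)
    if missing:
        raise CoverageError(f"anchor(s) missing from network: {sorted(missing)}")
    anchor_idx = [network.index(a) for a in anchors]
    survivors = set()
    for member in set(community) - anchors:
        if member not in network.nodes:
            continue
        i = network.index(member)
        if all(network.weights[i, j] > 0 for j in anchor_idx):
            survivors.add(member)
    return frozenset(survivors)


def rank_candidates(
    reports: Sequence[CommunityReport], candidates: Iterable[str]
) -> list[dict]:
    """Joint candidate ordering across community reports.

    Each row carries the candidate's CS and CS rank in every report.  Rows
    are sorted by the candidate's best (minimum) rank across reports, ties
    broken by mean CS descending, then by name.
    """
    candidates = sorted(set(candidates))
    for report in reports:
        missing = set(candidates) - report.members
        if missing:
            raise CoverageError(
                f"candidate(s) absent from report {report.network_id}: {sorted(missing)}"
            )
    rows = []
    for name in candidates:
        cs = {r.network_id: r.strength[name] for r in reports}
        ranks = {r.network_id: r.strength_rank[name] for r in reports}
        rows.append(
            {
                "candidate": name,
                "strength": cs,
                "rank": ranks,
                "min_rank": min(ranks.values()),
                "mean_strength": float(np.mean(list(cs.values()))),
            }
        )
    rows.sort(key=lambda r: (r["min_rank"], -r["mean_strength"], r["candidate"]))
    return rows


@dataclass
class PipelineConfig:
    """Configuration of the full analysis.

    ``treatments`` maps each treatment name to the inhibitor's main target
    kinase (after alias merging).  ``anchor_network`` names the treatment
    whose network the anchor filter consults; by default the last treatment
    listed.  ``excluded_known_members`` are kinases flagged as already-known
    pathway members: they are removed from the candidate ranking but still
    reported among the anchor-filter survivors.
    """

    treatments: dict[str, str]
    sign: str = "negative"
    null: str = "uniform"
    gamma: float = 1.0
    ensemble: int = 100
    seed: int = 0
    max_iterations: int = 20
    aliases: dict[str, str] = field(default_factory=dict)
    anchors: list[str] = field(default_factory=list)
    anchor_network: str | None = None
    excluded_known_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ConfigError("config must name at least one treatment")
        for name, target in self.treatments.items():
            if not target:
                raise ConfigError(f"treatment {name!r} has no target kinase")
        if self.anchor_network is None:
            self.anchor_network = list(self.treatments)[-1]
        if self.anchor_network not in self.treatments:
            raise ConfigError(f"anchor_network {self.anchor_network!r} not among treatments")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "treatments" not in cfg:
            raise ConfigError("config must contain 'treatments'")
        return cls(**{k: copy.deepcopy(v) for k, v in cfg.items()})

    def as_dict(self) -> dict:
        return {
            "treatments": dict(self.treatments),
            "sign": self.sign,
            "null": self.null,
            "gamma": self.gamma,
            "ensemble": self.ensemble,
            "seed": self.seed,
            "max_iterations": self.max_iterations,
            "aliases": dict(self.aliases),
            "anchors": list(self.anchors),
            "anchor_network": self.anchor_network,
            "excluded_known_members": list(self.excluded_known_members),
        }


def run_pipeline(table: ZScoreTable, config: PipelineConfig | Mapping) -> dict:
    """Full analysis: networks -> consensus communities -> selection ->
    intersection -> anchor filter -> CS ranking.

    Deterministic given config + seed; returns a JSON-serialisable report
    with stable content (serialise with ``sort_keys=True`` for byte-identical
    replays).  Stage failures are wrapped in :class:`PipelineError` with the
    stage name.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    report: dict = {"config": config.as_dict(), "treatments": {}}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except KincommError as exc:
            raise PipelineError(name, exc) from exc

    if config.aliases:
        table = stage("merge_aliases", merge_aliases, table, config.aliases)
    null = NullModel(kind=config.null, resolution=config.gamma)

    networks: dict[str, KinaseNetwork] = {}
    reports: dict[str, CommunityReport] = {}
    for t_index, (treatment, target) in enumerate(config.treatments.items()):
        net = stage("build_network", build_network, table, treatment, config.sign)
        networks[treatment] = net
        run_seed = derive_seed(config.seed, 1 + t_index)
        result = stage(
            "consensus",
            consensus_partition,
            net,
            null,
            ensemble_size=config.ensemble,
            seed=run_seed,
            max_iterations=config.max_iterations,
        )
        rep = stage("select_community", community_report, net, result.partition, target)
        reports[treatment] = rep
        report["treatments"][treatment] = {
            "target": target,
            "n_nodes": net.n,
            "n_edges": net.n_edges(),
            "consensus_seed": run_seed,
            "consensus_iterations": result.iterations,
            "n_communities": len(result.partition.communities),
            "modularity": modularity(net, result.partition, null),
            "community": sorted(rep.members),
            "community_strength": rep.strength,
            "strength_rank": rep.strength_rank,
        }

    names = list(config.treatments)
    if len(names) >= 2:
        shared = set(reports[names[0]].members)
        for t in names[1:]:
            shared &= reports[t].members
        inter = intersect_communities(reports[names[0]].members, reports[names[1]].members)
        report["intersection"] = {
            "treatments": names[:2],
            "shared": sorted(inter.shared),
            "only_first": sorted(inter.only_first),
            "only_second": sorted(inter.only_second),
        }
        candidates = shared
    else:
        candidates = set(reports[names[0]].members)

    if config.anchors:
        anchor_net = networks[config.anchor_network]
        survivors = stage("anchor_filter", anchor_filter, anchor_net, candidates, config.anchors)
    else:
        survivors = frozenset(candidates)
    ranked_pool = sorted(survivors - set(config.excluded_known_members) - set(config.anchors))
    ranking = stage("rank_candidates", rank_candidates, list(reports.values()), ranked_pool)
    report["anchor_filter"] = {
        "anchors": sorted(config.anchors),
        "network": config.anchor_network,
        "survivors": sorted(survivors),
        "excluded_known_members": sorted(
            set(config.excluded_known_members) & set(survivors)
        ),
    }
    report["ranking"] = ranking
    return report
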