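"""Bipartite virus-host interaction networks from spacer-protospacer matches.

A link is one (host MAG, viral node) pair; its weight is the number of
distinct spacers of that MAG matching that viral node. Viral scaffolds
binned into a vMAG are aggregated to one node, and a spacer hitting
several member scaffolds of one vMAG counts once. "Hyper-targeted"
elements are those hit at least 20 times by a single host's spacer
complement; cross-phylum calls require every supporting host to carry its
array on a scaffold of at least 10 kb and have at most 5.00% contamination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .arrays import SpacerSet
from .matching import MatchParams, MatchTable, match_all
from .seqio import ScaffoldRecord

logger = logging.getLogger(__name__)

HYPER_TARGET_THRESHOLD = 20
CROSS_PHYLUM_MIN_SCAFFOLD_LEN = 10_000
CROSS_PHYLUM_MAX_CONTAMINATION = 5.00


@dataclass(frozen=True)
class MagMetadata:
    mag_id: str
    phylum: str
    completeness: float
    contamination: float
    #: lengths of the array-bearing scaffolds of this MAG
    crispr_scaffold_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.contamination <= 100:
            raise ValueError("contamination must be a percentage in [0, 100]")


@dataclass
class VirusHostNetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def host_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "host")

    @property
    def viral_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "virus")

    @property
    def unique_link_count(self) -> int:
        return self.graph.number_of_edges()

    def links(self) -> list[tuple[str, str, int]]:
        """(host, virus, n_spacer_matches) per distinct pair."""
        return sorted(
            (h, v, d["n_spacer_matches"])
            for h, v, d in self.graph.edges(data=True)
        )

    def summary(self) -> tuple[int, int, int]:
        """(n host MAGs, n viral nodes, unique links)."""
        return len(self.host_nodes), len(self.viral_nodes), self.unique_link_count


@dataclass(frozen=True)
class CrossPhylumCall:
    virus: str
    phyla: tuple[str, ...]
    supporting_hosts: tuple[str, ...]


def build_network(matches: MatchTable, spacer_to_mag: dict[str, str],
                  virus_to_vmag: dict[str, str] | None = None) -> VirusHostNetwork:
    """Aggregate a match table into a bipartite host-virus network.

    ``virus_to_vmag`` maps member scaffold ids to their vMAG node; scaffolds
    absent from the map stand as their own viral node. Spacers lacking a MAG
    assignment are an error (they cannot be attributed to a host).
    """
    virus_to_vmag = virus_to_vmag or {}
    missing = sorted({m.spacer_id for m in matches.matches} - set(spacer_to_mag))
    if missing:
        raise ValueError(f"spacers with no MAG assignment: {missing}")

    per_link_spacers: dict[tuple[str, str], set[str]] = {}
    for m in matches.matches:
        host = spacer_to_mag[m.spacer_id]
        viral_node = virus_to_vmag.get(m.target_id, m.target_id)
        per_link_spacers.setdefault((host, viral_node), set()).add(m.spacer_id)

    net = VirusHostNetwork()
    for (host, virus), spacer_ids in sorted(per_link_spacers.items()):
        net.graph.add_node(host, kind="host")
        net.graph.add_node(virus, kind="virus")
        net.graph.add_edge(host, virus, n_spacer_matches=len(spacer_ids))
    return net


def flag_hyper_targeted(network: VirusHostNetwork,
                        threshold: int = HYPER_TARGET_THRESHOLD
                        ) -> list[tuple[str, str, int]]:
    """Links where one MAG's spacer complement hits one viral node at least
    ``threshold`` times, in descending order of hit count."""
    hits = [(h, v, n) for h, v, n in network.links() if n >= threshold]
    hits.sort(key=lambda x: (-x[2], x[0], x[1]))
    return hits


def curate_cross_phylum(network: VirusHostNetwork,
                        mag_metadata: dict[str, MagMetadata],
                        min_scaffold_len: int = CROSS_PHYLUM_MIN_SCAFFOLD_LEN,
                        max_contamination: float = CROSS_PHYLUM_MAX_CONTAMINATION
                        ) -> list[CrossPhylumCall]:
    """Viral nodes whose qualified hosts span >= 2 distinct phyla.

    A host supports a call only if all its array-bearing scaffolds used for
    linking are at least ``min_scaffold_len`` bp and its CheckM-style
    contamination is at most ``max_contamination`` percent. Hosts without a
    phylum label are excluded with a warning.
    """
    calls: list[CrossPhylumCall] = []
    for virus in network.viral_nodes:
        supporting: list[str] = []
        phyla: set[str] = set()
        for host in network.graph.neighbors(virus):
            meta = mag_metadata.get(host)
            if meta is None or not meta.phylum:
                logger.warning("host %s lacks a phylum label; excluded from "
                               "cross-phylum curation of %s", host, virus)
                continue
            if meta.contamination > max_contamination:
                continue
            if meta.crispr_scaffold_lengths and min(meta.crispr_scaffold_lengths) < min_scaffold_len:
                continue
            supporting.append(host)
            phyla.add(meta.phylum)
        if len(phyla) >= 2:
            calls.append(CrossPhylumCall(
                virus=virus,
                phyla=tuple(sorted(phyla)),
                supporting_hosts=tuple(sorted(supporting)),
            ))
    return calls


@dataclass(frozen=True)
class TargetingCell:
    source: str
    target: str
    matched_spacer_count: int
    spacer_total: int

    @property
    def percent(self) -> float:
        return round(100 * self.matched_spacer_count / self.spacer_total, 1)


@dataclass
class TargetingMatrix:
    cells: list[TargetingCell] = field(default_factory=list)

    def cell(self, source: str, target: str) -> TargetingCell:
        for c in self.cells:
            if c.source == source and c.target == target:
                return c
        raise KeyError((source, target))


def cross_site_matrix(spacer_sets: dict[str, "SpacerSet"],
                      viral_sets: dict[str, list["ScaffoldRecord"]],
                      params: MatchParams | None = None) -> TargetingMatrix:
    """Within/across-site targeting: for each ordered (source site, target
    site) pair, the count of source spacers with at least one retained
    protospacer match into the target site's viral elements, and that count
    as a percent of the source spacer complement (1 decimal)."""
    params = params or MatchParams()
    matrix = TargetingMatrix()
    for source, spacers in spacer_sets.items():
        for target, viruses in viral_sets.items():
            table = match_all(spacers, viruses, params, viral_element_mode=True)
            matched = len({m.spacer_id for m in table.matches})
            matrix.cells.append(TargetingCell(
                source=source,
                target=target,
                matched_spacer_count=matched,
                spacer_total=spacers.size,
            ))
    return matrix
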