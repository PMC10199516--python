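"""Gene cluster family (GCF) construction from domain-content distances.

BGCs are compared by their protein-domain content with an equally weighted
combination of a set-level Jaccard index and an order-sensitive adjacency
index over consecutive domain pairs; pairs closer than the cutoff
(default c = 0.3) are edges of an undirected similarity network, and GCFs
are its connected components. A family containing at least one reference
(MIBiG-like) record is "known".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx

from .records import BgcRecord, check_unique_ids

logger = logging.getLogger(__name__)

GCF_CUTOFF = 0.3


def domain_jaccard(a: BgcRecord, b: BgcRecord) -> float:
    """Jaccard index of the two domain sets; 1.0 when both are empty."""
    sa, sb = set(a.domains), set(b.domains)
    if not sa and not sb:
        return 1.0
    union = sa | sb
    return len(sa & sb) / len(union)


def _adjacent_pairs(domains: Sequence[str]) -> set[frozenset[str] | tuple[str, str]]:
    # unordered adjacent pairs; a self-adjacency (x, x) is kept as a 1-element frozenset
    return {frozenset(p) for p in zip(domains, domains[1:])}


def adjacency_index(a: BgcRecord, b: BgcRecord) -> float:
    """Jaccard index over unordered adjacent domain pairs of the ordered lists.

    Falls back to ``domain_jaccard`` when either record has fewer than two
    domains (no adjacency information available).
    """
    if len(a.domains) < 2 or len(b.domains) < 2:
        return domain_jaccard(a, b)
    pa, pb = _adjacent_pairs(a.domains), _adjacent_pairs(b.domains)
    return len(pa & pb) / len(pa | pb)


def bgc_distance(a: BgcRecord, b: BgcRecord) -> float:
    """Distance in [0, 1]: 1 - (0.5 * Jaccard + 0.5 * adjacency index).

    Symmetric, and 0 exactly for identical ordered domain lists. Two
    empty-domain BGCs are at distance 0; an empty against a non-empty is 1.
    """
    return 1.0 - 0.5 * (domain_jaccard(a, b) + adjacency_index(a, b))


def build_gcf_network(
    bgcs: Sequence[BgcRecord], cutoff: float = GCF_CUTOFF
) -> list[tuple[str, str, float]]:
    """All-pairs similarity network: an edge (i, j, d) iff d = distance < cutoff.

    The strict inequality makes the cutoff an exclusive boundary, so
    ``cutoff = 0`` yields no edges.
    """
    check_unique_ids(bgcs)
    n_empty = sum(1 for b in bgcs if not b.domains)
    if n_empty:
        logger.warning("%d BGCs have empty domain lists", n_empty)
    edges: list[tuple[str, str, float]] = []
    n_pairs = 0
    for a, b in combinations(bgcs, 2):
        n_pairs += 1
        d = bgc_distance(a, b)
        if d < cutoff:
            edges.append((a.bgc_id, b.bgc_id, d))
    logger.info("evaluated %d BGC pairs, %d edges at cutoff %g", n_pairs, len(edges), cutoff)
    return edges


@dataclass
class GeneClusterFamily:
    """A connected component of the BGC similarity network."""

    gcf_id: str
    member_bgc_ids: tuple[str, ...]
    is_known: bool
    habitat_set: frozenset[str]
    class_composition: dict[str, int]

    def __post_init__(self) -> None:
        if not self.member_bgc_ids:
            raise ValueError(f"GCF {self.gcf_id} has no members")


def assign_gcfs(
    bgcs: Sequence[BgcRecord],
    edges: Sequence[tuple[str, str, float]],
    mag_habitats: Mapping[str, str] | None = None,
) -> list[GeneClusterFamily]:
    """Extract families as connected components (singletons included).

    The family id is the smallest member bgc_id, which makes assignment
    deterministic. ``mag_habitats`` maps MAG ids to habitats; reference BGCs
    contribute no habitat. A family is known iff it contains a reference
    member.
    """
    by_id = {b.bgc_id: b for b in bgcs}
    check_unique_ids(bgcs)
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for src, dst, _ in edges:
        if src not in by_id or dst not in by_id:
            raise ValueError(f"edge ({src}, {dst}) references an unknown bgc_id")
        graph.add_edge(src, dst)

    families: list[GeneClusterFamily] = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        records = [by_id[m] for m in members]
        habitats = set()
        for r in records:
            if r.is_reference:
                continue
            if mag_habitats is not None and r.mag_id in mag_habitats:
                habitats.add(mag_habitats[r.mag_id])
        comp: dict[str, int] = {}
        for r in records:
            comp[r.bgc_class] = comp.get(r.bgc_class, 0) + 1
        families.append(
            GeneClusterFamily(
                gcf_id=members[0],
                member_bgc_ids=members,
                is_known=any(r.is_reference for r in records),
                habitat_set=frozenset(habitats),
                class_composition=comp,
            )
        )
    families.sort(key=lambda f: f.gcf_id)
    return families


def cluster_bgcs(
    bgcs: Sequence[BgcRecord],
    cutoff: float = GCF_CUTOFF,
    mag_habitats: Mapping[str, str] | None = None,
    per_class: bool = False,
) -> list[GeneClusterFamily]:
    """Network construction + component extraction in one call.

    ``per_class`` restricts edges to pairs of the same BGC class (BiG-SCAPE's
    per-class mode); the default is a single global network.
    """
    edges = build_gcf_network(bgcs, cutoff)
    if per_class:
        by_id = {b.bgc_id: b for b in bgcs}
        edges = [
            e for e in edges if by_id[e[0]].bgc_class == by_id[e[1]].bgc_class
        ]
    return assign_gcfs(bgcs, edges, mag_habitats)
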