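"""Enumeration of pairwise, triplet and quadruplet residue interactions.

An order-k interaction (k = 2, 3, 4) is a k-clique of the contact graph:
every member pair lies within the distance window — the mutual-contact
criterion, mirroring the sphere-packing fact that at most four equal spheres
can touch mutually in three dimensions (which is why order 5 and beyond is
never considered).

Cliques are enumerated by ordered vertex extension: vertices are ranked by
the canonical site order (chain id, then sequence index); each edge is
extended only by common neighbors of higher rank, so every clique is emitted
exactly once and output is lexicographically sorted by member keys — byte
stable across runs.  At a 7 Å cutoff contact graphs are sparse, so this is
near edge-linear in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .contact import INTER_CHAIN, INTRA_CHAIN, ContactGraph
from .structure_io import Site

ResidueKey = tuple[str, int, Optional[str]]


@dataclass(frozen=True)
class Interaction:
    """An order-k mutual-contact interaction.

    ``members`` are in canonical order (chain id, then seq_index);
    ``distances`` maps member-position pairs (a, b), a < b, to Å.
    """

    order: int
    members: tuple[Site, ...]
    distances: Mapping[tuple[int, int], float]
    span: str  # "intra-chain" | "inter-chain"

    def __post_init__(self) -> None:
        k = self.order
        assert len(self.members) == k and len(self.distances) == k * (k - 1) // 2

    @property
    def member_keys(self) -> tuple[ResidueKey, ...]:
        return tuple(s.residue_key for s in self.members)

    def distance(self, a: int, b: int) -> float:
        return self.distances[(a, b) if a < b else (b, a)]

    def distances_by_keys(self) -> dict[frozenset, float]:
        """Distances keyed by unordered residue-key pairs (for comparisons)."""
        return {
            frozenset((self.members[a].residue_key, self.members[b].residue_key)): d
            for (a, b), d in self.distances.items()
        }

    def contains_key(self, key: ResidueKey) -> bool:
        return key in self.member_keys


def make_interaction(
    members: Sequence[Site],
    pair_distance: Callable[[Site, Site], float],
) -> Interaction:
    """Build a canonical Interaction from member sites and a distance source."""
    ordered = tuple(sorted(members, key=lambda s: s.canonical_key()))
    distances = {
        (a, b): pair_distance(ordered[a], ordered[b])
        for a, b in combinations(range(len(ordered)), 2)
    }
    chains = {s.chain_id for s in ordered}
    return Interaction(
        order=len(ordered),
        members=ordered,
        distances=distances,
        span=INTER_CHAIN if len(chains) > 1 else INTRA_CHAIN,
    )


def _ranked(graph: ContactGraph):
    """Rank vertices canonically; return (rank->site index, adjacency in rank space)."""
    order = graph.canonical_order()
    rank_of = {site_idx: r for r, site_idx in enumerate(order)}
    adj = [frozenset(rank_of[j] for j in graph.neighbors(i)) for i in order]
    return order, adj


def _interaction_from_ranks(
    graph: ContactGraph, order: list[int], ranks: tuple[int, ...]
) -> Interaction:
    idxs = [order[r] for r in ranks]
    members = tuple(graph.sites[i] for i in idxs)  # rank order IS canonical order
    distances = {
        (a, b): graph.distance(idxs[a], idxs[b])
        for a, b in combinations(range(len(idxs)), 2)
    }
    chains = {s.chain_id for s in members}
    return Interaction(
        order=len(members),
        members=members,
        distances=distances,
        span=INTER_CHAIN if len(chains) > 1 else INTRA_CHAIN,
    )


def enumerate_pairs(graph: ContactGraph) -> list[Interaction]:
    """All order-2 interactions — one per contact edge, canonically sorted."""
    order, adj = _ranked(graph)
    out = []
    for i in range(len(order)):
        for j in sorted(r for r in adj[i] if r > i):
            out.append(_interaction_from_ranks(graph, order, (i, j)))
    return out


def enumerate_triplets(graph: ContactGraph) -> list[Interaction]:
    """All order-3 interactions — the triangles of the contact graph."""
    order, adj = _ranked(graph)
    out = []
    for i in range(len(order)):
        for j in sorted(r for r in adj[i] if r > i):
            for k in sorted(r for r in adj[i] & adj[j] if r > j):
                out.append(_interaction_from_ranks(graph, order, (i, j, k)))
    return out


def enumerate_quadruplets(graph: ContactGraph) -> list[Interaction]:
    """All order-4 interactions — the 4-cliques of the contact graph."""
    order, adj = _ranked(graph)
    out = []
    for i in range(len(order)):
        for j in sorted(r for r in adj[i] if r > i):
            common_ij = adj[i] & adj[j]
            for k in sorted(r for r in common_ij if r > j):
                for l in sorted(r for r in common_ij & adj[k] if r > k):
                    out.append(_interaction_from_ranks(graph, order, (i, j, k, l)))
    return out


_ENUMERATORS = {2: enumerate_pairs, 3: enumerate_triplets, 4: enumerate_quadruplets}


def enumerate_interactions(
    graph: ContactGraph, orders: Iterable[int] = (2, 3, 4)
) -> dict[int, list[Interaction]]:
    """Enumerate the requested orders; keys are the orders asked for."""
    result = {}
    for k in orders:
        if k not in _ENUMERATORS:
            raise ValueError(f"interaction order must be 2, 3 or 4, got {k}")
        result[k] = _ENUMERATORS[k](graph)
    return result
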