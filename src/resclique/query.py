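"""Anchored and residue-type interaction queries.

Two query styles mirror how structural biologists interrogate a site of
interest rather than the whole structure:

* anchored — all order-k interactions that contain *all* of 1–4 given
  residues (e.g. two catalytic-triad residues, order 3, to shortlist a third
  interacting residue);
* typed — all order-k interactions containing at least one (``any_member``)
  or only (``all_members``) residues of given amino-acid types (e.g. the
  quadruplets mediated by cysteines).

Anchored queries run a neighborhood-restricted search (candidates are the
common contact neighbors of the anchors) with a hard contract of equality to
filtering the full enumeration; typed queries filter the full enumeration
directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence, Union

from .cliques import Interaction, enumerate_interactions, make_interaction
from .contact import ContactGraph
from .errors import AnchorError, AnchorNotFoundError, InvalidResidueTypeError
from .structure_io import STANDARD_AA

ResidueKey = tuple[str, int, Optional[str]]
#: an anchor may omit the chain (None) when the selection has a single chain
AnchorKey = tuple[Optional[str], int, Optional[str]]


@dataclass(frozen=True)
class AnchorSpec:
    """1–4 distinct anchor residues that must all appear in each result."""

    anchors: tuple[AnchorKey, ...]
    order: int

    def __post_init__(self) -> None:
        if self.order not in (2, 3, 4):
            raise AnchorError(f"order must be 2, 3 or 4, got {self.order}")
        if not 1 <= len(self.anchors) <= self.order:
            raise AnchorError(
                f"{len(self.anchors)} anchors exceed order {self.order}"
                if len(self.anchors) > self.order
                else "at least one anchor required"
            )
        if len(set(self.anchors)) != len(self.anchors):
            raise AnchorError("anchor keys must be distinct")


@dataclass(frozen=True)
class TypeSpec:
    """Amino-acid types of interest plus membership semantics."""

    aa_types: frozenset[str]
    order: int
    mode: str = "any_member"  # "any_member" | "all_members"

    def __post_init__(self) -> None:
        object.__setattr__(self, "aa_types", frozenset(self.aa_types))
        if not self.aa_types:
            raise InvalidResidueTypeError("aa_types must be non-empty")
        bad = self.aa_types - STANDARD_AA
        if bad:
            raise InvalidResidueTypeError(
                f"unknown amino-acid code(s) {sorted(bad)}; "
                f"valid codes: {sorted(STANDARD_AA)}"
            )
        if self.order not in (2, 3, 4):
            raise InvalidResidueTypeError(f"order must be 2, 3 or 4, got {self.order}")
        if self.mode not in ("any_member", "all_members"):
            raise InvalidResidueTypeError(f"unknown mode {self.mode!r}")


def _resolve_anchor(graph: ContactGraph, anchor: AnchorKey) -> int:
    chain, number, icode = anchor
    if chain is None:
        chains = {s.chain_id for s in graph.sites}
        if len(chains) > 1:
            raise AnchorError(
                f"anchor residue {number}{icode or ''} is ambiguous: selection has "
                f"chains {sorted(chains)}; specify CHAIN:RESNUM"
            )
        chain = next(iter(chains))
    key = (chain, number, icode)
    for idx, site in enumerate(graph.sites):
        if site.residue_key == key:
            return idx
    raise AnchorNotFoundError(f"anchor not found: {chain}:{number}{icode or ''}")


def interactions_around(graph: ContactGraph, spec: AnchorSpec) -> list[Interaction]:
    """Order-k interactions whose member set contains every anchor.

    Candidates for the remaining k − a slots are restricted to the common
    contact neighbors of all anchors; the anchors themselves must also be
    mutually in contact.  Equivalent to filtering the full enumeration.
    """
    anchor_idx = [_resolve_anchor(graph, a) for a in spec.anchors]
    if len(set(anchor_idx)) != len(anchor_idx):
        raise AnchorError("anchor keys must be distinct")

    # anchors themselves must form a clique, else nothing can contain them all
    for i, j in combinations(anchor_idx, 2):
        if (min(i, j), max(i, j)) not in graph.edges:
            return []

    n_extra = spec.order - len(anchor_idx)
    if n_extra == 0:
        candidates: list[int] = []
    else:
        common = set.intersection(*(graph.neighbors(i) for i in anchor_idx))
        candidates = sorted(common - set(anchor_idx))

    out = []
    for extra in combinations(candidates, n_extra):
        ok = all(
            (min(i, j), max(i, j)) in graph.edges for i, j in combinations(extra, 2)
        )
        if not ok:
            continue
        idxs = anchor_idx + list(extra)
        idx_of = {id(graph.sites[i]): i for i in idxs}
        out.append(
            make_interaction(
                [graph.sites[i] for i in idxs],
                lambda a, b: graph.distance(idx_of[id(a)], idx_of[id(b)]),
            )
        )
    out.sort(key=lambda it: tuple(s.canonical_key() for s in it.members))
    return out


def interactions_by_type(graph: ContactGraph, spec: TypeSpec) -> list[Interaction]:
    """Order-k interactions selected by member amino-acid type."""
    full = enumerate_interactions(graph, orders=(spec.order,))[spec.order]
    if spec.mode == "any_member":
        pred = lambda it: any(s.aa_type in spec.aa_types for s in it.members)
    else:
        pred = lambda it: all(s.aa_type in spec.aa_types for s in it.members)
    return [it for it in full if pred(it)]


def parse_anchor(text: str) -> AnchorKey:
    """Parse ``CHAIN:RESNUM[:ICODE]`` or a bare residue number.

    Bare numbers resolve only against single-chain selections.
    """
    parts = text.split(":")
    try:
        if len(parts) == 1:
            return (None, int(parts[0]), None)
        if len(parts) == 2:
            return (parts[0], int(parts[1]), None)
        if len(parts) == 3:
            return (parts[0], int(parts[1]), parts[2] or None)
    except ValueError:
        pass
    raise AnchorError(f"cannot parse anchor {text!r}; expected CHAIN:RESNUM[:ICODE]")
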