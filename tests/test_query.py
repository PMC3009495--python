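"""Anchored (lite) and residue-type (cluster) queries vs filtered enumeration."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

import resclique as rc
from resclique.cliques import enumerate_interactions
from resclique.contact import DistanceWindow, build_contact_graph
from resclique.errors import AnchorError, AnchorNotFoundError, InvalidResidueTypeError
from resclique.query import (
    AnchorSpec,
    TypeSpec,
    interactions_around,
    interactions_by_type,
    parse_anchor,
)

from conftest import assert_same_interactions, keyset


@pytest.fixture(scope="module")
def typed_graph():
    """30-residue packing with a CYS/HIS/SER-sprinkled sequence, CB sites."""
    seq = (["ALA", "CYS", "GLY", "SER"] * 8)[:30]
    s = rc.generate_random_packing(30, seed=23, box_edge=22.0, aa_sequence=seq)
    sites = rc.select_sites(s, rc.SelectionPolicy(atom_type="CB"))
    return build_contact_graph(sites, DistanceWindow(1.0, 7.0))


class TestAnchored:
    def test_tetrahedron_single_anchor_returns_the_quadruplet(self, tetrahedron_graph):
        anchor = tetrahedron_graph.sites[0].residue_key
        spec = AnchorSpec(anchors=(anchor,), order=4)
        result = interactions_around(tetrahedron_graph, spec)
        assert len(result) == 1
        assert result[0].order == 4

    def test_full_anchor_set_checks_clique(self, tetrahedron_graph):
        keys = [s.residue_key for s in tetrahedron_graph.sites]
        spec = AnchorSpec(anchors=tuple(keys), order=4)
        assert len(interactions_around(tetrahedron_graph, spec)) == 1

    @pytest.mark.parametrize("order", [2, 3, 4])
    @pytest.mark.parametrize("n_anchors", [1, 2])
    def test_equals_filtered_enumeration(self, typed_graph, order, n_anchors):
        if n_anchors > order:
            pytest.skip("anchors cannot exceed order")
        full = enumerate_interactions(typed_graph, orders=(order,))[order]
        # try several anchor tuples, including ones with no hits
        site_keys = [s.residue_key for s in typed_graph.sites]
        rng = np.random.default_rng(order * 10 + n_anchors)
        for _ in range(6):
            anchors = tuple(
                site_keys[i]
                for i in rng.choice(len(site_keys), size=n_anchors, replace=False)
            )
            spec = AnchorSpec(anchors=anchors, order=order)
            direct = interactions_around(typed_graph, spec)
            filtered = [
                it for it in full
                if all(it.contains_key(a) for a in anchors)
            ]
            assert_same_interactions(direct, filtered)

    def test_anchored_subset_of_unanchored(self, typed_graph):
        full = enumerate_interactions(typed_graph, orders=(3,))[3]
        a1 = typed_graph.sites[4].residue_key
        a2 = typed_graph.sites[7].residue_key
        one = interactions_around(typed_graph, AnchorSpec((a1,), order=3))
        two = interactions_around(typed_graph, AnchorSpec((a1, a2), order=3))
        assert keyset(one) <= keyset(full)
        assert keyset(two) <= keyset(one)  # adding an anchor never enlarges

    def test_triad_completion_pattern(self, typed_graph):
        """Anchoring two residues at order 3 shortlists candidate third partners."""
        full = enumerate_interactions(typed_graph, orders=(3,))[3]
        pair = next(
            (it.member_keys[:2] for it in full), None
        )
        if pair is None:
            pytest.skip("fixture produced no triplet")
        hits = interactions_around(typed_graph, AnchorSpec(tuple(pair), order=3))
        assert hits  # the generating triplet is found
        for it in hits:
            assert set(pair) <= set(it.member_keys)
            assert len(set(it.member_keys) - set(pair)) == 1

    def test_unknown_anchor_named_in_error(self, tetrahedron_graph):
        with pytest.raises(AnchorNotFoundError, match="anchor not found: A:99"):
            interactions_around(
                tetrahedron_graph, AnchorSpec((("A", 99, None),), order=2)
            )

    def test_too_many_anchors_rejected(self):
        with pytest.raises(AnchorError, match="exceed"):
            AnchorSpec(
                anchors=(("A", 1, None), ("A", 2, None), ("A", 3, None)), order=2
            )

    def test_duplicate_anchors_rejected(self):
        with pytest.raises(AnchorError, match="distinct"):
            AnchorSpec(anchors=(("A", 1, None), ("A", 1, None)), order=3)

    def test_bare_number_anchor_on_single_chain(self, tetrahedron_graph):
        spec = AnchorSpec(anchors=((None, 1, None),), order=4)
        assert len(interactions_around(tetrahedron_graph, spec)) == 1

    def test_parse_anchor_forms(self):
        assert parse_anchor("A:42") == ("A", 42, None)
        assert parse_anchor("B:52:A") == ("B", 52, "A")
        assert parse_anchor("17") == (None, 17, None)
        with pytest.raises(AnchorError):
            parse_anchor("A:x")


class TestTyped:
    def test_absent_type_gives_empty(self, tetrahedron_graph):
        # poly-ALA structure: no cysteine anywhere
        for order in (2, 3, 4):
            spec = TypeSpec(aa_types={"CYS"}, order=order)
            assert interactions_by_type(tetrahedron_graph, spec) == []

    @pytest.mark.parametrize("order", [2, 3, 4])
    @pytest.mark.parametrize("mode", ["any_member", "all_members"])
    def test_equals_filtered_enumeration(self, typed_graph, order, mode):
        spec = TypeSpec(aa_types={"CYS", "SER"}, order=order, mode=mode)
        direct = interactions_by_type(typed_graph, spec)
        full = enumerate_interactions(typed_graph, orders=(order,))[order]
        quantifier = any if mode == "any_member" else all
        filtered = [
            it for it in full
            if quantifier(s.aa_type in spec.aa_types for s in it.members)
        ]
        assert_same_interactions(direct, filtered)

    def test_any_member_results_contain_a_listed_type(self, typed_graph):
        spec = TypeSpec(aa_types={"CYS"}, order=3, mode="any_member")
        for it in interactions_by_type(typed_graph, spec):
            assert any(s.aa_type == "CYS" for s in it.members)

    def test_all_members_subset_of_any_member(self, typed_graph):
        for order in (2, 3):
            any_ = interactions_by_type(
                typed_graph, TypeSpec(aa_types={"ALA", "GLY"}, order=order)
            )
            all_ = interactions_by_type(
                typed_graph,
                TypeSpec(aa_types={"ALA", "GLY"}, order=order, mode="all_members"),
            )
            assert keyset(all_) <= keyset(any_)

    def test_invalid_code_lists_valid_ones(self):
        with pytest.raises(InvalidResidueTypeError, match="XYZ"):
            TypeSpec(aa_types={"XYZ"}, order=2)
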