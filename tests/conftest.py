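"""Shared fixtures: tiny hand-written PDB texts and synthetic structures."""

from __future__ import annotations

import pytest

import resclique as rc

# ALA 1 (CA + CB), GLY 2 (CA only) — the minimal two-residue chain
TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       0.000   0.000   1.530  1.00  0.00           C
ATOM      4  N   GLY A   2       3.000   1.000   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
END
"""

# one CA in two alternate locations: A at x=1 (occ 0.40), B at x=2 (occ 0.60)
ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA  ALA A   2       5.000   0.000   0.000  1.00  0.00           C
TER
END
"""


def two_model_pdb() -> str:
    body = "".join(
        line + "\n"
        for line in TWO_RESIDUE_PDB.splitlines()
        if line.startswith("ATOM")
    )
    return f"MODEL        1\n{body}ENDMDL\nMODEL        2\n{body}ENDMDL\nEND\n"


@pytest.fixture(scope="session")
def two_residue_structure():
    return rc.parse_structure(TWO_RESIDUE_PDB, id="tiny")


@pytest.fixture(scope="session")
def tetrahedron_graph():
    s = rc.generate_polyhedron("tetrahedron", edge=5.0)
    sites = rc.select_sites(s, rc.SelectionPolicy(atom_type="CA"))
    return rc.build_contact_graph(sites, rc.DistanceWindow(1.0, 7.0))


@pytest.fixture(scope="session")
def packing_sites():
    """40-point seeded packing, CA sites — the workhorse random fixture."""
    s = rc.generate_random_packing(40, seed=11, box_edge=26.0, min_separation=3.0)
    return rc.select_sites(s, rc.SelectionPolicy(atom_type="CA"))


def keyset(interactions):
    """Canonical member-key tuples of an interaction list, as a set."""
    return {it.member_keys for it in interactions}


def assert_same_interactions(got, expected, tol=1e-9):
    """Set equality of member keys plus matching pairwise distances."""
    assert keyset(got) == keyset(expected)
    exp_by_key = {it.member_keys: it for it in expected}
    for it in got:
        ref = exp_by_key[it.member_keys]
        assert it.span == ref.span
        d_got, d_ref = it.distances_by_keys(), ref.distances_by_keys()
        assert d_got.keys() == d_ref.keys()
        for pair, d in d_got.items():
            assert abs(d - d_ref[pair]) <= tol
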