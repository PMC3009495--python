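"""Synthetic structures with known geometry, and the brute-force clique oracle.

Everything the engine does can be exercised without touching real coordinate
files: ideal α-helices (closed-form Cα geometry: radius 2.3 Å, rise 1.5 Å
per residue, 100° twist per residue), regular polyhedra (tetrahedron, square)
whose clique structure is known exactly, and seeded random packings with a
minimum pairwise separation — a crude stand-in for the excluded volume of
real side chains.

:func:`brute_force_cliques` restates the mutual-contact definition literally
(test every size-k subset against the window) and is the independent oracle
the enumeration engine is checked against.  It is deliberately exhaustive
and guarded to small n; it never backs the production path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .cliques import Interaction, make_interaction
from .contact import DistanceWindow
from .errors import PackingError, RescliqueError
from .structure_io import Atom, Chain, Model, Residue, Site, Structure

HELIX_RADIUS = 2.3  # Å, canonical α-helix Cα radius
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST_DEG = 100.0  # degrees per residue
CB_BOND = 1.53  # Å, Cα–Cβ bond length

_ORACLE_GUARD = 100  # brute force refuses larger inputs


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of a synthetic structure."""

    kind: str  # "ideal_helix" | "random_packing" | "polyhedron"
    n_residues: int = 10
    seed: int = 0
    box_edge: float = 30.0
    min_separation: float = 3.0
    shape: str = "tetrahedron"
    edge: float = 5.0
    aa_sequence: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise RescliqueError("n_residues must be >= 2")
        if self.kind == "random_packing" and not 0 < self.min_separation < self.box_edge:
            raise RescliqueError("need 0 < min_separation < box_edge")


def generate(spec: SyntheticSpec) -> Structure:
    if spec.kind == "ideal_helix":
        return generate_ideal_helix(spec.n_residues, aa_sequence=spec.aa_sequence)
    if spec.kind == "random_packing":
        return generate_random_packing(
            spec.n_residues,
            seed=spec.seed,
            box_edge=spec.box_edge,
            min_separation=spec.min_separation,
            aa_sequence=spec.aa_sequence,
        )
    if spec.kind == "polyhedron":
        return generate_polyhedron(spec.shape, edge=spec.edge)
    raise RescliqueError(f"unknown synthetic kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# generators


def _sequence(n: int, aa_sequence: Optional[Sequence[str]]) -> list[str]:
    if aa_sequence is None:
        return ["ALA"] * n
    if len(aa_sequence) != n:
        raise RescliqueError(
            f"aa_sequence length {len(aa_sequence)} != n_residues {n}"
        )
    return list(aa_sequence)


def _structure_from_coords(
    ca: np.ndarray,
    cb: Optional[np.ndarray],
    aa_types: Sequence[str],
    structure_id: str,
) -> Structure:
    residues = []
    for i, aa in enumerate(aa_types):
        atoms = [Atom(name="CA", coord=ca[i])]
        if cb is not None and aa != "GLY":  # glycine genuinely lacks CB
            atoms.append(Atom(name="CB", coord=cb[i]))
        residues.append(Residue(number=i + 1, icode=None, aa_type=aa, atoms=atoms))
    return Structure(
        id=structure_id, models=[Model(chains=[Chain(id="A", residues=residues)])]
    ).validate()


def helix_ca_coords(n_residues: int) -> np.ndarray:
    """Cα positions of the canonical α-helix, residue i at twist i·100°."""
    i = np.arange(n_residues)
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


def helix_ca_distance(separation: int) -> float:
    """Closed-form Cα(i)–Cα(i+separation) distance on the ideal helix.

    Chord of the circular projection plus the axial rise:
    sqrt((2R·sin(k·50°))² + (1.5·k)²).
    """
    half_angle = math.radians(HELIX_TWIST_DEG * separation / 2.0)
    chord = 2.0 * HELIX_RADIUS * abs(math.sin(half_angle))
    return math.hypot(chord, HELIX_RISE * separation)


def generate_ideal_helix(
    n_residues: int, aa_sequence: Optional[Sequence[str]] = None
) -> Structure:
    """Ideal α-helix; CB is placed 1.53 Å radially outward from each CA
    (along the local helix normal), so CB-mode selection is exercised too."""
    if n_residues < 2:
        raise RescliqueError("n_residues must be >= 2")
    ca = helix_ca_coords(n_residues)
    radial = ca.copy()
    radial[:, 2] = 0.0
    radial /= np.linalg.norm(radial, axis=1)[:, None]
    cb = ca + CB_BOND * radial
    return _structure_from_coords(
        ca, cb, _sequence(n_residues, aa_sequence), f"helix{n_residues}"
    )


def generate_random_packing(
    n_residues: int,
    seed: int = 0,
    box_edge: float = 30.0,
    min_separation: float = 3.0,
    aa_sequence: Optional[Sequence[str]] = None,
    max_retries: int = 10_000,
) -> Structure:
    """Uniform points in a cube, rejection-sampled to pairwise separation
    >= min_separation; reproducible from the seed.

    Emitted as a single-chain Cα(+Cβ) structure; CB sits at a fixed
    (0, 0, +1.53 Å) offset — geometry, not chemistry, is what matters here.
    """
    spec = SyntheticSpec(
        kind="random_packing",
        n_residues=n_residues,
        seed=seed,
        box_edge=box_edge,
        min_separation=min_separation,
    )
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    for _ in range(n_residues):
        for attempt in range(max_retries):
            p = rng.uniform(0.0, box_edge, size=3)
            if all(np.linalg.norm(p - q) >= min_separation for q in coords):
                coords.append(p)
                break
        else:
            raise PackingError(
                f"could not place point {len(coords) + 1}/{n_residues} after "
                f"{max_retries} retries; try a larger box_edge"
            )
    ca = np.array(coords)
    cb = ca + np.array([0.0, 0.0, CB_BOND])
    return _structure_from_coords(
        ca, cb, _sequence(n_residues, aa_sequence), f"packing{n_residues}s{seed}"
    )


_POLYHEDRA = {
    # unit-edge vertex sets
    "tetrahedron": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    / (2.0 * math.sqrt(2.0)),
    "square": np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float),
    "octahedron": np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    / math.sqrt(2.0),
}


def generate_polyhedron(shape: str, edge: float = 5.0) -> Structure:
    """Vertices of a regular polyhedron as a Cα-only poly-ALA chain."""
    if shape not in _POLYHEDRA:
        raise RescliqueError(
            f"unknown shape {shape!r}; available: {sorted(_POLYHEDRA)}"
        )
    ca = _POLYHEDRA[shape] * edge
    return _structure_from_coords(ca, None, ["ALA"] * len(ca), shape)


# ---------------------------------------------------------------------------
# brute-force oracle


@lru_cache(maxsize=16)
def _combo_index(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def brute_force_cliques(
    sites: Sequence[Site],
    window: DistanceWindow,
    min_seq_sep: int = 1,
    order: int = 2,
) -> list[Interaction]:
    """Exhaustively test every size-``order`` subset of sites (tests only).

    Distances are computed directly from coordinates, independently of the
    contact-graph machinery; canonical member ordering and list ordering
    match the engine, so results are directly comparable.
    """
    n = len(sites)
    if n > _ORACLE_GUARD:
        raise RescliqueError(
            f"brute-force oracle limited to n <= {_ORACLE_GUARD}, got {n}"
        )
    if order not in (2, 3, 4):
        raise RescliqueError(f"order must be 2, 3 or 4, got {order}")

    coords = np.stack([s.coord for s in sites])
    dmat = squareform(pdist(coords))
    eligible = (dmat >= window.d_lo) & (dmat <= window.d_hi)
    np.fill_diagonal(eligible, False)
    for i, j in combinations(range(n), 2):
        a, b = sites[i], sites[j]
        if a.chain_id == b.chain_id and abs(a.seq_index - b.seq_index) < min_seq_sep:
            eligible[i, j] = eligible[j, i] = False

    combos = _combo_index(n, order)
    mask = np.ones(len(combos), dtype=bool)
    for a, b in combinations(range(order), 2):
        mask &= eligible[combos[:, a], combos[:, b]]

    out = []
    for idxs in combos[mask]:
        index_of = {id(sites[int(i)]): int(i) for i in idxs}
        out.append(
            make_interaction(
                [sites[int(i)] for i in idxs],
                lambda x, y, _i=index_of: float(dmat[_i[id(x)], _i[id(y)]]),
            )
        )
    out.sort(key=lambda it: tuple(s.canonical_key() for s in it.members))
    return out
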