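"""PDB coordinate input and per-residue interaction-site selection.

A :class:`Structure` is a lightweight chain/residue/atom model built on top of
Biopython's PDB parser.  From a structure, :func:`select_sites` derives one
:class:`Site` per residue — the representative interaction point (Cα or Cβ)
used for all distance computations downstream — under an explicit
:class:`SelectionPolicy` covering atom type, glycine fallback, NMR model
choice, chain and residue-range restriction, hetero handling and altloc
resolution.

Residue identity is always the *author* numbering (number + insertion code)
as printed in the PDB file; sequential adjacency uses a 0-based ``seq_index``
within each chain.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import (
    ChainNotFoundError,
    EmptySelectionError,
    ModelNotFoundError,
    NoCoordinatesError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: residues never imported from PDB input (solvent)
WATER_NAMES = {"HOH", "WAT", "DOD"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


# ---------------------------------------------------------------------------
# coordinate model


@dataclass
class Atom:
    """One atom record; ``altloc`` is None for the blank alternate location."""

    name: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: Optional[str] = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ParseError(
                f"atom {self.name!r}: coordinate must be a finite 3-vector"
            )


@dataclass
class Residue:
    number: int
    icode: Optional[str]
    aa_type: str
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    def atoms_named(self, name: str) -> list[Atom]:
        return [a for a in self.atoms if a.name == name]

    def key(self, chain_id: str) -> tuple[str, int, Optional[str]]:
        return (chain_id, self.number, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise ChainNotFoundError(
            f"chain {chain_id!r} not found; available chains: "
            f"{[c.id for c in self.chains]}"
        )


@dataclass
class Structure:
    id: str
    models: list[Model] = field(default_factory=list)

    def validate(self) -> "Structure":
        """Check the structural invariants; returns self for chaining."""
        for mi, model in enumerate(self.models):
            seen: set[tuple[str, int, Optional[str]]] = set()
            for chain in model.chains:
                for res in chain.residues:
                    k = res.key(chain.id)
                    if k in seen:
                        raise ParseError(
                            f"duplicate residue key {k} in model {mi}"
                        )
                    seen.add(k)
        return self


# ---------------------------------------------------------------------------
# sites


@dataclass(frozen=True, eq=False)
class Site:
    """A residue's representative interaction point.

    ``residue_key`` is (chain id, author residue number, insertion code or
    None); ``seq_index`` is the residue's 0-based ordinal within its chain and
    drives minimum-sequence-separation filtering; ``source_atom`` records
    whether the coordinate came from CA, CB, or the glycine CA fallback when
    CB was requested.
    """

    residue_key: tuple[str, int, Optional[str]]
    aa_type: str
    seq_index: int
    coord: np.ndarray
    source_atom: str  # "CA" | "CB" | "CA-fallback"

    @property
    def chain_id(self) -> str:
        return self.residue_key[0]

    @property
    def number(self) -> int:
        return self.residue_key[1]

    @property
    def icode(self) -> Optional[str]:
        return self.residue_key[2]

    def canonical_key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_index)

    def label(self) -> str:
        """Human-readable descriptor, e.g. ``A:ALA:42`` or ``A:SER:52:A``."""
        base = f"{self.chain_id}:{self.aa_type}:{self.number}"
        return f"{base}:{self.icode}" if self.icode else base


@dataclass(frozen=True)
class SelectionPolicy:
    """How residues are turned into sites.

    atom_type
        "CA" or "CB"; glycine has no CB, handled by ``gly_policy``.
    gly_policy
        "fallback_to_ca" (default): glycine contributes its CA when CB is
        requested, marked ``source_atom="CA-fallback"``; "skip" drops it.
    model_index
        0-based index into the structure's models (first NMR model default).
    chains / residue_range
        optional restriction to chain ids and an author-number interval
        (inclusive on both ends).
    include_hetero
        include non-water HETATM residues (default off; MSE is already
        remapped to MET at parse time and never counts as hetero).
    """

    atom_type: str = "CB"
    gly_policy: str = "fallback_to_ca"
    model_index: int = 0
    chains: Optional[tuple[str, ...]] = None
    residue_range: Optional[tuple[int, int]] = None
    include_hetero: bool = False
    altloc_rule: str = "highest_occupancy_then_alphabetical"

    def __post_init__(self) -> None:
        if self.atom_type not in ("CA", "CB"):
            raise ValueError(f"atom_type must be 'CA' or 'CB', got {self.atom_type!r}")
        if self.gly_policy not in ("fallback_to_ca", "skip"):
            raise ValueError(f"unknown gly_policy {self.gly_policy!r}")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError(f"residue_range start {lo} > end {hi}")
        if self.chains is not None and not isinstance(self.chains, tuple):
            object.__setattr__(self, "chains", tuple(self.chains))


# ---------------------------------------------------------------------------
# parsing


def parse_structure(pdb_text: Union[str, IO[str]], id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    MODEL/ENDMDL boundaries are honored; waters are dropped; other HETATM
    residues are kept but flagged hetero (MSE is remapped to MET and treated
    as standard); every alternate location is retained — altloc conflicts are
    resolved later, at site-selection time.

    Raises :class:`NoCoordinatesError` for input without ATOM records and
    :class:`ParseError` (naming the offending line) for malformed coordinate
    fields.
    """
    handle = io.StringIO(pdb_text) if isinstance(pdb_text, str) else pdb_text
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_structure = parser.get_structure(id, handle)
    except PDBConstructionException as exc:  # strict mode names the line
        raise ParseError(f"malformed PDB record: {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"malformed PDB record: {exc}") from exc

    models: list[Model] = []
    for bio_model in bio_structure:
        chains: list[Chain] = []
        for bio_chain in bio_model:
            residues: list[Residue] = []
            for bio_res in bio_chain:
                hetfield, resnum, icode = bio_res.id
                resname = bio_res.get_resname().strip()
                if hetfield == "W" or resname in WATER_NAMES:
                    continue
                hetero = hetfield.strip() != ""
                if resname == "MSE":  # selenomethionine -> methionine
                    resname, hetero = "MET", False
                atoms: list[Atom] = []
                for bio_atom in bio_res.get_unpacked_list():
                    altloc = bio_atom.get_altloc().strip() or None
                    occ = bio_atom.get_occupancy()
                    atoms.append(
                        Atom(
                            name=bio_atom.get_name(),
                            coord=np.array(bio_atom.get_coord(), dtype=float),
                            occupancy=1.0 if occ is None else float(occ),
                            altloc=altloc,
                        )
                    )
                residues.append(
                    Residue(
                        number=int(resnum),
                        icode=icode.strip() or None,
                        aa_type=resname,
                        atoms=atoms,
                        hetero=hetero,
                    )
                )
            if residues:
                chains.append(Chain(id=str(bio_chain.id), residues=residues))
        if chains:
            models.append(Model(chains=chains))

    if not models or not any(
        res.atoms for m in models for c in m.chains for res in c.residues
    ):
        raise NoCoordinatesError("no coordinates: input contains no usable ATOM records")
    return Structure(id=id, models=models).validate()


def _resolve_altloc(atoms: Sequence[Atom]) -> Atom:
    """Highest occupancy wins; ties break alphabetically by altloc id."""
    return min(atoms, key=lambda a: (-a.occupancy, a.altloc or ""))


def _pick_site_atom(res: Residue, policy: SelectionPolicy) -> Optional[tuple[Atom, str]]:
    candidates = res.atoms_named(policy.atom_type)
    if candidates:
        return _resolve_altloc(candidates), policy.atom_type
    if policy.atom_type == "CB":
        if res.aa_type == "GLY" and policy.gly_policy == "skip":
            return None
        ca = res.atoms_named("CA")
        if ca and res.aa_type == "GLY":
            return _resolve_altloc(ca), "CA-fallback"
    return None


def select_sites(structure: Structure, policy: SelectionPolicy) -> list[Site]:
    """Derive one :class:`Site` per selected residue.

    Residues lacking the representative atom (missing density; non-glycine
    residues without CB in CB mode) are skipped with a logged warning rather
    than raising.  Output is ordered by (chain, seq_index).
    """
    if not 0 <= policy.model_index < len(structure.models):
        raise ModelNotFoundError(
            f"model index {policy.model_index} not in structure "
            f"({len(structure.models)} model(s))"
        )
    model = structure.models[policy.model_index]

    if policy.chains is not None:
        chains = [model.chain(cid) for cid in policy.chains]
    else:
        chains = model.chains

    sites: list[Site] = []
    for chain in chains:
        for seq_index, res in enumerate(chain.residues):
            if res.hetero and not policy.include_hetero:
                continue
            if policy.residue_range is not None:
                lo, hi = policy.residue_range
                if not lo <= res.number <= hi:
                    continue
            picked = _pick_site_atom(res, policy)
            if picked is None:
                logger.warning(
                    "residue %s:%s%s (%s) lacks a usable %s atom; skipped",
                    chain.id, res.number, res.icode or "", res.aa_type,
                    policy.atom_type,
                )
                continue
            atom, source = picked
            sites.append(
                Site(
                    residue_key=res.key(chain.id),
                    aa_type=res.aa_type,
                    seq_index=seq_index,
                    coord=atom.coord.copy(),
                    source_atom=source,
                )
            )
    if not sites:
        raise EmptySelectionError("empty selection: no residues yielded a site")
    return sites


# ---------------------------------------------------------------------------
# writing (synthetic fixtures and round-trips)

_PDB_ATOM = (
    "{record:<6s}{serial:>5d} {name:<4s}{altloc:1s}{resname:>3s} "
    "{chain:1s}{resnum:>4d}{icode:1s}   "
    "{x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{bfac:>6.2f}          {element:>2s}"
)


def _atom_name_field(name: str) -> str:
    # standard element-aligned padding: 1-char element names start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(structure: Structure, destination: Union[str, IO[str]]) -> None:
    """Serialize a Structure to wwPDB v3.3 fixed-width text."""
    own = isinstance(destination, str)
    handle = open(destination, "w") if own else destination
    try:
        multi = len(structure.models) > 1
        for mi, model in enumerate(structure.models, start=1):
            if multi:
                handle.write(f"MODEL     {mi:>4d}\n")
            serial = 0
            for chain in model.chains:
                for res in chain.residues:
                    for atom in res.atoms:
                        serial += 1
                        handle.write(
                            _PDB_ATOM.format(
                                record="HETATM" if res.hetero else "ATOM",
                                serial=serial,
                                name=_atom_name_field(atom.name),
                                altloc=atom.altloc or " ",
                                resname=res.aa_type,
                                chain=chain.id,
                                resnum=res.number,
                                icode=res.icode or " ",
                                x=atom.coord[0],
                                y=atom.coord[1],
                                z=atom.coord[2],
                                occ=atom.occupancy,
                                bfac=0.0,
                                element=atom.name[0],
                            )
                            + "\n"
                        )
                handle.write("TER\n")
            if multi:
                handle.write("ENDMDL\n")
        handle.write("END\n")
    finally:
        if own:
            handle.close()


def pdb_string(structure: Structure) -> str:
    buf = io.StringIO()
    write_pdb(structure, buf)
    return buf.getvalue()
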