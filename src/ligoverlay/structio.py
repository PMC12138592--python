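"""Hierarchical coordinate model and PDB/mmCIF input/output.

The in-memory model is a minimal chain/residue/atom hierarchy carrying unit
cell and space group, sufficient for superposition, symmetry expansion and
binding-site truncation.  File parsing and writing delegate to gemmi; only
the first model of multi-model files is kept, and for alternate conformers
the highest-occupancy altloc wins (first encountered on a tie).  Waters and
other heteroatoms are retained, flagged non-polymer, and participate in
distance-based truncation like any residue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "StructureError",
    "SelectionError",
    "load_structure",
    "select_chain",
    "select_residues",
    "write_structure",
]


class StructureError(ValueError):
    """Malformed or unreadable structure data."""


class SelectionError(KeyError):
    """A chain/residue selection matched nothing."""

    def __str__(self) -> str:  # KeyError quotes its repr by default
        return self.args[0] if self.args else ""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # Cartesian, Å
    occupancy: float = 1.0
    b_iso: float = 15.0
    is_polymer: bool = True

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise StructureError(f"atom {self.name}: position must be finite 3-vector")


@dataclass
class Residue:
    name: str
    seq_id: int
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.name} {self.seq_id} has no atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    @property
    def is_polymer(self) -> bool:
        return all(a.is_polymer for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, [replace(a, pos=a.pos.copy()) for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        seq_ids = [r.seq_id for r in self.residues]
        if len(set(seq_ids)) != len(seq_ids):
            raise StructureError(f"chain {self.chain_id}: duplicate residue seq_ids")

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    chains: list[Chain]
    cell: Optional[tuple[float, float, float, float, float, float]] = None
    space_group: Optional[str] = None
    name: str = "structure"

    def __post_init__(self) -> None:
        if self.space_group is not None:
            if self.cell is None:
                raise StructureError("space group given without a unit cell")
            a, b, c, al, be, ga = self.cell
            if min(a, b, c) <= 0 or not all(0 < x < 180 for x in (al, be, ga)):
                raise StructureError(f"invalid unit cell {self.cell}")

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield chain.chain_id, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def all_coords(self) -> np.ndarray:
        return np.array([a.pos for _, _, a in self.iter_atoms()]).reshape(-1, 3)

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains], self.cell, self.space_group, self.name)


# -- reading ---------------------------------------------------------------


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Single-conformer view: highest occupancy per atom name, first on tie."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def load_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file (first model only) into a :class:`Structure`."""
    path = Path(path)
    if not path.exists():
        raise StructureError(f"coordinate file not found: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    cell = None
    sg = None
    if st.cell.is_crystal():
        c = st.cell
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        sg = st.spacegroup_hm or None

    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            polymer = gres.entity_type == gemmi.EntityType.Polymer
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    b_iso=a.b_iso,
                    is_polymer=polymer,
                )
                for a in _pick_altlocs(gres)
            ]
            if atoms:
                residues.append(Residue(gres.name, gres.seqid.num, atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))
    if not chains:
        raise StructureError(f"{path}: no atoms found")
    return Structure(chains, cell=cell, space_group=sg, name=path.stem)


# -- selections ------------------------------------------------------------


def select_chain(s: Structure, chain_id: Optional[str] = None) -> Chain:
    """Named chain, or the first chain in file order when ``chain_id`` is None."""
    if not s.chains:
        raise SelectionError("structure has no chains")
    if chain_id is None:
        return s.chains[0]
    for chain in s.chains:
        if chain.chain_id == chain_id:
            return chain
    available = ", ".join(c.chain_id for c in s.chains)
    raise SelectionError(f"chain {chain_id!r} not found (available: {available})")


def select_residues(
    s: Structure, chain_id: str, resrange: tuple[int, int]
) -> list[tuple[str, Residue]]:
    """All residues of ``chain_id`` with seq_id inside the inclusive range."""
    chain = select_chain(s, chain_id)
    lo, hi = resrange
    hits = [(chain.chain_id, r) for r in chain.residues if lo <= r.seq_id <= hi]
    if not hits:
        raise SelectionError(
            f"ligand not found: no residues {lo}-{hi} in chain {chain_id!r}"
        )
    return hits


# -- writing ---------------------------------------------------------------


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.name
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell)
    if s.space_group is not None:
        st.spacegroup_hm = s.space_group
    model = gemmi.Model("1")
    for chain in s.chains:
        if not chain.residues:
            raise StructureError(f"chain {chain.chain_id} is empty")
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.pos)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_iso
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, format: Optional[str] = None) -> None:
    """Write PDB or mmCIF; format defaults from the file extension."""
    if not s.chains or all(not c.residues for c in s.chains):
        raise StructureError("refusing to write empty structure")
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = _to_gemmi(s)
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        elif format == "mmcif":
            st.make_mmcif_document().write_file(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc
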