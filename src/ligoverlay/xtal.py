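"""Crystallographic symmetry mates and binding-site truncation.

A ligand in a crystal can be contacted by residues from symmetry-related
copies of the asymmetric unit (lattice contacts).  This module enumerates
space-group images within a small lattice-shift window (-2..2 per axis,
ample for any cell larger than the contact cutoff), keeps the residue copies
that actually touch the ligand, and trims a structure to the ligand plus
every residue — own chain, other ASU chains, waters, symmetry copies — with
at least one atom inside the cutoff radius.  Residues are kept or dropped
whole.  Only the 65 Sohncke space groups (all-proper operators, the ones
available to chiral macromolecules) are accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .structio import Chain, Residue, Structure, StructureError

__all__ = [
    "SymOp",
    "UnitCellFrame",
    "SpaceGroupError",
    "space_group_ops",
    "symmetry_mates_near",
    "truncate_environment",
    "TRUNCATION_RADIUS",
]

logger = logging.getLogger(__name__)

TRUNCATION_RADIUS = 4.5  # Å; binding-site environment cutoff
SHIFT_RANGE = range(-2, 3)  # lattice translations searched per axis
FRESH_CHAIN_IDS = "abcdefghijklmnopqrstuvwxyz0123456789"


class SpaceGroupError(ValueError):
    """Unknown or unsupported space-group symbol."""


@dataclass(frozen=True)
class SymOp:
    """Fractional-coordinate symmetry operator x' = R·x + t."""

    rotation_frac: np.ndarray  # 3x3, integer entries
    translation_frac: np.ndarray  # components in [0, 1)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation_frac, dtype=float)
        t = np.mod(np.asarray(self.translation_frac, dtype=float), 1.0)
        object.__setattr__(self, "rotation_frac", R)
        object.__setattr__(self, "translation_frac", t)
        if abs(np.linalg.det(R)) < 1e-9:
            raise ValueError("symmetry rotation must be invertible")

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.rotation_frac, np.eye(3)) and np.allclose(
            self.translation_frac, 0.0
        )

    def apply_frac(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.rotation_frac.T + self.translation_frac

    def triplet(self) -> str:
        op = gemmi.Op()
        op.rot = [[int(round(x * 24)) for x in row] for row in self.rotation_frac]
        op.tran = [int(round(x * 24)) for x in self.translation_frac]
        return op.triplet()


@dataclass(frozen=True)
class UnitCellFrame:
    """Fractional ↔ Cartesian conversion for one unit cell."""

    orth: np.ndarray  # fractional -> Cartesian (Å)
    frac: np.ndarray  # Cartesian -> fractional

    @classmethod
    def from_cell(cls, cell: Sequence[float]) -> "UnitCellFrame":
        gc = gemmi.UnitCell(*cell)
        orth = np.array(gc.orth.mat.tolist())
        frac = np.array(gc.frac.mat.tolist())
        return cls(orth=orth, frac=frac)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.orth)))

    def to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart) @ self.frac.T

    def to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac) @ self.orth.T


def space_group_ops(symbol: str) -> list[SymOp]:
    """All coset representatives (including identity) of a Sohncke space
    group given by its Hermann–Mauguin symbol (spacing/case-insensitive)."""
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise SpaceGroupError(
            f"unknown space-group symbol {symbol!r}; supply a real-space map "
            "or operator override instead"
        )
    ops = []
    for op in sg.operations():
        R = np.array(op.rot, dtype=float) / 24.0
        t = np.array(op.tran, dtype=float) / 24.0
        if np.linalg.det(R) < 0:
            raise SpaceGroupError(
                f"{symbol!r} is not a Sohncke group (improper operator present); "
                "chiral macromolecules cannot crystallize in it"
            )
        ops.append(SymOp(R, t))
    identity = [o for o in ops if o.is_identity]
    rest = [o for o in ops if not o.is_identity]
    return identity + rest


def _ligand_keys(ligand: Sequence[tuple[str, Residue]]) -> set[tuple[str, int]]:
    return {(cid, res.seq_id) for cid, res in ligand}


def _ligand_coords(ligand: Sequence[tuple[str, Residue]]) -> np.ndarray:
    return np.vstack([res.coords for _, res in ligand])


def symmetry_mates_near(
    s: Structure,
    ligand: Sequence[tuple[str, Residue]],
    radius: float = TRUNCATION_RADIUS,
) -> list[tuple[SymOp, tuple[int, int, int], list[tuple[str, Residue]]]]:
    """Symmetry images of the structure's residues that contact the ligand.

    Returns ``(op, lattice_shift, residue_copies)`` triples for every
    non-identity image (any operator, lattice shifts with components in
    -2..2; identity with zero shift is the ASU itself and excluded) that
    places at least one residue atom within ``radius`` of a ligand atom.
    Residue copies carry Cartesian coordinates in the reference cell frame.
    Waters and heteroatoms count as residues; the ligand's own images do not.
    Without cell/space-group metadata (e.g. a cryoEM model) an empty list is
    returned with a logged warning.
    """
    if not ligand:
        raise ValueError("empty ligand selection")
    if s.cell is None or s.space_group is None:
        logger.warning(
            "%s: no cell/space group; skipping symmetry-mate search", s.name
        )
        return []
    frame = UnitCellFrame.from_cell(s.cell)
    ops = space_group_ops(s.space_group)
    lig_keys = _ligand_keys(ligand)
    tree = cKDTree(_ligand_coords(ligand))

    # flat candidate-atom table with a residue index per atom
    cand: list[tuple[str, Residue]] = []
    atom_res_idx: list[int] = []
    coords: list[np.ndarray] = []
    for chain in s.chains:
        for res in chain.residues:
            if (chain.chain_id, res.seq_id) in lig_keys:
                continue
            idx = len(cand)
            cand.append((chain.chain_id, res))
            for atom in res.atoms:
                coords.append(atom.pos)
                atom_res_idx.append(idx)
    if not cand:
        return []
    cart = np.array(coords)
    frac = frame.to_frac(cart)
    atom_res_idx = np.array(atom_res_idx)

    results = []
    for op in ops:
        frac_op = op.apply_frac(frac)
        for shift in product(SHIFT_RANGE, SHIFT_RANGE, SHIFT_RANGE):
            if op.is_identity and shift == (0, 0, 0):
                continue
            img = frame.to_cart(frac_op + np.array(shift, dtype=float))
            dist, _ = tree.query(img, distance_upper_bound=radius)
            hit_res = sorted(set(atom_res_idx[np.isfinite(dist)]))
            if not hit_res:
                continue
            copies = []
            for idx in hit_res:
                cid, res = cand[idx]
                new_res = res.copy()
                img_coords = img[atom_res_idx == idx]
                for atom, pos in zip(new_res.atoms, img_coords):
                    atom.pos = pos.copy()
                copies.append((cid, new_res))
            results.append((op, tuple(shift), copies))
    return results


def truncate_environment(
    s: Structure,
    ligand: Sequence[tuple[str, Residue]],
    radius: float = TRUNCATION_RADIUS,
    mates: Optional[
        Sequence[tuple[SymOp, tuple[int, int, int], list[tuple[str, Residue]]]]
    ] = None,
) -> Structure:
    """Trim to the ligand plus every residue with an atom within ``radius``.

    Symmetry-mate residues (from :func:`symmetry_mates_near`) are appended
    in fresh chains (lowercase letters then digits, deterministic order).
    A ligand with no neighbours yields ligand-only output.
    """
    if not ligand:
        raise ValueError("empty ligand selection")
    lig_keys = _ligand_keys(ligand)
    tree = cKDTree(_ligand_coords(ligand))

    def touches(res: Residue) -> bool:
        dist, _ = tree.query(res.coords, distance_upper_bound=radius)
        return bool(np.any(np.isfinite(dist)))

    chains: list[Chain] = []
    for chain in s.chains:
        kept = [
            res.copy()
            for res in chain.residues
            if (chain.chain_id, res.seq_id) in lig_keys or touches(res)
        ]
        if kept:
            chains.append(Chain(chain.chain_id, kept))

    if mates:
        used = {c.chain_id for c in chains} | {c.chain_id for c in s.chains}
        fresh = (cid for cid in FRESH_CHAIN_IDS if cid not in used)
        for _op, _shift, copies in mates:
            by_chain: dict[str, list[Residue]] = {}
            for cid, res in copies:
                if touches(res):
                    by_chain.setdefault(cid, []).append(res.copy())
            for cid in by_chain:
                try:
                    new_id = next(fresh)
                except StopIteration:
                    raise StructureError("ran out of fresh chain ids for mates")
                chains.append(Chain(new_id, by_chain[cid]))

    if not chains:
        raise ValueError("truncation produced no residues")
    return Structure(chains, cell=s.cell, space_group=s.space_group, name=s.name)
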