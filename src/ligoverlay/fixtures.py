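"""Synthetic protein–ligand crystal fixtures.

Everything the pipeline consumes can be generated here from a seed: an
ideal-geometry polyalanine helix plus a one-residue ligand inside a stated
unit cell, rigid-motion copies, Gaussian-atom map coefficients (and the MTZ
file carrying them), and a ready-made example input card with one reference
and two groups.  No downloads, no external data.

The structure-factor model is a point-atom Gaussian:

    F(h) = sum_atoms Z * exp(-B * |h*|^2 / 4) * exp(2*pi*i h.x_frac)

summed over the space-group images of each atom, which yields maps with
peaks at atom positions — sufficient to exercise synthesis, extraction and
carving, with no claim of crystallographic accuracy (no form-factor tables,
no bulk solvent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .density import MapCoefficients, write_map_coefficients
from .structio import Atom, Chain, Residue, Structure, write_structure
from .superpose import RigidTransform, apply_transform
from .xtal import UnitCellFrame, space_group_ops

__all__ = [
    "FixtureSpec",
    "make_complex",
    "make_coefficients",
    "random_transform",
    "make_fixture_set",
    "LIGAND_SEQ_ID",
]

LIGAND_SEQ_ID = 100
MAX_GRID_DIM = 64  # per-axis budget for synthesized fixture grids

# local-frame atom offsets (radial, tangential, axial) relative to CA
_BACKBONE_OFFSETS = {
    "N": (-0.45, -1.15, -0.70),
    "CA": (0.0, 0.0, 0.0),
    "C": (-0.40, 1.20, 0.60),
    "O": (0.20, 1.60, 1.60),
    "CB": (1.45, 0.15, -0.55),
}
_LIGAND_OFFSETS = {
    "C1": (0.0, 0.0, 0.0),
    "C2": (1.45, 0.0, 0.0),
    "O1": (-0.60, 1.25, 0.0),
    "N1": (-0.55, -0.70, 1.10),
}

HELIX_RADIUS = 2.3  # Å, CA distance from helix axis
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RISE = 1.5  # Å per residue


@dataclass
class FixtureSpec:
    n_residues: int = 10
    space_group: str = "P 1"
    cell: tuple[float, float, float, float, float, float] = (16.0, 16.0, 18.0, 90.0, 90.0, 90.0)
    ligand_offset: Optional[tuple[float, float, float]] = None
    motion: Optional[RigidTransform] = None
    d_min: float = 3.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.n_residues >= LIGAND_SEQ_ID:
            raise ValueError(f"n_residues must stay below {LIGAND_SEQ_ID}")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")


def make_complex(spec: FixtureSpec) -> tuple[Structure, list[tuple[str, Residue]]]:
    """Polyalanine helix + one-residue HETATM ligand inside the cell.

    Returns the structure and the ligand selection (chain A, seq 100).
    Deterministic for a fixed seed; optional coordinate jitter and a rigid
    motion producing a "mobile" copy.
    """
    frame = UnitCellFrame.from_cell(spec.cell)
    center = frame.to_cart(np.array([0.5, 0.5, 0.5]))
    rng = np.random.default_rng(spec.seed)

    residues: list[Residue] = []
    z0 = -(spec.n_residues - 1) * HELIX_RISE / 2.0
    for i in range(spec.n_residues):
        theta = np.deg2rad(HELIX_TWIST * i)
        e_r = np.array([np.cos(theta), np.sin(theta), 0.0])
        e_t = np.array([-np.sin(theta), np.cos(theta), 0.0])
        e_z = np.array([0.0, 0.0, 1.0])
        ca = center + HELIX_RADIUS * e_r + (z0 + i * HELIX_RISE) * e_z
        atoms = []
        for name, (dr, dt, dz) in _BACKBONE_OFFSETS.items():
            pos = ca + dr * e_r + dt * e_t + dz * e_z
            element = name[0]
            atoms.append(Atom(name=name, element=element, pos=pos, b_iso=15.0))
        residues.append(Residue("ALA", i + 1, atoms))

    if spec.ligand_offset is None:
        lig_center = center + np.array([HELIX_RADIUS + 2.3, 0.0, 0.0])
    else:
        lig_center = np.asarray(spec.ligand_offset, dtype=float)

    if spec.space_group.replace(" ", "").upper() != "P1":
        lig_frac = frame.to_frac(lig_center)
        if np.any(lig_frac < 0.0) or np.any(lig_frac >= 1.0):
            raise ValueError(
                f"ligand at fractional {lig_frac} lies outside the cell; "
                "periodic reasoning in symmetry tests would break"
            )

    lig_atoms = [
        Atom(name=name, element=name[0], pos=lig_center + np.array(off),
             b_iso=20.0, is_polymer=False)
        for name, off in _LIGAND_OFFSETS.items()
    ]
    ligand = Residue("LIG", LIGAND_SEQ_ID, lig_atoms)

    chain = Chain("A", residues + [ligand])
    s = Structure([chain], cell=spec.cell, space_group=spec.space_group, name="fixture")

    if spec.noise_sigma > 0:
        for _, _, atom in s.iter_atoms():
            atom.pos = atom.pos + rng.normal(0.0, spec.noise_sigma, 3)
    if spec.motion is not None:
        s = apply_transform(s, spec.motion)

    lig_sel = [("A", r) for r in s.chains[0].residues if r.seq_id == LIGAND_SEQ_ID]
    return s, lig_sel


def make_coefficients(s: Structure, d_min: float) -> MapCoefficients:
    """Gaussian-atom structure factors over the hemisphere-unique hkl set
    to ``d_min``, including F(000), summed over space-group images."""
    if s.cell is None or s.space_group is None:
        raise ValueError("structure needs cell and space group")
    if d_min < 3.0 * max(s.cell[:3]) / MAX_GRID_DIM:
        raise ValueError(
            f"d_min {d_min} would need synthesis grids beyond {MAX_GRID_DIM}^3"
        )
    frame = UnitCellFrame.from_cell(s.cell)
    ops = space_group_ops(s.space_group)

    hmax = np.ceil(np.linalg.norm(frame.orth, axis=0) / d_min).astype(int) + 1
    axes = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inv_d = np.linalg.norm(H @ frame.frac, axis=1)
    keep = inv_d <= 1.0 / d_min + 1e-12
    # hemisphere-unique: l > 0, or l = 0 and k > 0, or k = l = 0 and h >= 0
    h, k, l = H[:, 0], H[:, 1], H[:, 2]
    keep &= (l > 0) | ((l == 0) & (k > 0)) | ((l == 0) & (k == 0) & (h >= 0))
    H = H[keep]
    inv_d2 = inv_d[keep] ** 2

    coords = np.array([a.pos for _, _, a in s.iter_atoms()])
    z = np.array(
        [gemmi.Element(a.element).atomic_number for _, _, a in s.iter_atoms()],
        dtype=float,
    )
    b = np.array([a.b_iso for _, _, a in s.iter_atoms()])
    frac = frame.to_frac(coords)

    F = np.zeros(len(H), dtype=complex)
    damping = np.exp(-np.outer(inv_d2, b) / 4.0) * z[None, :]  # (N, A)
    for op in ops:
        xf = op.apply_frac(frac)
        phase = np.exp(2j * np.pi * (H @ xf.T))  # (N, A)
        F += np.sum(damping * phase, axis=1)

    return MapCoefficients(
        hkl=H,
        f=np.abs(F),
        phi_deg=np.rad2deg(np.angle(F)),
        d_min=d_min,
        cell=s.cell,
        space_group=s.space_group,
    )


def random_transform(rng: np.random.Generator, max_shift: float = 8.0) -> RigidTransform:
    """Uniform random proper rotation (quaternion method) + random shift."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-max_shift, max_shift, 3)
    return RigidTransform(R, t)


def make_fixture_set(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a complete runnable example: reference, two entries (one with
    an MTZ, one in a different space group), and the input card.

    Entry layout mirrors the documented card structure: one ``#REF`` line
    and two ``#G`` groups.  Returns a dict of the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    base_spec = FixtureSpec(seed=seed)
    base, _ = make_complex(base_spec)
    ref_path = out_dir / "ref.pdb"
    write_structure(base, ref_path)

    # entry 1: rigidly moved copy of the base crystal, with map coefficients
    motion = random_transform(rng)
    moved, _ = make_complex(FixtureSpec(seed=seed, motion=motion))
    entry1_path = out_dir / "entry1.pdb"
    write_structure(moved, entry1_path)
    coef = make_coefficients(moved, base_spec.d_min)
    mtz_path = out_dir / "entry1.mtz"
    write_map_coefficients(coef, mtz_path)

    # entry 2: same complex geometry packed differently in a P 21 crystal
    # form; the packing motion rotates about the cell centre so the ligand
    # stays inside the cell and the model remains crystal-consistent
    p21_cell = (16.0, 16.0, 18.0, 90.0, 100.0, 90.0)
    frame2 = UnitCellFrame.from_cell(p21_cell)
    center2 = frame2.to_cart(np.array([0.5, 0.5, 0.5]))
    R2 = random_transform(rng, max_shift=0.0).rotation
    motion2 = RigidTransform(R2, center2 - R2 @ center2 + rng.uniform(-1.0, 1.0, 3))
    p21_spec = FixtureSpec(
        seed=seed,
        space_group="P 1 21 1",
        cell=p21_cell,
        motion=motion2,
    )
    entry2, _ = make_complex(p21_spec)
    entry2_path = out_dir / "entry2.pdb"
    write_structure(entry2, entry2_path)

    card_text = (
        f"# example overlay card\n"
        f"#REF {ref_path.name} A\n"
        f"#G mapped\n"
        f"{entry1_path.name} {mtz_path.name} A {LIGAND_SEQ_ID} lig1 A\n"
        f"#G other_form\n"
        f"{entry2_path.name} A {LIGAND_SEQ_ID} lig2\n"
    )
    card_path = out_dir / "card.txt"
    card_path.write_text(card_text)
    return {
        "card": card_path,
        "reference": ref_path,
        "entry1": entry1_path,
        "entry1_mtz": mtz_path,
        "entry2": entry2_path,
    }
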