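"""Independent test oracles, shared across test modules.

Everything here is deliberately written from scratch (own triplet parser,
own orthogonalization matrix, brute-force enumeration, direct Fourier
summation) so it exercises none of the code paths it checks.
"""

from itertools import product

import numpy as np
from scipy.spatial.distance import cdist

from ligoverlay import Atom, Chain, Residue, Structure
from ligoverlay.xtal import UnitCellFrame

# International Tables coset representatives (Sohncke groups)
IT_OPERATORS = {
    "P 1": ["x,y,z"],
    "P 1 21 1": ["x,y,z", "-x,y+1/2,-z"],
    "C 1 2 1": ["x,y,z", "-x,y,-z", "x+1/2,y+1/2,z", "-x+1/2,y+1/2,-z"],
    "P 21 21 21": [
        "x,y,z", "-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2",
    ],
    "P 43 21 2": [
        "x,y,z", "-x,-y,z+1/2", "-y+1/2,x+1/2,z+3/4", "y+1/2,-x+1/2,z+1/4",
        "-x+1/2,y+1/2,-z+3/4", "x+1/2,-y+1/2,-z+1/4", "y,x,-z", "-y,-x,-z+1/2",
    ],
}

CELLS = {
    "P 1": (9.0, 10.0, 11.0, 90.0, 90.0, 90.0),
    "P 1 21 1": (10.0, 9.0, 11.0, 90.0, 103.0, 90.0),
    "C 1 2 1": (12.0, 10.0, 11.0, 90.0, 98.0, 90.0),
    "P 21 21 21": (10.0, 11.0, 12.0, 90.0, 90.0, 90.0),
    "P 43 21 2": (10.0, 10.0, 13.0, 90.0, 90.0, 90.0),
}


def parse_triplet(triplet):
    """'x,y,z'-style operator triplet -> (R, t), parsed from scratch."""
    R = np.zeros((3, 3))
    t = np.zeros(3)
    axis = {"x": 0, "y": 1, "z": 2}
    for row, part in enumerate(triplet.split(",")):
        part = part.replace(" ", "")
        sign, i = 1.0, 0
        while i < len(part):
            ch = part[i]
            if ch == "+":
                sign, i = 1.0, i + 1
            elif ch == "-":
                sign, i = -1.0, i + 1
            elif ch in axis:
                R[row, axis[ch]] = sign
                sign, i = 1.0, i + 1
            else:  # fraction like 1/2, 3/4
                num, den = part[i], part[i + 2]
                t[row] += sign * float(num) / float(den)
                sign, i = 1.0, i + 3
    return R, t


def orth_matrix(cell):
    """Standard PDB-convention orthogonalization, built from scratch."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.deg2rad([al, be, ga])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(c * c - cx * cx - cy * cy)
    return np.array(
        [[a, b * np.cos(ga), cx], [0.0, b * np.sin(ga), cy], [0.0, 0.0, cz]]
    )


def toy_crystal(space_group, cell, rng, n_res=2):
    """Tiny chain + one-residue ligand at random positions inside the cell."""
    orth = orth_matrix(cell)
    residues = []
    for i in range(n_res):
        frac = rng.uniform(0.15, 0.85, 3)
        center = orth @ frac
        atoms = [
            Atom(f"C{j+1}", "C", center + off)
            for j, off in enumerate(np.array([[0, 0, 0], [1.2, 0, 0], [0, 1.2, 0]]))
        ]
        residues.append(Residue("ALA", i + 1, atoms))
    lig_frac = rng.uniform(0.2, 0.8, 3)
    lig_center = orth @ lig_frac
    lig = Residue(
        "LIG",
        99,
        [
            Atom("L1", "C", lig_center, is_polymer=False),
            Atom("L2", "O", lig_center + np.array([1.3, 0, 0]), is_polymer=False),
        ],
    )
    s = Structure(
        [Chain("A", residues + [lig])], cell=cell, space_group=space_group
    )
    return s, [("A", lig)]


def brute_force_mates(s, ligand, radius, shift_range=3):
    """All-pairs enumeration over frozen IT operators and a wide shift box."""
    orth = orth_matrix(s.cell)
    frac_of = np.linalg.inv(orth)
    lig_xyz = np.vstack([r.coords for _, r in ligand])
    lig_keys = {(cid, r.seq_id) for cid, r in ligand}
    found = {}
    for triplet in IT_OPERATORS[s.space_group]:
        R, t = parse_triplet(triplet)
        is_ident = np.array_equal(R, np.eye(3)) and np.allclose(t, 0)
        for shift in product(*[range(-shift_range, shift_range + 1)] * 3):
            if is_ident and shift == (0, 0, 0):
                continue
            for chain in s.chains:
                for res in chain.residues:
                    if (chain.chain_id, res.seq_id) in lig_keys:
                        continue
                    frac = res.coords @ frac_of.T
                    img = (frac @ R.T + t + np.array(shift)) @ orth.T
                    if cdist(img, lig_xyz).min() <= radius:
                        found[(triplet, shift, chain.chain_id, res.seq_id)] = img
    return found


def direct_sum(coef, cart_points):
    """Direct Fourier summation (P1 data, Hermitian-completed)."""
    frame = UnitCellFrame.from_cell(coef.cell)
    full = {}
    fc = coef.f * np.exp(1j * np.deg2rad(coef.phi_deg))
    for hkl, v in zip(coef.hkl, fc):
        full.setdefault(tuple(hkl), v)
        full.setdefault(tuple(-hkl), np.conj(v))
    H = np.array(list(full.keys()))
    F = np.array(list(full.values()))
    xf = np.asarray(cart_points) @ frame.frac.T
    return (F[None, :] * np.exp(-2j * np.pi * (xf @ H.T))).sum(axis=1).real / frame.volume
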