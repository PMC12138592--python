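"""Rigid-body superposition of a mobile chain onto a reference chain.

Correspondence comes from a global sequence alignment on residue identity
(match +1, mismatch -1, gap -2); the rigid fit is a Kabsch least-squares
solution with the reflection excluded, refined by iterative outlier
rejection: pairs whose post-fit distance exceeds twice the current rmsd
(floor 2.0 Å) are dropped, for at most five cycles, never going below three
pairs.  This emulates the behaviour of sequence-independent superposition
tools on the intended inputs — the same protein solved in different crystal
forms with different ligands — where sequence-guided pairing is safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .structio import Chain, Structure

__all__ = [
    "RigidTransform",
    "SuperposeResult",
    "AlignmentError",
    "DegenerateGeometryError",
    "representative_atom",
    "pair_residues",
    "kabsch",
    "superpose_chains",
    "apply_transform",
]

REJECT_FACTOR = 2.0  # discard pairs beyond this multiple of the current rmsd
REJECT_FLOOR = 2.0  # Å; minimum rejection cutoff
MAX_CYCLES = 5
MIN_PAIRS = 3


class AlignmentError(ValueError):
    """Insufficient or failed residue correspondence."""


class DegenerateGeometryError(ValueError):
    """Point sets too degenerate (collinear/coincident) for a unique fit."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation: x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-8 or not np.allclose(
            R @ R.T, np.eye(3), atol=1e-8
        ):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


@dataclass
class SuperposeResult:
    transform: RigidTransform
    rmsd: float
    n_pairs_initial: int
    n_pairs_final: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


# Residue names mapped to one-letter codes for the sequence aligner; names
# outside this table get stable extra letters assigned per call.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def representative_atom(residue) -> np.ndarray:
    """CA for amino acids, C1'/P fallback for nucleotides, else first atom."""
    for name in ("CA", "C1'", "P"):
        for atom in residue.atoms:
            if atom.name == name:
                return atom.pos
    return residue.atoms[0].pos


def _encode(names_a: list[str], names_b: list[str]) -> tuple[str, str]:
    table = dict(_THREE_TO_ONE)
    pool = iter("BJOUXZbjouxz0123456789abcdefghiklmnpqrstvwy")
    for name in names_a + names_b:
        if name not in table:
            table[name] = next(pool)
    return "".join(table[n] for n in names_a), "".join(table[n] for n in names_b)


def pair_residues(mobile: Chain, reference: Chain) -> list[tuple[int, int]]:
    """Aligned (mobile_index, reference_index) pairs from a global alignment
    of residue-name sequences (match +1, mismatch -1, gap -2)."""
    if len(mobile.residues) < MIN_PAIRS or len(reference.residues) < MIN_PAIRS:
        raise AlignmentError("insufficient correspondence: chains need >= 3 residues")
    seq_m, seq_r = _encode(
        [r.name for r in mobile.residues], [r.name for r in reference.residues]
    )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(seq_m, seq_r)[0]
    pairs: list[tuple[int, int]] = []
    for (ms, me), (rs, _re) in zip(*alignment.aligned):
        pairs.extend((ms + k, rs + k) for k in range(me - ms))
    if len(pairs) < MIN_PAIRS:
        raise AlignmentError(
            f"insufficient correspondence: only {len(pairs)} aligned pairs"
        )
    return pairs


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid transform mapping ``mobile`` onto
    ``reference`` and the minimized rmsd.  Reflections are excluded by the
    usual sign correction on the smallest singular vector."""
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be equal-length lists of 3-vectors")
    if len(P) < MIN_PAIRS:
        raise DegenerateGeometryError("need at least 3 point pairs")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - Pc).T @ (Q - Qc)
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.abs(P - Pc).max(), np.abs(Q - Qc).max(), 1.0)
    if S[1] <= 1e-10 * scale * scale:
        # rank < 2: points (near-)collinear, rotation about the axis is free
        raise DegenerateGeometryError("degenerate (collinear) point sets")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Qc - R @ Pc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(P) - Q) ** 2, axis=1))))
    return transform, rmsd


def superpose_chains(mobile: Chain, reference: Chain) -> SuperposeResult:
    """Fit mobile onto reference with iterative outlier rejection."""
    pairs = pair_residues(mobile, reference)
    mob_pts = np.array([representative_atom(mobile.residues[i]) for i, _ in pairs])
    ref_pts = np.array([representative_atom(reference.residues[j]) for _, j in pairs])
    n_initial = len(pairs)
    keep = np.ones(n_initial, dtype=bool)
    transform, rmsd = kabsch(mob_pts, ref_pts)
    for _ in range(MAX_CYCLES):
        transform, rmsd = kabsch(mob_pts[keep], ref_pts[keep])
        cutoff = max(REJECT_FACTOR * rmsd, REJECT_FLOOR)
        dist = np.linalg.norm(transform.apply(mob_pts) - ref_pts, axis=1)
        new_keep = keep & (dist <= cutoff)
        if new_keep.sum() < MIN_PAIRS or new_keep.sum() == keep.sum():
            break
        keep = new_keep
    transform, rmsd = kabsch(mob_pts[keep], ref_pts[keep])
    return SuperposeResult(
        transform=transform,
        rmsd=rmsd,
        n_pairs_initial=n_initial,
        n_pairs_final=int(keep.sum()),
        pairs=[p for p, k in zip(pairs, keep) if k],
    )


def apply_transform(s: Structure, t: RigidTransform) -> Structure:
    """Return a copy of ``s`` with every atom position mapped to R·x + t."""
    out = s.copy()
    for _, _, atom in out.iter_atoms():
        atom.pos = t.rotation @ atom.pos + t.translation
    return out
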