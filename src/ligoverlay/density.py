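"""Electron-density maps: synthesis from MTZ coefficients, direct CCP4/MRC
ingest, fragment extraction, rigid transformation into the reference frame,
and sigma scaling.

Maps are held on regular grids.  A grid is defined by the Cartesian position
of node (0,0,0), three per-axis step vectors (which need not be orthogonal —
a full-cell crystallographic grid steps along the cell axes), the value
array, and the mean/RMS of the *parent* full map.  Keeping the parent
statistics with every fragment means a "1 sigma" contour of a carved
fragment is the same surface a full-map viewer would draw, which is the
crystallographic convention users expect.

Weighted 2Fo-Fc coefficients are accepted under the Refmac-style labels
FWT/PHWT, with 2FOFCWT/PH2FOFCWT (Phenix/Buster style) as fallback.
Synthesis expands the reflection set with the space-group operators and
Hermitian mates, places the coefficients on an FFT grid sampled at
d_min/sample_rate, and inverse-transforms:

    rho(x) = (1/V) * sum_h F(h) exp(i*phi(h)) exp(-2*pi*i h.x)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np
from scipy import ndimage

from .structio import Atom, Residue
from .superpose import RigidTransform
from .xtal import UnitCellFrame, space_group_ops

__all__ = [
    "DensityGrid",
    "MapCoefficients",
    "DensityError",
    "MapLabelError",
    "MapFormatError",
    "FlatMapError",
    "read_map_coefficients",
    "write_map_coefficients",
    "synthesize_map",
    "read_direct_map",
    "extract_fragment",
    "transform_map",
    "sigma_scale",
    "write_map",
    "PIPELINE_MAP_RADIUS",
    "STANDALONE_MAP_RADIUS",
]

PIPELINE_MAP_RADIUS = 3.0  # Å around the ligand in pipeline mode
STANDALONE_MAP_RADIUS = 9.0  # Å in standalone map-extract mode

#: (amplitude, phase) column-label pairs, in order of preference.
MAP_LABEL_PAIRS = [("FWT", "PHWT"), ("2FOFCWT", "PH2FOFCWT")]


class DensityError(ValueError):
    """Base class for map/coefficient errors."""


class MapLabelError(DensityError):
    """MTZ lacks a supported amplitude/phase label pair."""


class MapFormatError(DensityError):
    """Unreadable or degenerate map file."""


class FlatMapError(DensityError):
    """Constant map cannot be sigma-scaled."""


@dataclass
class DensityGrid:
    """Real-space map values on a regular 3D grid.

    ``spacing`` rows are the step vectors along the three grid axes; node
    (i,j,k) sits at ``origin + i*spacing[0] + j*spacing[1] + k*spacing[2]``.
    ``mean``/``sigma`` are statistics of the parent full map, carried through
    extraction and transformation.  ``cell``/``full_sampling``/``start``
    track the parent unit-cell lattice when the grid is (a fragment of) a
    crystallographic cell grid; ``periodic`` marks a grid covering exactly
    one unit cell.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray  # 3x3, rows are per-axis step vectors (Å)
    sigma: float
    mean: float
    periodic: bool = False
    cell: Optional[tuple[float, float, float, float, float, float]] = None
    full_sampling: Optional[tuple[int, int, int]] = None
    start: Optional[tuple[int, int, int]] = None
    coverage: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise MapFormatError("grid needs at least 2 nodes per axis")
        if abs(np.linalg.det(self.spacing)) < 1e-12:
            raise MapFormatError("grid step vectors must be linearly independent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def node_positions(self, idx: np.ndarray) -> np.ndarray:
        """Cartesian positions of (possibly fractional) grid indices."""
        return self.origin + np.asarray(idx, dtype=float) @ self.spacing

    def index_coords(self, cart: np.ndarray) -> np.ndarray:
        """Continuous grid-index coordinates of Cartesian points."""
        return (np.asarray(cart, dtype=float) - self.origin) @ np.linalg.inv(
            self.spacing
        )


@dataclass
class MapCoefficients:
    """Amplitude/phase Fourier coefficients with cell and symmetry."""

    hkl: np.ndarray  # (N, 3) int Miller indices
    f: np.ndarray  # amplitudes
    phi_deg: np.ndarray  # phases, degrees
    d_min: float
    cell: tuple[float, float, float, float, float, float]
    space_group: str = "P 1"
    labels: tuple[str, str] = ("FWT", "PHWT")

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=float)
        self.phi_deg = np.asarray(self.phi_deg, dtype=float)
        if self.d_min <= 0:
            raise DensityError("d_min must be positive")
        keys = {tuple(h) for h in self.hkl}
        if len(keys) != len(self.hkl):
            raise DensityError("duplicate Miller indices in coefficient set")


# -- MTZ -------------------------------------------------------------------


def read_map_coefficients(path: str | Path) -> MapCoefficients:
    """Read weighted map coefficients from an MTZ file (FWT/PHWT preferred,
    2FOFCWT/PH2FOFCWT fallback)."""
    try:
        mtz = gemmi.read_mtz_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read MTZ {path}: {exc}") from exc
    labels = [c.label for c in mtz.columns]
    pair = next(
        (p for p in MAP_LABEL_PAIRS if p[0] in labels and p[1] in labels), None
    )
    if pair is None:
        raise MapLabelError(
            f"{path}: no supported map-coefficient labels; need one of "
            f"{MAP_LABEL_PAIRS}, found {labels}"
        )
    data = np.array(mtz, copy=True)
    col = {label: i for i, label in enumerate(labels)}
    hkl = data[:, [col["H"], col["K"], col["L"]]].astype(int)
    f = data[:, col[pair[0]]]
    phi = data[:, col[pair[1]]]
    ok = np.isfinite(f) & np.isfinite(phi)
    c = mtz.cell
    return MapCoefficients(
        hkl=hkl[ok],
        f=f[ok],
        phi_deg=phi[ok],
        d_min=float(mtz.resolution_high()),
        cell=(c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
        space_group=mtz.spacegroup.hm if mtz.spacegroup else "P 1",
        labels=pair,
    )


def write_map_coefficients(coef: MapCoefficients, path: str | Path) -> None:
    """Write coefficients to MTZ under the given (default FWT/PHWT) labels."""
    mtz = gemmi.Mtz(with_base=True)
    sg = gemmi.find_spacegroup_by_name(coef.space_group)
    if sg is None:
        raise DensityError(f"unknown space group {coef.space_group!r}")
    mtz.spacegroup = sg
    mtz.set_cell_for_all(gemmi.UnitCell(*coef.cell))
    mtz.add_dataset("overlay")
    amp_label, phi_label = coef.labels
    mtz.add_column(amp_label, "F")
    mtz.add_column(phi_label, "P")
    data = np.column_stack([coef.hkl.astype(float), coef.f, coef.phi_deg])
    mtz.set_data(data)
    mtz.update_reso()
    mtz.write_to_file(str(path))


# -- synthesis -------------------------------------------------------------


def _expand_to_p1(coef: MapCoefficients) -> dict[tuple[int, int, int], complex]:
    """Symmetry-expand and Hermitian-complete the coefficient set.

    For a density obeying rho(R x + t) = rho(x), F(h R) = F(h) exp(-2 pi i h.t);
    the Friedel mate is the complex conjugate at -h.
    """
    ops = space_group_ops(coef.space_group)
    full: dict[tuple[int, int, int], complex] = {}
    fc = coef.f * np.exp(1j * np.deg2rad(coef.phi_deg))
    for op in ops:
        h_rot = coef.hkl @ op.rotation_frac  # row vector h times R
        phase_shift = np.exp(-2j * np.pi * (coef.hkl @ op.translation_frac))
        vals = fc * phase_shift
        h_int = np.rint(h_rot).astype(int)
        for h, v in zip(h_int, vals):
            key = (int(h[0]), int(h[1]), int(h[2]))
            full.setdefault(key, v)
            mate = (-key[0], -key[1], -key[2])
            full.setdefault(mate, np.conj(v))
    return full


def synthesize_map(coef: MapCoefficients, sample_rate: float = 3.0) -> DensityGrid:
    """Inverse Fourier synthesis of one unit cell of density.

    The grid spacing is at most ``d_min / sample_rate`` per axis;
    ``sample_rate`` below 2 would undersample the band limit and is
    rejected.  Mean and RMS are computed over the full cell and stored.
    """
    if sample_rate < 2:
        raise DensityError(f"sample_rate {sample_rate} is sub-Nyquist (< 2)")
    if len(coef.hkl) == 0:
        raise DensityError("empty coefficient set")
    full = _expand_to_p1(coef)
    frame = UnitCellFrame.from_cell(coef.cell)
    volume = frame.volume
    hmax = np.max(np.abs(np.array(list(full.keys()))), axis=0)
    target = coef.d_min / sample_rate
    axis_len = np.array(coef.cell[:3])
    dims = np.maximum(
        np.ceil(axis_len / target).astype(int), 2 * hmax + 1
    )
    dims = np.maximum(dims, 2)
    grid = np.zeros(tuple(dims), dtype=complex)
    for (h, k, l), v in full.items():
        grid[h % dims[0], k % dims[1], l % dims[2]] = v
    values = np.real(np.fft.fftn(grid)) / volume
    mean = float(values.mean())
    sigma = float(values.std())
    orth = frame.orth
    spacing = np.stack([orth[:, i] / dims[i] for i in range(3)])
    return DensityGrid(
        values=values,
        origin=np.zeros(3),
        spacing=spacing,
        sigma=sigma,
        mean=mean,
        periodic=True,
        cell=coef.cell,
        full_sampling=tuple(int(n) for n in dims),
        start=(0, 0, 0),
    )


# -- CCP4/MRC --------------------------------------------------------------


def read_direct_map(path: str | Path) -> DensityGrid:
    """Read a CCP4/MRC map.  Both origin conventions are honored: start
    indices (NCSTART...) and the MRC origin vector add up.  Statistics are
    recomputed over all voxels."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read map {path}: {exc}") from exc
    values = np.array(ccp4.grid.array, dtype=float)
    if values.size == 0 or values.ndim != 3 or min(values.shape) < 2:
        raise MapFormatError(f"{path}: degenerate map dimensions {values.shape}")
    axis_order = tuple(ccp4.header_i32(i) for i in (17, 18, 19))
    nstart_file = [ccp4.header_i32(i) for i in (5, 6, 7)]
    if sorted(axis_order) != [1, 2, 3]:
        raise MapFormatError(f"{path}: bad axis correspondence {axis_order}")
    if axis_order != (1, 2, 3):
        # file axes (col,row,sec) -> cell axes (a,b,c)
        perm = [axis_order.index(i + 1) for i in range(3)]
        values = np.transpose(values, axes=perm)
        nstart = [nstart_file[p] for p in perm]
    else:
        nstart = nstart_file
    m = tuple(ccp4.header_i32(i) for i in (8, 9, 10))
    if min(m) < 1:
        raise MapFormatError(f"{path}: bad cell sampling {m}")
    gc = ccp4.grid.unit_cell
    cell = (gc.a, gc.b, gc.c, gc.alpha, gc.beta, gc.gamma)
    frame = UnitCellFrame.from_cell(cell)
    origin_vec = np.array([ccp4.header_float(i) for i in (50, 51, 52)])
    origin = origin_vec + frame.orth @ (np.array(nstart, dtype=float) / np.array(m))
    spacing = np.stack([frame.orth[:, i] / m[i] for i in range(3)])
    periodic = (
        values.shape == m
        and all(n == 0 for n in nstart)
        and np.allclose(origin_vec, 0.0)
    )
    mean = float(values.mean())
    sigma = float(values.std())
    return DensityGrid(
        values=values,
        origin=origin,
        spacing=spacing,
        sigma=sigma,
        mean=mean,
        periodic=periodic,
        cell=cell,
        full_sampling=m,
        start=tuple(nstart),
    )


def write_map(g: DensityGrid, path: str | Path) -> None:
    """Write a CCP4/MRC map (mode 2, float32).

    Cell-lattice grids keep their parent cell and start indices; free
    orthogonal box grids are written as a P1 box with the MRC origin vector.
    Parent mean/RMS go into the DMEAN/ARMS header words so viewers contour
    fragments on the full-map sigma scale.
    """
    if g.values.size == 0:
        raise MapFormatError("refusing to write empty grid")
    na, nb, nc = g.shape
    on_lattice = (
        g.cell is not None and g.full_sampling is not None and g.start is not None
    )
    if on_lattice:
        cell = gemmi.UnitCell(*g.cell)
        m = g.full_sampling
        start = g.start
        origin_vec = np.zeros(3)
    else:
        lengths = np.linalg.norm(g.spacing, axis=1)
        ortho = np.allclose(
            g.spacing / lengths[:, None], np.eye(3), atol=1e-9
        )
        if not ortho:
            raise MapFormatError(
                "free grids must be axis-aligned orthogonal to be written"
            )
        cell = gemmi.UnitCell(
            na * lengths[0], nb * lengths[1], nc * lengths[2], 90, 90, 90
        )
        m = (na, nb, nc)
        start = (0, 0, 0)
        origin_vec = g.origin
    grid = gemmi.FloatGrid(na, nb, nc)
    grid.set_unit_cell(cell)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    np.asarray(grid.array)[:] = g.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((5, 6, 7), start):
        ccp4.set_header_i32(word, int(value))
    for word, value in zip((8, 9, 10), m):
        ccp4.set_header_i32(word, int(value))
    for word, value in zip((50, 51, 52), origin_vec):
        ccp4.set_header_float(word, float(value))
    ccp4.set_header_float(22, float(g.mean))  # DMEAN
    ccp4.set_header_float(55, float(g.sigma))  # ARMS
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise MapFormatError(f"cannot write map {path}: {exc}") from exc


# -- fragment extraction ---------------------------------------------------

Selection = Union[np.ndarray, Sequence[Atom], Sequence[tuple[str, Residue]]]


def _selection_coords(atoms: Selection) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        coords = atoms.reshape(-1, 3)
    else:
        items = list(atoms)
        if not items:
            raise DensityError("empty selection")
        if isinstance(items[0], tuple):
            coords = np.vstack([res.coords for _, res in items])
        else:
            coords = np.array([a.pos for a in items])
    if coords.size == 0:
        raise DensityError("empty selection")
    return coords


def extract_fragment(g: DensityGrid, atoms: Selection, radius: float) -> DensityGrid:
    """Minimal axis-aligned subgrid containing every point within ``radius``
    of the selection; periodic parents wrap across cell boundaries.  Parent
    statistics and lattice bookkeeping carry over."""
    coords = _selection_coords(atoms)
    inv = np.linalg.inv(g.spacing)
    u = (coords - g.origin) @ inv
    halfwidth = radius * np.linalg.norm(inv, axis=0)  # per-index-axis bound
    lo = np.floor(u.min(axis=0) - halfwidth).astype(int)
    hi = np.ceil(u.max(axis=0) + halfwidth).astype(int)
    shape = np.array(g.shape)
    if g.periodic:
        # a request spanning more than the cell clamps to one full period,
        # anchored at the selection so its Cartesian frame stays aligned
        for i in range(3):
            if hi[i] - lo[i] + 1 > shape[i]:
                hi[i] = lo[i] + shape[i] - 1
        idx = [np.arange(lo[i], hi[i] + 1) % shape[i] for i in range(3)]
        values = g.values[np.ix_(*idx)]
    else:
        lo_c = np.maximum(lo, 0)
        hi_c = np.minimum(hi, shape - 1)
        if np.any(lo_c > hi_c) or np.any(u.max(axis=0) < -1e-9) or np.any(
            u.min(axis=0) > shape - 1 + 1e-9
        ):
            raise DensityError("selection not covered by map")
        lo, hi = lo_c, hi_c
        values = g.values[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1]
    if min(values.shape) < 2:
        raise DensityError("fragment too small; enlarge radius")
    start = None
    if g.start is not None:
        start = tuple(int(s + d) for s, d in zip(g.start, lo))
    return DensityGrid(
        values=values.copy(),
        origin=g.origin + lo @ g.spacing,
        spacing=g.spacing.copy(),
        sigma=g.sigma,
        mean=g.mean,
        periodic=False,
        cell=g.cell,
        full_sampling=g.full_sampling,
        start=start,
    )


# -- rigid transformation --------------------------------------------------


def transform_map(g: DensityGrid, t: RigidTransform) -> DensityGrid:
    """Resample ``g`` on an axis-aligned grid in the frame reached by ``t``.

    Each output node y takes the trilinear interpolation of ``g`` at
    t^-1(y); nodes falling outside a non-periodic source get 0 and lower the
    reported ``coverage`` fraction.  Statistics pass through unchanged.
    """
    corners_idx = np.array(
        [[i, j, k] for i in (0, g.shape[0] - 1)
         for j in (0, g.shape[1] - 1)
         for k in (0, g.shape[2] - 1)]
    )
    corners = t.apply(g.node_positions(corners_idx))
    bbox_min = corners.min(axis=0)
    bbox_max = corners.max(axis=0)
    step = float(np.min(np.linalg.norm(g.spacing, axis=1)))
    extent = bbox_max - bbox_min
    dims = np.maximum(np.ceil(extent / step - 1e-9).astype(int) + 1, 2)

    # index coords in g of every output node, as an affine map of (i,j,k)
    inv_s = np.linalg.inv(g.spacing)
    M = step * t.rotation @ inv_s  # applied as v_row @ M
    c = ((bbox_min - t.translation) @ t.rotation - g.origin) @ inv_s
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    v = np.stack([ii, jj, kk], axis=-1).astype(float)
    u = v @ M + c  # (...,3) source index coords
    if g.periodic:
        values = ndimage.map_coordinates(
            g.values, np.moveaxis(u, -1, 0), order=1, mode="grid-wrap"
        )
        coverage = 1.0
    else:
        # clip to the edge before interpolating: scipy's constant mode
        # zeroes coordinates an epsilon beyond n-1 instead of blending
        shape = np.array(g.shape, dtype=float)
        inside = np.all((u >= -1e-9) & (u <= shape - 1 + 1e-9), axis=-1)
        clipped = np.clip(u, 0.0, shape - 1)
        values = ndimage.map_coordinates(
            g.values, np.moveaxis(clipped, -1, 0), order=1, mode="nearest"
        )
        values[~inside] = 0.0
        coverage = float(inside.mean())
    return DensityGrid(
        values=values,
        origin=bbox_min,
        spacing=np.eye(3) * step,
        sigma=g.sigma,
        mean=g.mean,
        periodic=False,
        cell=None,
        full_sampling=None,
        start=None,
        coverage=coverage,
    )


# -- sigma scaling ---------------------------------------------------------


def sigma_scale(g: DensityGrid) -> DensityGrid:
    """Rescale values to parent-map sigma units: (v - mean)/sigma.

    Contouring the result at 1.0 equals contouring the original at
    mean + 1 sigma.  Idempotent once mean=0, sigma=1 are stored."""
    scale_ref = max(float(np.max(np.abs(g.values))), 1.0)
    if not np.isfinite(g.sigma) or g.sigma <= 1e-12 * scale_ref:
        raise FlatMapError("flat map: sigma is zero, cannot sigma-scale")
    values = (g.values - g.mean) / g.sigma
    return replace(
        g,
        values=values,
        sigma=1.0,
        mean=0.0,
        spacing=g.spacing.copy(),
        origin=g.origin.copy(),
    )
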