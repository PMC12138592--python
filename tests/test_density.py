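"""Map coefficients, Fourier synthesis, CCP4 I/O, extraction, transforms.

The synthesis oracle is direct summation over the Hermitian-expanded
reflection set, implemented here from scratch; grid transforms are checked
against index-shift and index-permutation oracles.
"""

import numpy as np
import pytest
import gemmi

from ligoverlay import (
    DensityError,
    DensityGrid,
    FixtureSpec,
    FlatMapError,
    MapCoefficients,
    MapFormatError,
    MapLabelError,
    RigidTransform,
    extract_fragment,
    make_coefficients,
    make_complex,
    read_direct_map,
    read_map_coefficients,
    sigma_scale,
    synthesize_map,
    transform_map,
    write_map,
    write_map_coefficients,
)
from ligoverlay.fixtures import random_transform
from ligoverlay.xtal import UnitCellFrame
from oracles import direct_sum

CELL = (16.0, 16.0, 18.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="module")
def fixture_maps():
    s, lig = make_complex(FixtureSpec(seed=3))
    coef = make_coefficients(s, 3.0)
    grid = synthesize_map(coef)
    return s, lig, coef, grid


# -- MTZ labels ------------------------------------------------------------


class TestMtz:
    def test_fwt_phwt_read(self, fixture_maps, tmp_path):
        _, _, coef, _ = fixture_maps
        path = tmp_path / "c.mtz"
        write_map_coefficients(coef, path)
        back = read_map_coefficients(path)
        assert back.labels == ("FWT", "PHWT")
        assert len(back.hkl) == len(coef.hkl)
        order = np.lexsort(back.hkl.T), np.lexsort(coef.hkl.T)
        assert np.array_equal(back.hkl[order[0]], coef.hkl[order[1]])
        assert np.allclose(back.f[order[0]], coef.f[order[1]], rtol=1e-5)

    def test_2fofcwt_fallback(self, fixture_maps, tmp_path):
        _, _, coef, _ = fixture_maps
        alt = MapCoefficients(
            hkl=coef.hkl, f=coef.f, phi_deg=coef.phi_deg, d_min=coef.d_min,
            cell=coef.cell, space_group=coef.space_group,
            labels=("2FOFCWT", "PH2FOFCWT"),
        )
        path = tmp_path / "alt.mtz"
        write_map_coefficients(alt, path)
        back = read_map_coefficients(path)
        assert back.labels == ("2FOFCWT", "PH2FOFCWT")

    def test_unsupported_labels_error_lists_columns(self, tmp_path):
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.find_spacegroup_by_name("P 1")
        mtz.set_cell_for_all(gemmi.UnitCell(*CELL))
        mtz.add_dataset("d")
        mtz.add_column("FP", "F")
        mtz.add_column("SIGFP", "Q")
        mtz.set_data(np.array([[1.0, 0.0, 0.0, 5.0, 0.1]]))
        path = tmp_path / "fp.mtz"
        mtz.write_to_file(str(path))
        with pytest.raises(MapLabelError, match="FP"):
            read_map_coefficients(path)


# -- synthesis -------------------------------------------------------------


class TestSynthesis:
    def test_dc_term_gives_constant_map(self):
        frame = UnitCellFrame.from_cell(CELL)
        coef = MapCoefficients(
            hkl=[[0, 0, 0]], f=[frame.volume], phi_deg=[0.0], d_min=3.0, cell=CELL
        )
        g = synthesize_map(coef)
        assert np.allclose(g.values, 1.0, atol=1e-12)

    def test_single_reflection_cosine_wave(self, rng):
        coef = MapCoefficients(
            hkl=[[1, 0, 0]], f=[1.0], phi_deg=[0.0], d_min=3.0, cell=CELL
        )
        g = synthesize_map(coef)
        dims = np.array(g.shape)
        idx = np.column_stack([rng.integers(0, n, 20) for n in dims])
        pts = g.node_positions(idx)
        expected = direct_sum(coef, pts)  # (2/V) cos(2 pi x/a)
        got = g.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.allclose(got, expected, atol=1e-8)
        frame = UnitCellFrame.from_cell(CELL)
        assert np.allclose(
            got, 2.0 / frame.volume * np.cos(2 * np.pi * idx[:, 0] / dims[0]),
            atol=1e-8,
        )

    def test_fixture_set_matches_direct_summation(self, fixture_maps, rng):
        _, _, coef, g = fixture_maps
        assert len(coef.hkl) <= 500
        idx = np.column_stack([rng.integers(0, n, 50) for n in g.shape])
        got = g.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        expected = direct_sum(coef, g.node_positions(idx))
        assert np.abs(got - expected).max() <= 1e-6 * g.sigma

    def test_parseval_variance(self, fixture_maps):
        _, _, coef, g = fixture_maps
        frame = UnitCellFrame.from_cell(coef.cell)
        full = {}
        fc = coef.f * np.exp(1j * np.deg2rad(coef.phi_deg))
        for hkl, v in zip(coef.hkl, fc):
            full.setdefault(tuple(hkl), v)
            full.setdefault(tuple(-int(x) for x in hkl), np.conj(v))
        power = sum(abs(v) ** 2 for k, v in full.items() if k != (0, 0, 0))
        expected_var = power / frame.volume**2
        assert g.values.var() == pytest.approx(expected_var, rel=0.01)

    def test_sub_nyquist_rejected(self, fixture_maps):
        _, _, coef, _ = fixture_maps
        with pytest.raises(DensityError, match="[Nn]yquist"):
            synthesize_map(coef, sample_rate=1.5)

    def test_grid_spacing_honors_sample_rate(self, fixture_maps):
        _, _, coef, g = fixture_maps
        steps = np.linalg.norm(g.spacing, axis=1)
        assert np.all(steps <= coef.d_min / 3.0 + 1e-9)


# -- CCP4/MRC --------------------------------------------------------------


class TestCcp4:
    def test_round_trip_float32(self, fixture_maps, tmp_path):
        _, _, _, g = fixture_maps
        path = tmp_path / "full.ccp4"
        write_map(g, path)
        back = read_direct_map(path)
        assert back.shape == g.shape
        assert np.allclose(back.values, g.values.astype(np.float32), atol=1e-6)
        assert np.allclose(back.spacing, g.spacing, atol=1e-5)
        assert back.periodic

    def test_fragment_start_indices_round_trip(self, fixture_maps, tmp_path):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, 3.0)
        path = tmp_path / "frag.ccp4"
        write_map(frag, path)
        back = read_direct_map(path)
        assert np.allclose(back.values, frag.values.astype(np.float32), atol=1e-6)
        assert np.allclose(back.origin, frag.origin, atol=1e-4)
        assert not back.periodic

    def test_header_cell_matches_grid(self, fixture_maps, tmp_path):
        _, _, coef, g = fixture_maps
        path = tmp_path / "hdr.ccp4"
        write_map(g, path)
        ccp4 = gemmi.read_ccp4_map(str(path))
        cell = ccp4.grid.unit_cell
        assert (cell.a, cell.b, cell.c) == pytest.approx(coef.cell[:3], abs=1e-4)
        assert [ccp4.header_i32(i) for i in (8, 9, 10)] == list(g.shape)

    def test_parent_stats_stored_in_header(self, fixture_maps, tmp_path):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, 3.0)
        path = tmp_path / "stats.ccp4"
        write_map(frag, path)
        ccp4 = gemmi.read_ccp4_map(str(path))
        assert ccp4.header_float(22) == pytest.approx(g.mean, abs=1e-6)
        assert ccp4.header_float(55) == pytest.approx(g.sigma, abs=1e-6)

    def test_free_box_grid_round_trip(self, tmp_path, rng):
        g = DensityGrid(
            values=rng.normal(size=(6, 7, 8)), origin=np.array([3.0, -2.0, 5.0]),
            spacing=np.eye(3) * 0.9, sigma=1.0, mean=0.0,
        )
        path = tmp_path / "box.mrc"
        write_map(g, path)
        back = read_direct_map(path)
        assert np.allclose(back.values, g.values.astype(np.float32), atol=1e-6)
        assert np.allclose(back.origin, g.origin, atol=1e-5)
        assert np.allclose(back.spacing, g.spacing, atol=1e-5)

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "junk.ccp4"
        path.write_bytes(b"not a map" * 10)
        with pytest.raises(MapFormatError):
            read_direct_map(path)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(MapFormatError):
            DensityGrid(
                values=np.zeros((1, 4, 4)), origin=np.zeros(3),
                spacing=np.eye(3), sigma=1.0, mean=0.0,
            )


# -- extraction ------------------------------------------------------------


class TestExtract:
    def test_whole_cell_radius_returns_parent(self, fixture_maps):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, radius=50.0)
        assert frag.shape == g.shape
        assert np.array_equal(np.sort(frag.values, axis=None),
                              np.sort(g.values, axis=None))

    def test_single_atom_analytic_voxel_count(self):
        g = DensityGrid(
            values=np.zeros((40, 40, 40)), origin=np.zeros(3),
            spacing=np.eye(3) * 0.5, sigma=1.0, mean=0.5,
        )
        point = np.array([[10.0, 10.0, 10.0]])  # exactly node (20,20,20)
        frag = extract_fragment(g, point, radius=3.0)
        expected = 2 * int(np.ceil(3.0 / 0.5)) + 1  # 13 nodes per axis
        assert frag.shape == (expected, expected, expected)

    def test_containment_of_all_points_within_radius(self, fixture_maps, rng):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, radius=3.0)
        lig_xyz = np.vstack([r.coords for _, r in lig])
        # random points in balls around ligand atoms must fall inside the box
        for atom in lig_xyz:
            offsets = rng.normal(size=(200, 3))
            offsets = offsets / np.linalg.norm(offsets, axis=1)[:, None]
            pts = atom + offsets * rng.uniform(0, 3.0, 200)[:, None]
            u = frag.index_coords(pts)
            assert np.all(u >= -1e-9)
            assert np.all(u <= np.array(frag.shape) - 1 + 1e-9)

    def test_atoms_well_inside_bounds(self, fixture_maps):
        _, lig, _, g = fixture_maps
        radius = 3.0
        frag = extract_fragment(g, lig, radius)
        lig_xyz = np.vstack([r.coords for _, r in lig])
        u = frag.index_coords(lig_xyz)
        step = np.linalg.norm(frag.spacing, axis=1)
        margin = radius / step  # index-units margin per axis
        assert np.all(u >= margin - 1)
        assert np.all(u <= np.array(frag.shape) - 1 - margin + 1)

    def test_selection_outside_nonperiodic_map(self, fixture_maps):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, 3.0)  # non-periodic fragment
        far = np.array([[200.0, 200.0, 200.0]])
        with pytest.raises(DensityError, match="not covered"):
            extract_fragment(frag, far, radius=0.5)


# -- rigid transformation --------------------------------------------------


class TestTransform:
    def test_identity_preserves_nodes_exactly(self, fixture_maps):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, 3.0)
        out = transform_map(frag, RigidTransform.identity())
        assert out.shape == frag.shape
        assert np.array_equal(out.values, frag.values)

    def test_integer_voxel_translation_exact(self, fixture_maps):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, 3.0)
        step = np.linalg.norm(frag.spacing[0])
        t = RigidTransform(np.eye(3), frag.spacing[0] * 3 - frag.spacing[2] * 2)
        out = transform_map(frag, t)
        assert out.shape == frag.shape
        assert np.abs(out.values - frag.values).max() <= 1e-12

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_quarter_turn_matches_permutation_oracle(self, axis, rng):
        vals = rng.normal(size=(7, 7, 7))
        g = DensityGrid(
            values=vals, origin=np.zeros(3), spacing=np.eye(3) * 0.8,
            sigma=1.0, mean=0.0,
        )
        R = np.eye(3)
        i, j = [(1, 2), (2, 0), (0, 1)][axis]
        R[i, i] = R[j, j] = 0.0
        R[j, i], R[i, j] = 1.0, -1.0  # +90 deg about `axis`
        out = transform_map(g, RigidTransform(R, np.zeros(3)))
        # oracle: rotating the map +90 about `axis` permutes/flips indices
        oracle = np.flip(np.swapaxes(vals, i, j), axis=i)
        assert out.shape == oracle.shape
        assert np.abs(out.values - oracle).max() <= 1e-10

    def test_round_trip_within_twice_single_step_error(self, fixture_maps, rng):
        _, _, coef, g = fixture_maps
        t = random_transform(rng, max_shift=3.0)
        gt = transform_map(g, t)
        all_idx = lambda grid: np.stack(
            np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij"), -1
        ).reshape(-1, 3)
        idx = all_idx(gt)
        y = gt.node_positions(idx)
        exact = direct_sum(coef, (y - t.translation) @ t.rotation)
        err1 = np.abs(gt.values.reshape(-1) - exact).max()
        back = transform_map(gt, t.inverse())
        idxb = all_idx(back)
        yb = back.node_positions(idxb)
        u = gt.index_coords(t.apply(yb))
        interior = np.all((u > 0.5) & (u < np.array(gt.shape) - 1.5), axis=1)
        err2 = np.abs(back.values.reshape(-1) - direct_sum(coef, yb))[interior].max()
        assert err2 <= 2 * err1

    def test_coverage_flag_drops_when_rotated_box_leaves_source(self, rng):
        g = DensityGrid(
            values=rng.normal(size=(8, 8, 8)), origin=np.zeros(3),
            spacing=np.eye(3), sigma=1.0, mean=0.0,
        )
        theta = np.deg2rad(45)
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        out = transform_map(g, RigidTransform(R, np.zeros(3)))
        assert 0.0 < out.coverage < 1.0


# -- sigma scaling ---------------------------------------------------------


class TestSigmaScale:
    def test_noise_map_scaled_to_zero_mean_unit_rms(self, rng):
        vals = rng.normal(2.0, 3.0, size=(12, 12, 12))
        g = DensityGrid(
            values=vals, origin=np.zeros(3), spacing=np.eye(3),
            sigma=float(vals.std()), mean=float(vals.mean()),
        )
        scaled = sigma_scale(g)
        assert abs(scaled.values.mean()) <= 1e-6
        assert abs(np.sqrt((scaled.values**2).mean()) - 1.0) <= 1e-6
        assert scaled.sigma == 1.0 and scaled.mean == 0.0

    def test_idempotent_once_scaled(self, rng):
        vals = rng.normal(size=(8, 8, 8))
        g = DensityGrid(
            values=vals, origin=np.zeros(3), spacing=np.eye(3),
            sigma=float(vals.std()), mean=float(vals.mean()),
        )
        once = sigma_scale(g)
        twice = sigma_scale(once)
        assert np.array_equal(once.values, twice.values)

    def test_fragment_scaling_uses_parent_stats(self, fixture_maps):
        _, lig, _, g = fixture_maps
        frag = extract_fragment(g, lig, 3.0)
        scaled = sigma_scale(frag)
        assert np.allclose(scaled.values, (frag.values - g.mean) / g.sigma)

    def test_flat_map_raises(self):
        g = DensityGrid(
            values=np.full((4, 4, 4), 7.0), origin=np.zeros(3),
            spacing=np.eye(3), sigma=0.0, mean=7.0,
        )
        with pytest.raises(FlatMapError, match="flat"):
            sigma_scale(g)
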