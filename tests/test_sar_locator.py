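import numpy as np
import pytest

from sardas.errors import GeometryError, InputError
from sardas.phantom import BreastPhantom, contains, make_default_phantom
from sardas.sar_locator import (
    FieldGrid,
    FieldParams,
    SarMap,
    locate_tumor,
    plan_aperture,
    plan_full_ring,
    sar_from_field,
    synthesize_field,
)


def small_axes():
    ax = np.arange(-50.0, 51.0, 2.0)
    return ax, ax.copy(), np.arange(0.0, 51.0, 2.0)


class TestSarFromField:
    def test_direct_arithmetic(self):
        """σ=1.2 S/m, E=100 V/m, ρ=1000 kg/m³ at a tumor voxel gives 12 W/kg."""
        ph = make_default_phantom(tumor_center=(0, 0, 24), tumor_radius=5)
        x = np.array([0.0]); y = np.array([0.0]); z = np.array([24.0])
        grid = FieldGrid(x=x, y=y, z=z, magnitude=np.full((1, 1, 1), 100.0))
        sar = sar_from_field(grid, ph)
        assert sar.sar[0, 0, 0] == pytest.approx(12.0)

    def test_zero_field_gives_zero_map(self, default_phantom):
        x, y, z = small_axes()
        grid = FieldGrid(x=x, y=y, z=z, magnitude=np.zeros((x.size, y.size, z.size)))
        assert not np.any(sar_from_field(grid, default_phantom).sar)

    def test_uniform_field_ratio_is_sigma_over_rho(self, default_phantom):
        """Brute-force per-voxel check: SAR ratio between tissues = (σ/ρ) ratio."""
        x, y, z = small_axes()
        grid = FieldGrid(x=x, y=y, z=z, magnitude=np.full((x.size, y.size, z.size), 2.5))
        sar = sar_from_field(grid, default_phantom)
        skin = sar.sar[sar.labels == -2]
        interior = sar.sar[sar.labels == -3]
        expected = (default_phantom.skin.conductivity / default_phantom.skin.mass_density) / (
            default_phantom.interior.conductivity / default_phantom.interior.mass_density
        )
        assert np.unique(skin).size == 1 and np.unique(interior).size == 1
        assert skin[0] / interior[0] == pytest.approx(expected)

    def test_homogeneous_degree_two_in_field(self, default_phantom):
        x, y, z = small_axes()
        rng = np.random.default_rng(0)
        mag = rng.uniform(0, 10, size=(x.size, y.size, z.size))
        s1 = sar_from_field(FieldGrid(x, y, z, mag), default_phantom).sar
        s3 = sar_from_field(FieldGrid(x, y, z, 3.0 * mag), default_phantom).sar
        np.testing.assert_allclose(s3, 9.0 * s1, rtol=1e-12)


class TestSynthesizeField:
    def test_source_inside_phantom_rejected(self, default_phantom):
        with pytest.raises(GeometryError):
            synthesize_field(default_phantom, (0, 0, 20))

    def test_superposition_dominates_single_source(self, default_phantom):
        f1 = synthesize_field(default_phantom, (0, 0, 60))
        f2 = synthesize_field(default_phantom, (60, 0, 10))
        summed = FieldGrid(f1.x, f1.y, f1.z, f1.magnitude + f2.magnitude)
        s_sum = sar_from_field(summed, default_phantom).sar
        s_one = sar_from_field(f1, default_phantom).sar
        assert np.all(s_sum >= s_one)

    @pytest.mark.parametrize("radius", [1.0, 3.0, 5.0])
    def test_sar_argmax_inside_tumor(self, radius):
        """Exhaustive grid scan: the SAR maximum falls inside the tumor sphere."""
        ph = make_default_phantom(tumor_radius=radius)
        field = synthesize_field(ph, (0, 0, 60))
        est = locate_tumor(sar_from_field(field, ph))
        assert est is not None and est.confident
        center = np.array(ph.tumors[0].center)
        assert np.linalg.norm(np.array(est.position) - center) <= radius

    def test_no_tumor_not_confident(self):
        ph = BreastPhantom()
        field = synthesize_field(ph, (0, 0, 60))
        est = locate_tumor(sar_from_field(field, ph))
        assert est is not None and not est.confident


class TestLocateTumor:
    def test_single_nonzero_voxel(self):
        x = np.array([0.0, 1.0]); y = np.array([0.0, 1.0]); z = np.array([0.0, 1.0])
        sar = np.zeros((2, 2, 2))
        sar[1, 0, 1] = 5.0
        est = locate_tumor(SarMap(x, y, z, sar))
        assert est.position == (1.0, 0.0, 1.0)
        assert est.sar_max == 5.0

    def test_all_zero_map_signals_no_detection(self):
        x = np.array([0.0, 1.0])
        est = locate_tumor(SarMap(x, x, x, np.zeros((2, 2, 2))))
        assert est is None

    def test_constant_map_lexicographic_tie_break(self):
        x = np.array([0.0, 1.0, 2.0])
        est = locate_tumor(SarMap(x, x, x, np.ones((3, 3, 3))))
        assert est.position == (0.0, 0.0, 0.0)


class TestPlanAperture:
    def test_default_grid_on_z_axis(self, default_phantom):
        geom = plan_aperture((0, 0, 25.0), default_phantom)
        assert geom.n_positions == 9
        radii = np.linalg.norm(geom.positions, axis=1)
        np.testing.assert_allclose(radii, 60.0, rtol=1e-12)
        # central antenna of the 3x3 centered grid lies on the +z axis
        np.testing.assert_allclose(geom.positions[4], [0, 0, 60.0], atol=1e-9)

    def test_single_position_on_radial_ray(self, default_phantom):
        geom = plan_aperture((10.0, 5.0, 20.0), default_phantom, rows=1, cols=1)
        u = np.array([10.0, 5.0, 20.0])
        u = u / np.linalg.norm(u)
        np.testing.assert_allclose(geom.positions[0], 60.0 * u, atol=1e-9)

    def test_neighbour_angular_separations(self, default_phantom):
        """Within-row separations are exactly the step; across rows the step
        contracts by at most the O(step²) spherical factor."""
        geom = plan_aperture((0, 0, 25.0), default_phantom, angular_step=10.0)
        dirs = geom.positions / np.linalg.norm(geom.positions, axis=1, keepdims=True)
        grid = dirs.reshape(3, 3, 3)

        def angle(a, b):
            return np.degrees(np.arccos(np.clip(a @ b, -1, 1)))

        for i in range(3):
            for j in range(2):
                assert angle(grid[i, j], grid[i, j + 1]) == pytest.approx(10.0, abs=1e-6)
        for i in range(2):
            for j in range(3):
                assert angle(grid[i, j], grid[i + 1, j]) == pytest.approx(10.0, rel=0.02)

    def test_positions_in_air(self, default_phantom, tumor_estimate):
        geom = plan_aperture(tumor_estimate.center_estimate, default_phantom)
        for p in geom.positions:
            assert contains(default_phantom, p) == "air"

    def test_boresights_point_at_estimate(self, default_phantom):
        est = np.array([15.0, -10.0, 20.0])
        geom = plan_aperture(est, default_phantom)
        for p, b in zip(geom.positions, geom.boresights):
            expect = est - p
            expect = expect / np.linalg.norm(expect)
            np.testing.assert_allclose(b, expect, atol=1e-12)

    def test_origin_estimate_rejected(self, default_phantom):
        with pytest.raises(InputError):
            plan_aperture((0, 0, 0), default_phantom)

    def test_arc_mode_single_row(self, default_phantom):
        geom = plan_aperture((0, 0, 25.0), default_phantom, rows=3, cols=3, mode="arc")
        assert (geom.grid_rows, geom.grid_cols) == (1, 9)
        dirs = geom.positions / np.linalg.norm(geom.positions, axis=1, keepdims=True)
        for a, b in zip(dirs[:-1], dirs[1:]):
            sep = np.degrees(np.arccos(np.clip(a @ b, -1, 1)))
            assert sep == pytest.approx(10.0, abs=1e-6)


class TestPlanFullRing:
    @pytest.mark.parametrize("n,expected", [(36, 10.0), (4, 90.0)])
    def test_azimuth_spacing(self, default_phantom, n, expected):
        geom = plan_full_ring(default_phantom, n_positions=n)
        az = np.degrees(np.arctan2(geom.positions[:, 1], geom.positions[:, 0]))
        diffs = np.diff(az)
        diffs = np.where(diffs < 0, diffs + 360, diffs)
        np.testing.assert_allclose(diffs, expected, atol=1e-9)

    def test_equidistant_from_axis(self, default_phantom):
        geom = plan_full_ring(default_phantom, n_positions=12, plane_height=14.0)
        rho = np.hypot(geom.positions[:, 0], geom.positions[:, 1])
        np.testing.assert_allclose(rho, 60.0, rtol=1e-12)
        np.testing.assert_allclose(geom.positions[:, 2], 14.0)
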