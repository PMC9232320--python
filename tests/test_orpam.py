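"""OR-PAM scan simulator: PSF contracts, projections, uniformity curves."""

import math

import numpy as np
import pytest

import pakit
from pakit import orpam
from pakit.forward import SensitivityModel
from pakit.orpam import (
    JitterModel,
    ScanConfig,
    ScanVolume,
    bscan,
    depth_section,
    detector_uniformity_curve,
    max_projection,
    max_projection_profile,
    scan,
)


@pytest.fixture(scope="module")
def fiber_volume(tissue):
    """8.2 μm fiber along y, scanned with the 9.9 μm default spot."""
    amap = pakit.make_fiber(8.2, 1, 100.0, (160, 24, 40), (0.5, 4.0, 1.0))
    config = ScanConfig(spot_fwhm=9.9, step=0.5, trajectory="raster",
                        pixels=(150, 5), axial_kernel_fwhm=15.0)
    return amap, config, scan(amap, config, tissue)


class TestScan:
    def test_uniform_map_constant_away_from_edges(self, tissue):
        amap = pakit.AbsorptionMap(values=np.full((60, 60, 30), 10.0),
                                   spacing=(10.0, 10.0, 10.0))
        config = ScanConfig(spot_fwhm=20.0, step=10.0, pixels=(20, 20),
                            axial_kernel_fwhm=20.0)
        volume = scan(amap, config, tissue)
        central = max_projection(volume)[5:-5, 5:-5]
        assert central.std() / central.mean() < 1e-6
        # Gruneisen scaling: amplitude = Γ × absorption
        assert central.mean() == pytest.approx(0.25 * 10.0, rel=1e-6)

    def test_point_absorber_map_fwhm_equals_spot(self, tissue):
        amap = pakit.make_point_targets([[40.0, 40.0, 20.0]], 100.0,
                                        (80, 80, 40), (1.0, 1.0, 1.0))
        config = ScanConfig(spot_fwhm=9.9, step=1.0, pixels=(60, 60),
                            axial_kernel_fwhm=10.0)
        volume = scan(amap, config, tissue)
        image = max_projection(volume)
        profile = image[:, np.argmax(image.max(axis=0))]
        width = pakit.measure_fwhm(profile, spacing=1.0)
        assert width == pytest.approx(9.9, rel=0.05)

    def test_scan_extent_overrun_rejected(self, tissue):
        amap = pakit.AbsorptionMap(values=np.zeros((20, 20, 10)),
                                   spacing=(10.0, 10.0, 10.0))
        config = ScanConfig(spot_fwhm=10.0, step=50.0, pixels=(20, 20))
        with pytest.raises(ValueError, match="exceeds map extent"):
            scan(amap, config, tissue)

    def test_needs_3d_map(self, tissue):
        amap = pakit.AbsorptionMap(values=np.zeros((20, 20)),
                                   spacing=(10.0, 10.0))
        with pytest.raises(ValueError, match="3-D"):
            scan(amap, ScanConfig(pixels=(4, 4)), tissue)

    def test_jitter_determinism_and_effect(self, tissue):
        amap = pakit.make_fiber(20.0, 1, 100.0, (60, 20, 20),
                                (2.0, 5.0, 5.0))
        base_cfg = dict(spot_fwhm=10.0, step=2.0, pixels=(50, 4),
                        axial_kernel_fwhm=15.0)
        clean = scan(amap, ScanConfig(**base_cfg), tissue)
        jit1 = scan(amap, ScanConfig(jitter=JitterModel(2.0, seed=1), **base_cfg),
                    tissue)
        jit2 = scan(amap, ScanConfig(jitter=JitterModel(2.0, seed=1), **base_cfg),
                    tissue)
        assert not np.array_equal(clean.a_lines, jit1.a_lines)
        assert np.array_equal(jit1.a_lines, jit2.a_lines)

    def test_rotary_matches_raster_inside_disc(self, tissue):
        """Rotary and raster scans of a smooth target agree after regridding
        (≤ 2% RMS inside the disc) at step ≤ spot/3."""
        n, sp = 64, 5.0
        center = [(n - 1) / 2 * sp] * 3
        amap = pakit.make_uniform_sphere(60.0, center, 100.0, (n, n, n),
                                         (sp, sp, sp))
        step, spot = 5.0, 15.0
        diameter = 240.0
        rot = scan(amap, ScanConfig(spot_fwhm=spot, step=step,
                                    trajectory="rotary",
                                    scan_diameter=diameter,
                                    axial_kernel_fwhm=20.0), tissue)
        n_pix = len(rot.x_coords)
        ras = scan(amap, ScanConfig(spot_fwhm=spot,
                                    step=(rot.x_coords[1] - rot.x_coords[0]),
                                    trajectory="raster", pixels=(n_pix, n_pix),
                                    axial_kernel_fwhm=20.0), tissue)
        map_rot, map_ras = max_projection(rot), max_projection(ras)
        gx, gy = np.meshgrid(rot.x_coords - center[0],
                             rot.y_coords - center[1], indexing="ij")
        inside = np.hypot(gx, gy) <= 0.4 * diameter
        rms = np.sqrt(np.mean((map_rot[inside] - map_ras[inside]) ** 2))
        assert rms <= 0.02 * map_ras.max()


class TestProjections:
    def test_bscan_of_fiber_is_single_blob(self, fiber_volume):
        _, config, volume = fiber_volume
        image = bscan(volume, 2, axis=0)
        assert image.shape == (150, volume.a_lines.shape[2])
        k_depth = np.unravel_index(np.argmax(image), image.shape)[1]
        assert abs(k_depth - 19.5) < 4  # fiber at the 20 μm depth plane

    def test_bscan_out_of_range(self, fiber_volume):
        volume = fiber_volume[2]
        with pytest.raises(IndexError):
            bscan(volume, 99, axis=0)

    def test_zero_volume_zero_bscan(self, fiber_volume):
        volume = fiber_volume[2]
        empty = ScanVolume(a_lines=np.zeros_like(volume.a_lines),
                           x_coords=volume.x_coords, y_coords=volume.y_coords,
                           depth_coords=volume.depth_coords, config=volume.config)
        assert not bscan(empty, 0).any()

    def test_map_single_voxel(self):
        a = np.zeros((4, 5, 6))
        a[1, 2, 3] = 7.0
        image = max_projection(a)
        assert np.count_nonzero(image) == 1
        assert image[1, 2] == 7.0

    def test_map_invariant_to_depth_permutation(self, fiber_volume):
        volume = fiber_volume[2]
        shuffled = volume.a_lines[:, :, np.random.default_rng(0).permutation(
            volume.a_lines.shape[2])]
        np.testing.assert_array_equal(max_projection(volume),
                                      max_projection(shuffled))

    def test_profile_apparent_size_of_fiber(self, fiber_volume):
        _, config, volume = fiber_volume
        profile = max_projection_profile(bscan(volume, 2, axis=0))
        width = pakit.measure_fwhm(profile, spacing=config.step)
        assert 10.0 <= width <= 13.0  # 8.2 μm fiber reads ≈ 11 μm


class TestDepthSection:
    def test_full_thickness_equals_map(self, oral_scan):
        _, _, volume = oral_scan
        span = float(volume.depth_coords[-1] - volume.depth_coords[0])
        section = depth_section(volume, span / 2 + volume.depth_coords[0],
                                2.1 * span)
        np.testing.assert_array_equal(section, max_projection(volume))

    def test_superficial_section_contains_only_loop_layer(self, oral_scan):
        amap, _, _ = oral_scan
        section = depth_section(amap, 100.0, 120.0)
        deep = depth_section(amap, 1000.0, 120.0)
        assert section.any() and deep.any()
        # loop layer diameters (8–15 μm) vs trunk (80–120 μm)
        loop_rep = pakit.vessel_morphometry(section, 10.0, threshold=1.0)
        trunk_rep = pakit.vessel_morphometry(deep, 10.0, threshold=1.0)
        assert loop_rep.mean_diameter < trunk_rep.mean_diameter

    def test_empty_slab_rejected(self, oral_scan):
        volume = oral_scan[2]
        with pytest.raises(ValueError, match="slab"):
            depth_section(volume, 1e6, 1.0)


class TestDetectorUniformity:
    positions = np.linspace(-1500.0, 1500.0, 201)

    def test_ideal_ratio_exactly_one(self):
        curve, ratio = detector_uniformity_curve(SensitivityModel(kind="ideal"),
                                                 self.positions)
        assert ratio == 1.0
        assert np.all(curve == 1.0)

    def test_line_focused_more_uniform_than_flat_field(self):
        _, r_line = detector_uniformity_curve(
            SensitivityModel(kind="line_focused"), self.positions)
        _, r_flat = detector_uniformity_curve(
            SensitivityModel(kind="flat_field"), self.positions)
        assert r_line > r_flat

    def test_curves_symmetric_about_axis(self):
        for kind in ("line_focused", "flat_field"):
            curve, _ = detector_uniformity_curve(SensitivityModel(kind=kind),
                                                 self.positions)
            np.testing.assert_allclose(curve, curve[::-1], rtol=1e-10)


class TestBroadeningLaw:
    def test_quadrature_broadening_for_gaussian_target(self, tissue):
        """apparent² ≈ true² + spot² for a Gaussian-profile absorber."""
        true_fwhm, spot = 12.0, 9.9
        sigma = true_fwhm / (2 * math.sqrt(2 * math.log(2)))
        x = np.arange(100) * 1.0
        blob = np.exp(-0.5 * ((x - 49.5) / sigma) ** 2)
        values = np.zeros((100, 100, 20))
        values[:, :, 10] = blob[:, None] * blob[None, :]
        amap = pakit.AbsorptionMap(values=values, spacing=(1.0, 1.0, 5.0))
        volume = scan(amap, ScanConfig(spot_fwhm=spot, step=1.0,
                                       pixels=(80, 80),
                                       axial_kernel_fwhm=10.0), tissue)
        image = max_projection(volume)
        profile = image[:, image.shape[1] // 2]
        apparent = pakit.measure_fwhm(profile, spacing=1.0)
        expected = math.hypot(true_fwhm, spot)
        assert apparent ** 2 == pytest.approx(expected ** 2, rel=0.10)

    @pytest.mark.parametrize("true_size", [1.0, 4.0, 8.0])
    def test_resolution_floor(self, tissue, true_size):
        """No target below the spot size reads smaller than the spot."""
        amap = pakit.make_fiber(true_size, 1, 100.0, (160, 24, 40),
                                (0.5, 4.0, 1.0))
        config = ScanConfig(spot_fwhm=9.9, step=0.5, pixels=(150, 5),
                            axial_kernel_fwhm=15.0)
        volume = scan(amap, config, tissue)
        profile = max_projection_profile(bscan(volume, 2, axis=0))
        width = pakit.measure_fwhm(profile, spacing=config.step)
        assert width >= 0.95 * 9.9
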