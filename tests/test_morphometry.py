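"""Morphometric panel against analytic oracles on digitized primitives."""

import numpy as np
import pytest
from scipy import ndimage

from callusct import (
    DensityCalibration,
    DegenerateStructureError,
    GreyVolume,
    LabelVolume,
    analyse,
    bone_mineral_content,
    bone_surface,
    bone_volume,
    degree_of_anisotropy,
    local_thickness,
    make_primitive,
    structure_model_index,
    tissue_mineral_density,
    trabecular_thickness,
)

VOX = 10.0  # um


class TestBoneVolume:
    def test_empty_mask_is_zero(self):
        assert bone_volume(np.zeros((4, 4, 4), bool), VOX) == 0.0

    def test_million_voxels_at_10um_is_one_mm3(self):
        assert bone_volume(np.ones((100, 100, 100), bool), VOX) == pytest.approx(1.0)

    def test_digitized_cylinder_matches_analytic_volume(self):
        # radius 0.5 mm, length 2 mm -> pi * 0.25 * 2 mm^3
        mask = make_primitive("rod", 1.0, (200, 120, 120), VOX)
        assert bone_volume(mask, VOX) == pytest.approx(np.pi * 0.25 * 2.0, rel=0.01)

    def test_additive_over_disjoint_components_and_monotone(self):
        two = make_primitive("two_spheres", (0.2, 0.5), (100, 40, 40), VOX)
        one = make_primitive("sphere", 0.2, (40, 40, 40), VOX)
        assert bone_volume(two, VOX) == pytest.approx(2 * bone_volume(one, VOX), rel=0.01)
        assert bone_volume(two | np.roll(two, 3, 0), VOX) >= bone_volume(two, VOX)


class TestBoneSurface:
    def test_sphere_area_within_3_percent(self):
        mask = make_primitive("sphere", 0.6, (70, 70, 70), VOX)
        assert bone_surface(mask, VOX) == pytest.approx(4 * np.pi * 0.3**2, rel=0.03)

    def test_doubling_voxel_size_quadruples_area(self):
        mask = make_primitive("sphere", 0.3, (40, 40, 40), VOX)
        assert bone_surface(mask, 2 * VOX) == pytest.approx(4 * bone_surface(mask, VOX), rel=1e-6)

    def test_disjoint_spheres_areas_add(self):
        two = make_primitive("two_spheres", (0.24, 0.6), (110, 40, 40), VOX)
        one = make_primitive("sphere", 0.24, (40, 40, 40), VOX)
        assert bone_surface(two, VOX) == pytest.approx(2 * bone_surface(one, VOX), rel=0.02)

    def test_error_shrinks_with_resolution(self):
        # same 0.6 mm sphere digitized at 20 um and 10 um
        coarse = make_primitive("sphere", 0.6, (40, 40, 40), 20.0)
        fine = make_primitive("sphere", 0.6, (70, 70, 70), 10.0)
        truth = 4 * np.pi * 0.3**2
        err_c = abs(bone_surface(coarse, 20.0) - truth)
        err_f = abs(bone_surface(fine, 10.0) - truth)
        assert err_f < err_c

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateStructureError):
            bone_surface(np.zeros((4, 4, 4), bool), VOX)


class TestLocalThickness:
    def test_solid_sphere_reads_its_diameter(self):
        mask = make_primitive("sphere", 0.36, (47, 47, 47), VOX)
        tmap = local_thickness(mask, VOX)
        interior = ndimage.binary_erosion(mask, iterations=3)
        assert np.median(tmap.data[interior]) == pytest.approx(0.36, rel=0.05)

    def test_odd_slab_reads_its_thickness(self):
        mask = make_primitive("plate", 0.09, (31, 60, 60), VOX)
        tmap = local_thickness(mask, VOX)
        core = mask & ~np.zeros_like(mask)
        vals = tmap.data[core]
        assert np.median(vals) == pytest.approx(0.09, rel=0.02)

    def test_single_voxel_reads_one_voxel_size(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[4, 4, 4] = True
        tmap = local_thickness(mask, VOX)
        assert tmap.data[4, 4, 4] == pytest.approx(0.01)

    def test_map_zero_outside_compartment(self):
        mask = make_primitive("sphere", 0.1, (20, 20, 20), VOX)
        tmap = local_thickness(mask, VOX)
        assert (tmap.data[~mask] == 0).all()
        assert (tmap.data[mask] > 0).all()


class TestTrabecularThickness:
    def test_cylinder_within_5_percent_of_diameter(self):
        mask = make_primitive("rod", 0.2, (100, 33, 33), VOX)
        tbth = trabecular_thickness(local_thickness(mask, VOX))
        assert tbth == pytest.approx(0.2, rel=0.05)

    def test_uniform_map_mean(self):
        from callusct.morphometry import ThicknessMap

        data = np.zeros((4, 4, 4))
        data[1:3] = 0.07
        assert trabecular_thickness(ThicknessMap(data, VOX)) == pytest.approx(0.07)

    def test_two_strut_mixture_is_volume_weighted_mean(self):
        # two parallel odd-width slabs: 11 and 5 voxels thick
        mask = np.zeros((60, 40, 40), bool)
        mask[10:21] = True
        mask[40:45] = True
        tbth = trabecular_thickness(local_thickness(mask, VOX))
        expected = (11 * 0.11 + 5 * 0.05) / 16
        assert tbth == pytest.approx(expected, rel=0.05)

    def test_empty_rejected(self):
        from callusct.morphometry import ThicknessMap

        with pytest.raises(DegenerateStructureError):
            trabecular_thickness(ThicknessMap(np.zeros((3, 3, 3)), VOX))


class TestStructureModelIndex:
    def test_sphere_rod_plate_reference_values(self):
        sphere = make_primitive("sphere", 0.44, (56, 56, 56), VOX)
        rod = make_primitive("rod", 0.24, (120, 56, 56), VOX)
        plate = make_primitive("plate", 0.08, (24, 110, 110), VOX)
        smi_sphere = structure_model_index(sphere)
        smi_rod = structure_model_index(rod)
        smi_plate = structure_model_index(plate)
        assert smi_sphere == pytest.approx(4.0, abs=0.3)
        assert smi_rod == pytest.approx(3.0, abs=0.3)
        assert smi_plate == pytest.approx(0.0, abs=0.3)
        # structural ordering: plates are the most stable end of the scale
        assert smi_plate < smi_rod < smi_sphere

    def test_voxel_size_independent(self):
        mask = make_primitive("sphere", 0.3, (40, 40, 40), VOX)
        assert structure_model_index(mask, 10.0) == pytest.approx(
            structure_model_index(mask, 34.0)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateStructureError):
            structure_model_index(np.zeros((4, 4, 4), bool))


@pytest.fixture(scope="module")
def sphere_cloud():
    rng = np.random.default_rng(42)
    n = 96
    m = np.zeros((n, n, n), bool)
    z, y, x = np.ogrid[:n, :n, :n]
    for _ in range(80):
        c = rng.uniform(10, n - 10, 3)
        m |= (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2 <= 49
    return m


class TestDegreeOfAnisotropy:
    def test_isotropic_sphere_cloud_near_unity(self, sphere_cloud):
        res = degree_of_anisotropy(sphere_cloud, seed=0)
        assert 1.0 <= res.da <= 1.15

    def test_parallel_plates_strongly_anisotropic_along_z(self):
        plates = make_primitive("plate_stack", (0.05, 0.16), (96, 96, 96), VOX)
        res = degree_of_anisotropy(plates, seed=0)
        assert res.da > 2.0
        # unique fabric axis is the plate normal, i.e. the z axis
        assert abs(res.anisotropy_axis[0]) > 0.99

    def test_da_at_least_one_and_deterministic(self, sphere_cloud):
        a = degree_of_anisotropy(sphere_cloud, seed=3)
        b = degree_of_anisotropy(sphere_cloud, seed=3)
        assert a.da >= 1.0
        assert a.da == b.da

    def test_rotation_by_90_degrees_preserves_da(self):
        plates = make_primitive("plate_stack", (0.05, 0.16), (96, 96, 96), VOX)
        rotated = np.transpose(plates, (1, 0, 2)).copy()
        da1 = degree_of_anisotropy(plates, seed=0).da
        da2 = degree_of_anisotropy(rotated, seed=0).da
        assert da2 == pytest.approx(da1, rel=0.05)
        assert abs(degree_of_anisotropy(rotated, seed=0).anisotropy_axis[1]) > 0.99

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateStructureError):
            degree_of_anisotropy(np.zeros((8, 8, 8), bool))
        with pytest.raises(ValueError, match="directions"):
            degree_of_anisotropy(np.ones((8, 8, 8), bool), n_directions=10)


class TestTissueMineralDensity:
    @staticmethod
    def density_volume(data):
        return GreyVolume(np.asarray(data, float), VOX, value_kind="density")

    def test_uniform_block_exact(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[2:10, 2:10, 2:10] = True
        vol = self.density_volume(np.full((12, 12, 12), 646.01))
        assert tissue_mineral_density(vol, mask) == pytest.approx(646.01)

    def test_two_voxel_peel_removes_bright_rim(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        data = np.full((14, 14, 14), 500.0)
        rim = mask & ~ndimage.binary_erosion(mask)
        data[rim] = 900.0  # partial-volume-like bright shell, 1 voxel thick
        assert tissue_mineral_density(self.density_volume(data), mask) == pytest.approx(500.0)

    def test_thin_plate_vanishes_under_peel(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[5:8] = True  # 3 voxels thick
        with pytest.raises(DegenerateStructureError, match="2"):
            tissue_mineral_density(self.density_volume(np.zeros((12, 12, 12))), mask)

    def test_requires_calibrated_volume(self):
        grey = GreyVolume(np.zeros((6, 6, 6)), VOX, value_kind="grey")
        with pytest.raises(ValueError, match="calibrated"):
            tissue_mineral_density(grey, np.ones((6, 6, 6), bool))

    def test_equals_brute_force_mean_over_eroded_mask(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((16, 16, 16), bool)
        mask[3:13, 3:13, 3:13] = True
        mask &= rng.random((16, 16, 16)) < 0.9
        data = rng.uniform(300, 900, (16, 16, 16))
        # oracle: erode twice by explicit 6-neighbourhood intersection
        m = mask
        for _ in range(2):
            eroded = m.copy()
            for ax in range(3):
                eroded &= np.roll(m, 1, ax) & np.roll(m, -1, ax)
            eroded[0] = eroded[-1] = False
            eroded[:, 0] = eroded[:, -1] = False
            eroded[:, :, 0] = eroded[:, :, -1] = False
            m = eroded
        if m.any():
            expected = data[m].mean()
            got = tissue_mineral_density(self.density_volume(data), mask)
            assert got == pytest.approx(expected)


class TestBoneMineralContent:
    def test_examples_and_identity(self):
        assert bone_mineral_content(0.0, 700.0) == 0.0
        assert bone_mineral_content(1000.0, 1000.0) == pytest.approx(1000.0)
        # product of a realistic BV and TMD with the mm^3 -> cm^3 conversion
        assert bone_mineral_content(55.28, 646.01) == pytest.approx(35.711, abs=5e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bone_mineral_content(-1.0, 0.0)


@pytest.fixture(scope="module")
def analysed(small_phantom):
    spec, vol, truth = small_phantom
    calib = DensityCalibration(2.0, 0.0)
    return spec, vol, truth, analyse(vol, truth, calib, "callus", da_seed=1)


class TestAnalyse:
    def test_panel_invariants(self, analysed):
        _, _, _, res = analysed
        assert res.bv_mm3 > 0 and res.bs_mm2 > 0 and res.tbth_mm > 0
        assert res.da >= 1.0
        assert res.bmc_mg == pytest.approx(res.bv_mm3 * res.tmd_mgHAcm3 / 1000.0, rel=1e-12)

    def test_tmd_reflects_calibrated_callus_plateau(self, analysed):
        spec, _, _, res = analysed
        # noise-free phantom: callus grey 250, calibration slope 2 -> 500
        assert res.tmd_mgHAcm3 == pytest.approx(2.0 * spec.grey_levels[1])

    def test_bone_superset_has_at_least_callus_volume(self, small_phantom):
        _, vol, truth = small_phantom
        calib = DensityCalibration(2.0, 0.0)
        from callusct.morphometry import compartment_mask

        bv_callus = bone_volume(compartment_mask(truth, "callus"), vol.voxel_size_um)
        bv_bone = bone_volume(compartment_mask(truth, "bone"), vol.voxel_size_um)
        assert bv_bone >= bv_callus

    def test_empty_compartment_rejected(self):
        vol = GreyVolume(np.zeros((8, 8, 8)), VOX)
        labels = LabelVolume(np.zeros((8, 8, 8), np.uint8), VOX)
        with pytest.raises(DegenerateStructureError, match="callus"):
            analyse(vol, labels, DensityCalibration(2.0, 0.0))
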