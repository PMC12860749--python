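import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marrowquant.ct_marrow import (
    CctvResult,
    TissueClass,
    classify_voxel,
    compute_cctv,
    infiltrated_band,
    manual_ctv,
    manual_ctv_multi,
    medullary_working_mask,
)
from marrowquant.errors import AlignmentError, DegenerateMaskError, InvalidInputError
from marrowquant.grids import LabelMask, VolumeGrid

from conftest import make_grid, make_mask


def brute_force_cctv(ct: VolumeGrid, mask: LabelMask) -> CctvResult:
    """Independent per-voxel oracle for the cumulative CT value."""
    voxvol = ct.voxel_volume_mm3
    cum = 0.0
    n_mm = 0
    n_cav = 0
    for idx in zip(*np.nonzero(mask.data)):
        n_cav += 1
        hu = float(ct.data[idx])
        if -30 < hu <= 120:
            cum += hu
            n_mm += 1
    return CctvResult(
        cctv=cum * voxvol / (n_cav * voxvol),
        cumulative_hu=cum,
        mm_volume_mm3=n_mm * voxvol,
        cavity_volume_mm3=n_cav * voxvol,
    )


class TestClassifyVoxel:
    @pytest.mark.parametrize(
        "hu,expected",
        [
            (-100, TissueClass.FAT_MARROW),
            (50, TissueClass.INFILTRATED),
            (150, TissueClass.CORTICAL),
            (-300, TissueClass.OUT_OF_RANGE),
            # boundaries
            (-200, TissueClass.FAT_MARROW),
            (np.nextafter(-200, -np.inf), TissueClass.OUT_OF_RANGE),
            (-30, TissueClass.FAT_MARROW),
            (np.nextafter(-30, 0), TissueClass.INFILTRATED),
            (120, TissueClass.INFILTRATED),
            (np.nextafter(120, 200), TissueClass.CORTICAL),
        ],
    )
    def test_bands(self, hu, expected):
        assert classify_voxel(hu) == expected

    @given(st.floats(min_value=-2000, max_value=2000, allow_nan=False))
    def test_partition_every_finite_hu(self, hu):
        assert classify_voxel(hu) in TissueClass

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            classify_voxel(bad)

    @given(
        st.lists(
            st.floats(min_value=-500, max_value=500, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_vectorized_band_matches_scalar(self, values):
        arr = np.asarray(values)
        vec = infiltrated_band(arr)
        scalar = np.array([classify_voxel(v) == TissueClass.INFILTRATED for v in values])
        assert np.array_equal(vec, scalar)


class TestMedullaryWorkingMask:
    def test_excludes_cortical_epiphysis_keeps_120(self):
        data = np.full((4, 4, 4), -80.0)
        cavity = np.zeros((4, 4, 4), bool)
        cavity[1:3, 1:3, 1:3] = True
        epi = np.zeros((4, 4, 4), bool)
        epi[1, 1, 1] = True
        data[1, 1, 2] = 200.0  # cortical-density voxel inside cavity -> excluded
        data[1, 2, 1] = 120.0  # boundary: strict >, so retained
        out = medullary_working_mask(make_grid(data), make_mask(cavity), make_mask(epi))
        assert not out.data[1, 1, 1]  # epiphysis excluded
        assert not out.data[1, 1, 2]  # HU > 120 excluded
        assert out.data[1, 2, 1]  # HU == 120 retained
        assert out.data[2, 2, 2]

    def test_shape_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            medullary_working_mask(
                make_grid(np.zeros((4, 4, 4))),
                make_mask(np.ones((5, 4, 4), bool)),
                make_mask(np.zeros((4, 4, 4), bool)),
            )


class TestManualCtv:
    def test_uniform_cavity_recovers_constant(self, uniform_cavity):
        ct, mask = uniform_cavity
        res = manual_ctv(ct, mask, radii_mm=[3.0])
        assert res.ctv == pytest.approx(-80.0, abs=1e-12)

    def test_two_regions_picks_hotter(self):
        # two homogeneous infiltrated blocks at 20 and 35 HU inside fat marrow
        data = np.full((24, 24, 12), -80.0)
        mask = np.zeros_like(data, bool)
        mask[2:22, 2:22, 2:10] = True
        data[4:12, 4:12, 3:9] = 20.0
        data[14:22, 12:20, 3:9] = 35.0
        res = manual_ctv(make_grid(data), make_mask(mask), radii_mm=[2.0])
        assert res.ctv == pytest.approx(35.0, abs=1e-12)

    def test_spherical_lesion_recovered_exactly(self):
        data = np.full((32, 32, 32), -80.0)
        mask = np.zeros_like(data, bool)
        mask[4:28, 4:28, 4:28] = True
        zz, yy, xx = np.indices(data.shape)
        lesion = (zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 6**2
        data[lesion] = 40.0
        res = manual_ctv(make_grid(data), make_mask(mask), radii_mm=[3.0])
        assert res.ctv == pytest.approx(40.0, abs=1e-12)

    def test_exhaustive_sweep_oracle(self, rng):
        """Implementation equals a brute-force sweep over every center."""
        data = rng.normal(-50, 40, size=(10, 10, 6))
        mask = np.zeros_like(data, bool)
        mask[1:9, 1:9, 1:5] = True
        ct, m = make_grid(data), make_mask(mask)
        r = 2.0
        res = manual_ctv(ct, m, radii_mm=[r])
        # oracle: loop all centers, disc in the (0,1) plane of axis 2
        offs = [
            (i, j)
            for i in range(-2, 3)
            for j in range(-2, 3)
            if i * i + j * j <= r * r
        ]
        best = -np.inf
        for z in range(10):
            for y in range(10):
                for x in range(6):
                    pts = [(z + i, y + j, x) for i, j in offs]
                    if all(
                        0 <= a < 10 and 0 <= b < 10 and mask[a, b, c] for a, b, c in pts
                    ):
                        best = max(best, np.mean([data[p] for p in pts]))
        assert res.ctv == pytest.approx(best, abs=1e-9)

    def test_monotone_in_planted_lesion_hu(self):
        values = []
        for hu in (0.0, 20.0, 40.0, 60.0):
            data = np.full((20, 20, 10), -80.0)
            mask = np.zeros_like(data, bool)
            mask[2:18, 2:18, 2:8] = True
            data[6:14, 6:14, 3:7] = hu
            values.append(manual_ctv(make_grid(data), make_mask(mask), radii_mm=[2.0]).ctv)
        assert values == sorted(values)

    def test_invariant_to_voxels_outside_all_rois(self, uniform_cavity):
        ct, mask = uniform_cavity
        base = manual_ctv(ct, mask, radii_mm=[3.0]).ctv
        modified = ct.data.copy()
        modified[~mask.data] = 500.0  # outside the mask entirely
        res = manual_ctv(make_grid(modified), mask, radii_mm=[3.0])
        assert res.ctv == base

    def test_no_fitting_roi_raises(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4] = True
        with pytest.raises(DegenerateMaskError):
            manual_ctv(make_grid(np.zeros((8, 8, 8))), make_mask(mask), radii_mm=[3.0])

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateMaskError):
            manual_ctv(make_grid(np.zeros((8, 8, 8))), make_mask(np.zeros((8, 8, 8), bool)))

    def test_result_within_mask_hu_range(self, rng):
        data = rng.normal(0, 50, size=(16, 16, 8))
        mask = np.zeros_like(data, bool)
        mask[2:14, 2:14, 1:7] = True
        res = manual_ctv(make_grid(data), make_mask(mask), radii_mm=[2.0, 3.0])
        vals = data[mask]
        assert vals.min() <= res.ctv <= vals.max()

    def test_multi_bone_takes_best(self, uniform_cavity):
        ct, mask = uniform_cavity
        hot = ct.data.copy()
        hot_mask = np.zeros_like(mask.data)
        hot_mask[3:13, 3:13, 3:13] = True
        hot[hot_mask] = 10.0
        ct2 = make_grid(hot)
        res = manual_ctv_multi(ct2, [mask, make_mask(hot_mask)], radii_mm=[3.0])
        # same voxels, both masks see 10.0; per-bone values reported
        assert res.per_bone_values == [10.0, 10.0]


class TestComputeCctv:
    def test_worked_example(self):
        # 1000-voxel cavity at 1 mm^3, 200 MM voxels at 30 HU -> cCTv = 6.0
        data = np.full((10, 10, 10), -80.0)
        mask = np.ones((10, 10, 10), bool)
        data.flat[:200] = 30.0
        res = compute_cctv(make_grid(data), make_mask(mask))
        assert res.cctv == pytest.approx(6.0, abs=1e-12)
        assert res.mm_volume_mm3 == 200.0
        assert res.cavity_volume_mm3 == 1000.0

    def test_no_mm_voxels_gives_zero(self, uniform_cavity):
        ct, mask = uniform_cavity
        res = compute_cctv(ct, mask)
        assert res.cctv == 0.0
        assert res.mm_volume_mm3 == 0.0

    def test_identity_when_all_mm_constant(self):
        data = np.full((6, 6, 6), 25.0)
        res = compute_cctv(make_grid(data), make_mask(np.ones((6, 6, 6), bool)))
        assert res.cctv == pytest.approx(25.0, abs=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateMaskError):
            compute_cctv(make_grid(np.zeros((4, 4, 4))), make_mask(np.zeros((4, 4, 4), bool)))

    def test_literal_interpretation_flag(self):
        data = np.full((10, 10, 10), -80.0)
        data.flat[:200] = 30.0
        mask = make_mask(np.ones((10, 10, 10), bool))
        literal = compute_cctv(make_grid(data), mask, interpretation="literal")
        # sum(HU) * V_MM / V_cav = 6000 * 200/1000
        assert literal.cctv == pytest.approx(1200.0)
        with pytest.raises(InvalidInputError):
            compute_cctv(make_grid(data), mask, interpretation="nonsense")

    def test_anisotropic_spacing(self):
        data = np.full((8, 8, 8), 40.0)
        ct = make_grid(data, spacing=(2.0, 2.0, 2.5))
        mask = make_mask(np.ones((8, 8, 8), bool), spacing=(2.0, 2.0, 2.5))
        res = compute_cctv(ct, mask)
        assert res.cavity_volume_mm3 == pytest.approx(8**3 * 10.0)
        assert res.cctv == pytest.approx(40.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(-30, 80, size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) < 0.7
        if not mask.any():
            mask[0, 0, 0] = True
        ct, m = make_grid(data), make_mask(mask)
        got = compute_cctv(ct, m)
        want = brute_force_cctv(ct, m)
        assert got.cctv == pytest.approx(want.cctv, abs=1e-9)
        assert got.cumulative_hu == pytest.approx(want.cumulative_hu, abs=1e-9)
        assert got.mm_volume_mm3 == want.mm_volume_mm3

    def test_monotone_in_infiltration_fraction(self):
        from marrowquant.phantom import make_ct_phantom, PhantomSpec

        values = []
        for f in (0.1, 0.3, 0.5):
            spec = PhantomSpec(
                grid_shape=(32, 32, 32),
                infiltration_fraction=f,
                fat_hu_sd=0.0,
                lesion_hu_sd=0.0,
                seed=2,
            )
            ct, masks, _ = make_ct_phantom(spec)
            w = medullary_working_mask(ct, masks["medullary_cavity"], masks["epiphysis"])
            values.append(compute_cctv(ct, w).cctv)
        assert values == sorted(values)

    def test_recovery_noise_free(self):
        from marrowquant.phantom import make_ct_phantom, PhantomSpec

        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            infiltration_fraction=0.25,
            infiltration_pattern="focal",
            lesion_hu_mean=40.0,
            fat_hu_sd=0.0,
            lesion_hu_sd=0.0,
            seed=4,
        )
        ct, masks, truth = make_ct_phantom(spec)
        w = medullary_working_mask(ct, masks["medullary_cavity"], masks["epiphysis"])
        res = compute_cctv(ct, w)
        assert res.cctv == pytest.approx(40.0 * truth.realized_infiltration_fraction, abs=1e-9)
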