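"""Radiomic features, outcome derivation and expert-score encoding."""

import itertools

import numpy as np
import pytest

from hiemap.atlas import ZMap
from hiemap.core_io import RegionLabelMap, ValidationError, Volume3D
from hiemap.features import (
    RegionInjuryFlags,
    derive_outcomes,
    intensity_stats,
    lesion_anatomy_features,
    lesion_feature_vector,
    lesion_free_feature_vector,
    lesion_geometry_features,
    nichd_score,
    texture_features,
)
from hiemap.synthetic import PhantomSpec, make_parcellation


def _vol(arr, spacing=(1.0, 1.0, 1.0)):
    return Volume3D(np.asarray(arr, float), spacing=spacing)


class TestNICHDScore:
    @pytest.mark.parametrize("flags,expected", [
        (RegionInjuryFlags(), "0"),
        (RegionInjuryFlags(cerebral_lesions="minimal"), "1A"),
        (RegionInjuryFlags(cerebral_lesions="extensive"), "1B"),
        (RegionInjuryFlags(ws=1), "2A"),
        (RegionInjuryFlags(bgt=1, cerebral_lesions="minimal"), "2B"),
        (RegionInjuryFlags(plic=1, cerebral_lesions="extensive"), "2B"),
        (RegionInjuryFlags(hemispheric_devastation=1, bgt=1), "3"),
    ])
    def test_table_rules(self, flags, expected):
        assert nichd_score(flags) == expected

    def test_total_over_all_flag_combinations(self):
        """Every combination yields exactly one of the six levels."""
        levels = set()
        for bgt, alic, plic, ws, cer, dev in itertools.product(
                (0, 1), (0, 1), (0, 1), (0, 1),
                ("none", "minimal", "extensive"), (0, 1)):
            score = nichd_score(RegionInjuryFlags(bgt, alic, plic, ws, cer, dev))
            assert score in ("0", "1A", "1B", "2A", "2B", "3")
            levels.add(score)
        assert levels == {"0", "1A", "1B", "2A", "2B", "3"}


class TestOutcomes:
    def test_any_domain_at_85_triggers_delay(self):
        rec = derive_outcomes(bsid_cognitive=90, bsid_language=84, bsid_motor=100)
        assert rec.developmental_delay == 1

    def test_motor_boundary_inclusive(self):
        rec = derive_outcomes(bsid_cognitive=100, bsid_language=100, bsid_motor=85,
                              documented_motor_abnormality=0)
        assert rec.motor_impairment == 1

    def test_all_normal(self):
        rec = derive_outcomes(bsid_cognitive=100, bsid_language=100, bsid_motor=100,
                              documented_delay=0, documented_motor_abnormality=0)
        assert rec.developmental_delay == 0
        assert rec.motor_impairment == 0

    def test_missing_propagates_not_negative(self):
        rec = derive_outcomes(bsid_motor=None, documented_motor_abnormality=None)
        assert rec.motor_impairment is None

    def test_documented_flag_dominates_missing_score(self):
        rec = derive_outcomes(documented_motor_abnormality=1)
        assert rec.motor_impairment == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            derive_outcomes(bsid_motor=49)


class TestIntensityStats:
    def test_closed_form_five_values(self):
        out = intensity_stats(np.array([1.0, 2, 3, 4, 5]))
        assert [out[f"p{q:03d}"] for q in (0, 25, 50, 75, 100)] == [1, 2, 3, 4, 5]
        assert out["mean"] == 3.0

    def test_constant_region_degenerate(self):
        out = intensity_stats(np.full(10, 7.0))
        assert all(out[f"p{q:03d}"] == 7.0 for q in (0, 25, 50, 75, 100))
        assert out["skewness"] == 0.0 and out["kurtosis"] == 0.0
        assert out["entropy"] == 0.0 and out["uniformity"] == 1.0

    def test_normal_sample_moments(self):
        v = np.random.default_rng(0).standard_normal(1000)
        out = intensity_stats(v)
        assert abs(out["skewness"]) <= 0.25
        assert abs(out["kurtosis"]) <= 0.5

    def test_percentiles_monotone_under_monotone_transform(self):
        v = np.random.default_rng(1).random(100)
        a = intensity_stats(v)
        b = intensity_stats(2.0 * v + 1.0)
        for q in (0, 25, 50, 75, 100):
            assert b[f"p{q:03d}"] == pytest.approx(2.0 * a[f"p{q:03d}"] + 1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            intensity_stats(np.array([]))


class TestTexture:
    def test_constant_region_energy_one_contrast_zero(self):
        img = _vol(np.ones((4, 4, 4)))
        region = _vol(np.ones((4, 4, 4)))
        out = texture_features(img, region)
        assert out["glcm_contrast"] == 0.0
        assert out["glcm_energy"] == 1.0

    def test_checkerboard_off_diagonal_oracle(self):
        """2-level checkerboard along x, offset (1,0,0) only: every pair is
        a 0-1 transition, so the GLCM is purely off-diagonal and the
        contrast equals the hand-enumerated value (= 1 at 2 levels)."""
        arr = np.indices((4, 4, 1)).sum(axis=0) % 2
        img = _vol(arr.astype(float))
        region = _vol(np.ones((4, 4, 1)))
        out = texture_features(img, region, levels=2, offsets=[(1, 0, 0)])
        # hand enumeration: 12 directed pairs, all 0<->1, symmetric 24 counts
        # contrast = sum P(i,j) (i-j)^2 = 1.0; energy = 2*(0.5^2) = 0.5
        assert out["glcm_contrast"] == pytest.approx(1.0)
        assert out["glcm_energy"] == pytest.approx(0.5)

    def test_stripes_long_runs_along_stripe_axis(self):
        """Stripes constant along x: long-run emphasis along x strictly
        exceeds along y."""
        arr = np.zeros((6, 6, 1))
        arr[:, 1::2, :] = 1.0  # varies along y, constant along x
        out = texture_features(_vol(arr), _vol(np.ones((6, 6, 1))), levels=2)
        assert out["glrlm_long_run_emphasis_x"] > out["glrlm_long_run_emphasis_y"]

    def test_tiny_region_rejected(self):
        img = _vol(np.ones((3, 3, 3)))
        region = _vol(np.zeros((3, 3, 3)))
        region.data[0, 0, 0] = 1.0
        with pytest.raises(ValidationError):
            texture_features(img, region)


class TestGeometry:
    def test_single_voxel_closed_form(self):
        arr = np.zeros((5, 5, 5)); arr[2, 2, 2] = 1.0
        out = lesion_geometry_features(_vol(arr))
        assert out["lesion.geometry.volume_mm3"] == 1.0
        assert out["lesion.geometry.surface_area_mm2"] == 6.0
        expected_sphericity = np.pi ** (1 / 3) * 6.0 ** (2 / 3) / 6.0
        assert out["lesion.geometry.sphericity"] == pytest.approx(expected_sphericity)
        assert out["lesion.geometry.sphericity"] == pytest.approx(0.806, abs=0.001)

    def test_cube_counting(self):
        arr = np.zeros((7, 7, 7)); arr[2:5, 2:5, 2:5] = 1.0
        out = lesion_geometry_features(_vol(arr))
        assert out["lesion.geometry.volume_mm3"] == 27.0
        assert out["lesion.geometry.surface_area_mm2"] == 54.0
        assert out["lesion.geometry.max_diameter_x_mm"] == 3.0
        assert out["lesion.geometry.compactness"] == pytest.approx(1.0)

    def test_digital_sphere_high_sphericity(self):
        x, y, z = np.meshgrid(*(np.arange(24),) * 3, indexing="ij")
        arr = ((x - 11.5) ** 2 + (y - 11.5) ** 2 + (z - 11.5) ** 2 <= 64).astype(float)
        out = lesion_geometry_features(_vol(arr))
        assert out["lesion.geometry.sphericity_mesh"] >= 0.9

    def test_anisotropic_spacing_respected(self):
        arr = np.zeros((4, 4, 4)); arr[1, 1, 1] = 1.0
        out = lesion_geometry_features(_vol(arr, spacing=(1, 1, 2)))
        assert out["lesion.geometry.volume_mm3"] == 2.0
        assert out["lesion.geometry.surface_area_mm2"] == pytest.approx(2 * 1 + 4 * 2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            lesion_geometry_features(_vol(np.zeros((3, 3, 3))))


@pytest.fixture(scope="module")
def parcellation():
    spec = PhantomSpec(shape=(20, 20, 12), seed=17)
    mask, labels = make_parcellation(spec)
    return spec, mask, labels


class TestAnatomy:
    def test_lesion_filling_one_region(self, parcellation):
        spec, mask, labels = parcellation
        lesion = (labels.labels == 3).astype(float)
        out = lesion_anatomy_features(_vol(lesion), labels)
        n_brain = (labels.labels > 0).sum()
        assert out["lesion.anatomy.whole_brain_fraction"] == pytest.approx(
            lesion.sum() / n_brain)
        assert out["lesion.anatomy.region_fraction.region1_left"] == 1.0
        for rid in labels.region_ids:
            if rid != 3:
                assert out[f"lesion.anatomy.region_fraction.{labels.names[rid]}"] == 0.0

    def test_mirror_symmetric_lesion_ratio_one(self, parcellation):
        spec, mask, labels = parcellation
        lesion = np.zeros(spec.shape)
        lesion[labels.labels == 1] = 1.0
        lesion[labels.labels == 2] = 1.0
        out = lesion_anatomy_features(_vol(lesion), labels)
        assert out["lesion.anatomy.lr_ratio.region0_left_region0_right"] == \
            pytest.approx(1.0)
        assert out["lesion.anatomy.lr_asym.region0_left_region0_right"] == \
            pytest.approx(0.0, abs=1e-9)

    def test_random_mask_matches_count_oracle(self, parcellation):
        spec, mask, labels = parcellation
        rng = np.random.default_rng(4)
        lesion = (rng.random(spec.shape) < 0.2) & (labels.labels > 0)
        out = lesion_anatomy_features(_vol(lesion.astype(float)), labels)
        for rid in labels.region_ids:
            inside = labels.labels == rid
            expected = (lesion & inside).sum() / inside.sum()
            assert out[f"lesion.anatomy.region_fraction.{labels.names[rid]}"] == \
                pytest.approx(expected)

    def test_empty_mask_zero_fractions_missing_center(self, parcellation):
        spec, mask, labels = parcellation
        out = lesion_anatomy_features(_vol(np.zeros(spec.shape)), labels)
        assert out["lesion.anatomy.whole_brain_fraction"] == 0.0
        assert np.isnan(out["lesion.anatomy.mass_center_x"])


@pytest.fixture(scope="module")
def patient(parcellation):
    spec, mask, labels = parcellation
    rng = np.random.default_rng(23)
    adc = _vol(rng.normal(1200, 100, spec.shape))
    z = _vol(rng.standard_normal(spec.shape))
    zmap = ZMap(z=z, valid=mask)
    lesion = np.zeros(spec.shape)
    lesion[8:12, 8:12, 5:8] = 1.0
    lesion *= labels.labels > 0
    return adc, zmap, _vol(lesion), labels


class TestFeatureVectors:
    def test_lesion_row_deterministic_and_complete(self, patient):
        adc, zmap, lesion, labels = patient
        r1 = lesion_feature_vector(adc, zmap, lesion, labels)
        r2 = lesion_feature_vector(adc, zmap, lesion, labels)
        assert list(r1) == list(r2)
        assert all(r1[k] == r2[k] or (np.isnan(r1[k]) and np.isnan(r2[k]))
                   for k in r1)
        # every category is represented exactly once per feature name
        for ns in ("lesion.anatomy.", "lesion.geometry.", "lesion.histogram.adc.",
                   "lesion.histogram.z.", "lesion.texture.adc.", "lesion.texture.z."):
            assert any(k.startswith(ns) for k in r1)
        assert len(set(r1)) == len(r1)

    def test_empty_lesion_routes_to_lesion_free(self, patient):
        adc, zmap, lesion, labels = patient
        row = lesion_feature_vector(adc, zmap, lesion.with_data(np.zeros(lesion.shape)),
                                    labels)
        nonempty = lesion_feature_vector(adc, zmap, lesion, labels)
        assert list(row) == list(nonempty)
        assert all(np.isnan(v) for v in row.values())

    def test_lesion_free_region_means_match_oracle(self, patient):
        adc, zmap, lesion, labels = patient
        row = lesion_free_feature_vector(adc, zmap, labels)
        for rid in labels.region_ids:
            inside = labels.labels == rid
            name = labels.names[rid]
            assert row[f"free.region.{name}.z.mean"] == \
                pytest.approx(zmap.z.data[inside].mean())

    def test_lesion_free_volumes_partition_brain(self, patient):
        adc, zmap, lesion, labels = patient
        row = lesion_free_feature_vector(adc, zmap, labels)
        total = sum(row[f"free.region.{labels.names[rid]}.volume_mm3"]
                    for rid in labels.region_ids)
        assert total == pytest.approx((labels.labels > 0).sum() * adc.voxel_volume)

    def test_mirror_symmetric_phantom_zero_asymmetry(self, parcellation):
        spec, mask, labels = parcellation
        rng = np.random.default_rng(29)
        half = rng.normal(1200, 100, spec.shape)
        sym = np.where(np.arange(spec.shape[0])[:, None, None] < spec.shape[0] // 2,
                       half, half[::-1, :, :])
        adc = _vol(sym)
        zmap = ZMap(z=_vol(np.zeros(spec.shape)), valid=mask)
        row = lesion_free_feature_vector(adc, zmap, labels)
        asym = {k: v for k, v in row.items()
                if k.startswith("free.asym.") and ".adc." in k}
        assert asym
        for k, v in asym.items():
            assert v == pytest.approx(0.0, abs=1e-9), k
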