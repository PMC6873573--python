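"""Lesion detection: thresholding, morphology, classification, scoring."""

import numpy as np
import pytest

from hiemap.atlas import ZMap, compute_z_map, build_atlas
from hiemap.core_io import ValidationError, Volume3D
from hiemap.detect import (
    ClassifierDetector,
    ThresholdDetector,
    adapt_to_target,
    detect_by_threshold,
    fit_voxel_classifier,
    loocv_detection,
    postprocess_morphology,
    regularize_with_frequency_atlas,
    roc_sweep,
    score_detection,
)
from hiemap.synthetic import (
    LesionSpec,
    PhantomSpec,
    SiteEffect,
    make_controls,
    make_patient,
    population_atlas,
)


def _zmap_from(z_arr, valid=None):
    z = Volume3D(np.asarray(z_arr, float))
    v = Volume3D(np.ones(z.shape) if valid is None else np.asarray(valid, float))
    return ZMap(z=z, valid=v)


def _mask(arr):
    return Volume3D(np.asarray(arr, float))


class TestThreshold:
    def test_zero_z_gives_empty_mask(self):
        zmap = _zmap_from(np.zeros((4, 4, 4)))
        for tau in (-1.0, -2.0, -2.5):
            assert not detect_by_threshold(zmap, tau).data.any()

    def test_noise_free_lesion_detected(self, lesioned_zmap, lesioned_case):
        mask = detect_by_threshold(lesioned_zmap, -2.0)
        metrics = score_detection(mask, lesioned_case.true_mask)
        assert metrics.dice >= 0.9

    def test_threshold_nesting(self, lesioned_zmap):
        masks = {tau: detect_by_threshold(lesioned_zmap, tau).data > 0
                 for tau in (-1.0, -2.0, -2.5)}
        assert np.all(masks[-2.5] <= masks[-2.0])
        assert np.all(masks[-2.0] <= masks[-1.0])

    def test_high_side_selects_vasogenic(self):
        z = np.zeros((4, 4, 4))
        z[0, 0, 0] = 3.0
        mask = detect_by_threshold(_zmap_from(z), -2.0, high_side=True)
        assert mask.data.sum() == 1 and mask.data[0, 0, 0] == 1

    def test_strict_inequality_at_boundary(self):
        z = np.full((2, 2, 2), -2.0)
        assert not detect_by_threshold(_zmap_from(z), -2.0).data.any()


class TestMorphology:
    def test_identity_when_disabled(self):
        rng = np.random.default_rng(0)
        m = _mask(rng.random((6, 6, 6)) < 0.3)
        out = postprocess_morphology(m, 0, 0, 1)
        np.testing.assert_array_equal(out.data, m.data)

    def test_small_component_removed(self):
        arr = np.zeros((6, 6, 6))
        arr[3, 3, 3] = 1.0
        out = postprocess_morphology(_mask(arr), 0, 0, min_component=2)
        assert not out.data.any()

    def test_closing_fills_hole(self):
        """5^3 cube with a one-voxel hole: closing radius 1 restores the cube."""
        arr = np.zeros((9, 9, 9))
        arr[2:7, 2:7, 2:7] = 1.0
        arr[4, 4, 4] = 0.0
        out = postprocess_morphology(_mask(arr), 0, closing_radius=1)
        expected = np.zeros((9, 9, 9))
        expected[2:7, 2:7, 2:7] = 1.0
        np.testing.assert_array_equal(out.data, expected)

    def test_opening_anti_extensive_closing_extensive(self):
        rng = np.random.default_rng(1)
        m = _mask(rng.random((8, 8, 8)) < 0.4)
        opened = postprocess_morphology(m, opening_radius=1)
        closed = postprocess_morphology(m, closing_radius=1)
        assert np.all(opened.data <= m.data)
        assert np.all(closed.data >= m.data)


class TestRegularize:
    def test_weight_zero_identity(self):
        rng = np.random.default_rng(2)
        p = Volume3D(rng.random((4, 4, 4)))
        prior = Volume3D(rng.random((4, 4, 4)))
        out = regularize_with_frequency_atlas(p, prior, 0.0)
        np.testing.assert_array_equal(out.data, p.data)

    def test_zero_prior_absorbs_at_full_weight(self):
        p = Volume3D(np.full((4, 4, 4), 0.8))
        prior_arr = np.full((4, 4, 4), 0.5)
        prior_arr[1, 1, 1] = 0.0
        out = regularize_with_frequency_atlas(p, Volume3D(prior_arr), 1.0)
        assert out.data[1, 1, 1] == 0.0

    def test_prior_out_of_range_rejected(self):
        p = Volume3D(np.zeros((2, 2, 2)))
        with pytest.raises(ValidationError):
            regularize_with_frequency_atlas(p, Volume3D(np.full((2, 2, 2), 1.5)), 0.5)


class TestScore:
    def test_perfect_match(self, lesioned_case):
        m = score_detection(lesioned_case.true_mask, lesioned_case.true_mask)
        assert (m.dice, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_hand_counted_dice(self):
        """|P|=4, |R|=6, |P inter R|=3 -> Dice 0.6."""
        p = np.zeros((3, 3, 3))
        r = np.zeros((3, 3, 3))
        p.ravel()[[0, 1, 2, 3]] = 1
        r.ravel()[[1, 2, 3, 10, 11, 12]] = 1
        m = score_detection(_mask(p), _mask(r))
        assert m.dice == pytest.approx(0.6)

    def test_disjoint_masks_dice_zero(self):
        p = np.zeros((3, 3, 3)); p[0, 0, 0] = 1
        r = np.zeros((3, 3, 3)); r[2, 2, 2] = 1
        assert score_detection(_mask(p), _mask(r)).dice == 0.0

    def test_both_empty_flagged_dice_one(self):
        m = score_detection(_mask(np.zeros((2, 2, 2))), _mask(np.zeros((2, 2, 2))))
        assert m.dice == 1.0 and m.both_empty

    def test_dice_symmetric(self):
        rng = np.random.default_rng(3)
        a = _mask(rng.random((5, 5, 5)) < 0.3)
        b = _mask(rng.random((5, 5, 5)) < 0.3)
        assert score_detection(a, b).dice == pytest.approx(score_detection(b, a).dice)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            score_detection(_mask(np.zeros((2, 2, 2))), _mask(np.zeros((2, 2, 3))))


class TestROC:
    def test_perfect_separation_auc_one(self):
        z = np.zeros((6, 6, 6))
        truth = np.zeros((6, 6, 6))
        z[:2] = -5.0
        truth[:2] = 1.0
        res = roc_sweep(_zmap_from(z), _mask(truth), [-1, -1.5, -2, -2.5])
        assert res.auc == pytest.approx(1.0)
        assert len(res.roc) == 4

    def test_random_z_auc_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal((10, 10, 10))
            truth = rng.random((10, 10, 10)) < 0.3
            aucs.append(roc_sweep(_zmap_from(z), _mask(truth), [-2.0]).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_tpr_fpr_monotone_in_tau(self, lesioned_zmap, lesioned_case):
        taus = [-3.0, -2.5, -2.0, -1.5, -1.0, -0.5]
        res = roc_sweep(lesioned_zmap, lesioned_case.true_mask, taus)
        tprs = [p[1] for p in res.roc]
        fprs = [p[2] for p in res.roc]
        assert all(a <= b for a, b in zip(tprs, tprs[1:]))
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValidationError):
            roc_sweep(_zmap_from(np.zeros((3, 3, 3))), _mask(np.zeros((3, 3, 3))), [-2])


def _classifier_cases(n_cases, spec, site=None, seed0=0, noise=True):
    """Cases with Z computed against the source-site atlas: a site effect on
    the patient therefore biases both the raw ADC and the Z channel, which
    is exactly the cross-site situation adaptation is meant to fix."""
    atl = population_atlas(spec)
    _, brain_mask, _ = make_controls(spec, 2)
    cases = []
    for i in range(n_cases):
        lesion = LesionSpec(center=(8, 8, 6), radius_mm=3.0, z_offset=-3.5)
        case = make_patient(spec, [lesion], site=site, seed=seed0 + i, noise=noise)
        zmap = compute_z_map(case.volume, atl, patient_mask=brain_mask)
        cases.append((zmap, case.volume, case.true_mask))
    return cases


class TestClassifier:
    SPEC = PhantomSpec(shape=(16, 16, 12), seed=21)

    def test_separable_training_high_accuracy(self):
        cases = _classifier_cases(3, self.SPEC)
        model = fit_voxel_classifier(cases[:2], channels=("z",), seed=0)
        zmap, adc, truth = cases[2]
        prob = model.predict_proba(zmap, adc)
        pred = (prob.data > 0.5)
        valid = zmap.valid.data > 0
        acc = np.mean(pred[valid] == (truth.data > 0)[valid])
        assert acc >= 0.99

    def test_recipe_with_and_without_adc_both_run(self):
        cases = _classifier_cases(2, self.SPEC)
        for channels in (("z",), ("z", "adc")):
            model = fit_voxel_classifier(cases, channels=channels, seed=0)
            prob = model.predict_proba(*cases[0][:2])
            assert prob.data.min() >= 0 and prob.data.max() <= 1

    def test_all_empty_truth_rejected(self):
        spec = self.SPEC
        atl = population_atlas(spec)
        _, brain_mask, _ = make_controls(spec, 2)
        case = make_patient(spec, [], seed=0)
        zmap = compute_z_map(case.volume, atl, patient_mask=brain_mask)
        with pytest.raises(ValidationError, match="single class"):
            fit_voxel_classifier([(zmap, case.volume, case.true_mask)])

    def test_adapt_fallback_is_identity(self):
        cases = _classifier_cases(2, self.SPEC)
        model = fit_voxel_classifier(cases, seed=0)
        # an all-normal target: no silver lesion voxels -> no adaptation
        spec = self.SPEC
        atl = population_atlas(spec)
        _, brain_mask, _ = make_controls(spec, 2)
        target = make_patient(spec, [], seed=99)
        zmap = compute_z_map(target.volume, atl, patient_mask=brain_mask)
        mask, out_model, adapted = adapt_to_target(model, zmap, target.volume,
                                                   confidence=0.999999)
        assert not adapted
        prob = model.predict_proba(zmap, target.volume)
        expected = (prob.data > 0.5) & (zmap.valid.data > 0)
        np.testing.assert_array_equal(mask.data > 0, expected)

    def test_adapt_matched_site_stable(self):
        cases = _classifier_cases(4, self.SPEC)
        model = fit_voxel_classifier(cases[:3], seed=0)
        zmap, adc, truth = cases[3]
        unadapted = ClassifierDetector().fit_predict(cases[:3], zmap, adc)
        adapted_mask, _, _ = adapt_to_target(model, zmap, adc)
        d0 = score_detection(unadapted, truth).dice
        d1 = score_detection(adapted_mask, truth).dice
        assert abs(d1 - d0) <= 0.05

    def test_adapt_helps_under_site_shift(self):
        """Silver-standard retraining recovers accuracy on a site whose raw
        ADC scale differs from the training site (>= 8/10 seeds)."""
        spec = self.SPEC
        train = _classifier_cases(3, spec, seed0=0)
        model = fit_voxel_classifier(train, channels=("z", "adc"), seed=0)
        wins = 0
        for seed in range(10):
            target = _classifier_cases(1, spec, site=SiteEffect(scale=1.15),
                                       seed0=100 + seed)[0]
            zmap, adc, truth = target
            prob = model.predict_proba(zmap, adc)
            valid = zmap.valid.data > 0
            unadapted = zmap.z.with_data(((prob.data > 0.5) & valid).astype(float))
            adapted_mask, _, did = adapt_to_target(model, zmap, adc)
            d0 = score_detection(unadapted, truth).dice
            d1 = score_detection(adapted_mask, truth).dice
            wins += d1 >= d0
        assert wins >= 8


class TestLOOCV:
    def test_eight_cases_eight_folds(self):
        spec = PhantomSpec(shape=(16, 16, 12), seed=31)
        cases = _classifier_cases(8, spec, noise=False)
        res = loocv_detection(cases, ThresholdDetector(tau=-2.0))
        assert len(res["per_case_dice"]) == 8
        assert len(res["folds"]) == 8
        assert sorted(f[1] for f in res["folds"]) == list(range(8))

    def test_threshold_detector_matches_non_cv(self, lesioned_zmap, lesioned_case):
        cases = [(lesioned_zmap, lesioned_case.volume, lesioned_case.true_mask)] * 3
        res = loocv_detection(cases, ThresholdDetector(tau=-2.0))
        direct = score_detection(detect_by_threshold(lesioned_zmap, -2.0),
                                 lesioned_case.true_mask).dice
        assert res["per_case_dice"] == [pytest.approx(direct)] * 3

    def test_fold_enumeration_oracle(self):
        spec = PhantomSpec(shape=(16, 16, 12), seed=32)
        cases = _classifier_cases(3, spec, noise=False)
        res = loocv_detection(cases, ThresholdDetector(tau=-2.0))
        assert res["folds"] == [((1, 2), 0), ((0, 2), 1), ((0, 1), 2)]

    def test_single_case_rejected(self, lesioned_zmap, lesioned_case):
        with pytest.raises(ValidationError):
            loocv_detection([(lesioned_zmap, None, lesioned_case.true_mask)],
                            ThresholdDetector())
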