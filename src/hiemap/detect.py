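"""Lesion detection from ADC and Z maps, post-processing and scoring.

Two detector families are provided: plain thresholding of the Z map
(z < tau for ischemic lesions, optionally z > |tau| for vasogenic
regions) and a voxel-wise classifier on hand-crafted features of the
voxel and its geometric neighbourhood.  The classifier supports a
self-adaptive "silver standard" retraining step for target images from
unseen sites: voxels the source model labels with very high confidence
are taken as provisional truth and the model is refit on the target's
own feature distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from hiemap.atlas import ZMap
from hiemap.core_io import ValidationError, Volume3D, require_same_grid

__all__ = [
    "DetectionMetrics",
    "VoxelClassifierModel",
    "detect_by_threshold",
    "postprocess_morphology",
    "regularize_with_frequency_atlas",
    "fit_voxel_classifier",
    "adapt_to_target",
    "score_detection",
    "roc_sweep",
    "loocv_detection",
]

# 26-connectivity structuring element for connected components.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionMetrics:
    dice: float
    sensitivity: float
    specificity: float
    both_empty: bool = False
    roc: list[tuple[float, float, float]] | None = None  # (tau, tpr, fpr)
    auc: float | None = None


def detect_by_threshold(zmap: ZMap, tau: float, high_side: bool = False) -> Volume3D:
    """Threshold the Z map: mask = 1 where z < tau inside the valid region.

    ``tau`` is negative for ischemic (low-diffusivity) lesions; with
    ``high_side=True`` the detector instead selects z > |tau|, the
    vasogenic-edema regime.  The inequality is strict: boundary voxels
    are excluded.
    """
    if not np.isfinite(tau):
        raise ValidationError("tau must be finite")
    valid = zmap.valid.data > 0
    if high_side:
        hit = zmap.z.data > abs(tau)
    else:
        hit = zmap.z.data < tau
    return zmap.z.with_data((hit & valid).astype(np.float64))


def _ball(radius: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    x, y, z = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return x * x + y * y + z * z <= r * r


def postprocess_morphology(mask: Volume3D, opening_radius: int = 0,
                           closing_radius: int = 0, min_component: int = 1) -> Volume3D:
    """Binary opening, then closing (ball structuring elements), then
    removal of 26-connected components smaller than ``min_component``."""
    if opening_radius < 0 or closing_radius < 0:
        raise ValidationError("radii must be non-negative")
    m = mask.data > 0
    if opening_radius > 0:
        m = ndimage.binary_opening(m, structure=_ball(opening_radius))
    if closing_radius > 0:
        # dilation then erosion, treating outside-the-grid as foreground in
        # the erosion so closing stays extensive at the array border
        m = ndimage.binary_dilation(m, structure=_ball(closing_radius))
        m = ndimage.binary_erosion(m, structure=_ball(closing_radius),
                                   border_value=1)
    if min_component > 1 and m.any():
        lab, n = ndimage.label(m, structure=CONN26)
        sizes = ndimage.sum_labels(m, lab, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component) + 1
        m = np.isin(lab, keep)
    return mask.with_data(m.astype(np.float64))


def regularize_with_frequency_atlas(prob_map: Volume3D, freq_atlas: Volume3D,
                                    weight: float) -> Volume3D:
    """Blend a detector's probability map with a population lesion prior.

    Returns ``(1-w)*p + w*(p*prior / max(p*prior))``; weight 0 is the
    identity, weight 1 fully trusts the prior-modulated map (a voxel the
    population is never lesioned at is suppressed to 0).
    """
    require_same_grid(prob_map, freq_atlas, "probability map and frequency atlas")
    if not (0.0 <= weight <= 1.0):
        raise ValidationError("weight must lie in [0, 1]")
    f = freq_atlas.data
    if f.min() < 0 or f.max() > 1:
        raise ValidationError("frequency atlas values must lie in [0, 1]")
    p = prob_map.data
    post = p * f
    peak = post.max()
    if peak > 0:
        post = post / peak * p.max()
    return prob_map.with_data((1.0 - weight) * p + weight * post)


@dataclass(frozen=True)
class VoxelClassifierModel:
    """Voxel-wise normal-vs-lesion classifier on hand-crafted features.

    ``channels`` selects which images feed the feature vector ("z",
    "adc" or both); each channel contributes the voxel value plus the
    mean and standard deviation of its neighbourhood within
    ``neighborhood_radius`` voxels.
    """

    channels: tuple[str, ...] = ("z", "adc")
    neighborhood_radius: int = 1
    estimator: object | None = None
    background_ratio: float = 3.0  # background:lesion subsampling ratio
    adapted: bool = False

    def features(self, zmap: ZMap, adc: Volume3D | None) -> np.ndarray:
        cols = []
        size = 2 * self.neighborhood_radius + 1
        for ch in self.channels:
            if ch == "z":
                img = zmap.z.data
            elif ch == "adc":
                if adc is None:
                    raise ValidationError("recipe includes the adc channel but no ADC volume given")
                img = adc.data
            else:
                raise ValidationError(f"unknown channel {ch!r}")
            cols.append(img)
            if self.neighborhood_radius > 0:
                mean = ndimage.uniform_filter(img, size=size)
                sq = ndimage.uniform_filter(img * img, size=size)
                cols.append(mean)
                cols.append(np.sqrt(np.maximum(sq - mean * mean, 0.0)))
        return np.stack([c.ravel() for c in cols], axis=1)

    def predict_proba(self, zmap: ZMap, adc: Volume3D | None) -> Volume3D:
        if self.estimator is None:
            raise ValidationError("model is not fitted")
        X = self.features(zmap, adc)
        p = self.estimator.predict_proba(X)[:, 1].reshape(zmap.z.shape)
        p = p * (zmap.valid.data > 0)
        return zmap.z.with_data(p)


def fit_voxel_classifier(training: Sequence[tuple[ZMap, Volume3D | None, Volume3D]],
                         channels: tuple[str, ...] = ("z", "adc"),
                         neighborhood_radius: int = 1,
                         estimator: object | None = None,
                         background_ratio: float = 3.0,
                         seed: int = 0) -> VoxelClassifierModel:
    """Fit the voxel classifier on (zmap, adc, truth-mask) training cases.

    Background voxels are subsampled to ``background_ratio`` times the
    lesion count to tame class imbalance; the estimator defaults to a
    logistic regression, and any scikit-learn classifier exposing
    ``predict_proba`` (SVM with probability calibration, random forest)
    can be plugged in.
    """
    model = VoxelClassifierModel(channels=channels,
                                 neighborhood_radius=neighborhood_radius,
                                 background_ratio=background_ratio)
    rng = np.random.default_rng(seed)
    Xs, ys = [], []
    for zmap, adc, truth in training:
        X = model.features(zmap, adc)
        y = (truth.data > 0).ravel()
        valid = (zmap.valid.data > 0).ravel()
        pos = np.flatnonzero(y & valid)
        neg = np.flatnonzero(~y & valid)
        if pos.size and neg.size > background_ratio * pos.size:
            neg = rng.choice(neg, size=int(background_ratio * pos.size), replace=False)
        idx = np.concatenate([pos, neg])
        Xs.append(X[idx])
        ys.append(y[idx])
    X = np.concatenate(Xs)
    y = np.concatenate(ys)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set contains a single class")
    if estimator is not None:
        est = clone(estimator)
    else:
        # standardized, class-balanced logistic: channel scales differ by
        # orders of magnitude (z vs raw ADC) and lesions are rare
        est = make_pipeline(StandardScaler(),
                            LogisticRegression(max_iter=1000, class_weight="balanced"))
    est.fit(X, y)
    return replace(model, estimator=est)


def adapt_to_target(model: VoxelClassifierModel, target_z: ZMap,
                    target_adc: Volume3D | None = None,
                    confidence: float = 0.75) -> tuple[Volume3D, VoxelClassifierModel, bool]:
    """Self-adaptive "silver standard" retraining on one target image.

    Voxels the source model labels lesion with probability above
    ``confidence`` become silver lesion samples; those below
    ``1 - confidence`` become silver background.  The classifier is
    refit on the target's own features of those voxels only, then
    re-predicts (threshold 0.5).  If either silver class is empty the
    unadapted prediction is returned and ``adapted`` is False.
    """
    prob = model.predict_proba(target_z, target_adc)
    valid = target_z.valid.data > 0
    unadapted = target_z.z.with_data(((prob.data > 0.5) & valid).astype(np.float64))
    p = prob.data
    silver_pos = (p > confidence) & valid
    silver_neg = (p < 1.0 - confidence) & valid
    if not silver_pos.any() or not silver_neg.any():
        return unadapted, model, False
    X = model.features(target_z, target_adc)
    idx = np.flatnonzero((silver_pos | silver_neg).ravel())
    y = silver_pos.ravel()[idx]
    est = clone(model.estimator)
    est.fit(X[idx], y)
    adapted = replace(model, estimator=est, adapted=True)
    prob2 = adapted.predict_proba(target_z, target_adc)
    mask = target_z.z.with_data(((prob2.data > 0.5) & valid).astype(np.float64))
    return mask, adapted, True


def score_detection(pred: Volume3D, ref: Volume3D,
                    valid: Volume3D | None = None) -> DetectionMetrics:
    """Dice, sensitivity and specificity of a predicted mask vs reference.

    Both masks empty is a legitimate clinical situation (lesion-free
    patients); Dice is then defined as 1 and flagged, so cohort means
    are not poisoned by 0/0.
    """
    require_same_grid(pred, ref, "prediction and reference")
    region = np.ones(pred.shape, dtype=bool)
    if valid is not None:
        require_same_grid(pred, valid, "masks and valid region")
        region = valid.data > 0
    p = (pred.data > 0) & region
    r = (ref.data > 0) & region
    np_, nr = int(p.sum()), int(r.sum())
    inter = int((p & r).sum())
    if np_ == 0 and nr == 0:
        return DetectionMetrics(dice=1.0, sensitivity=1.0, specificity=1.0, both_empty=True)
    dice = 2.0 * inter / (np_ + nr)
    sens = inter / nr if nr else 1.0
    neg = region & ~r
    spec = int((neg & ~p).sum()) / int(neg.sum()) if neg.any() else 1.0
    return DetectionMetrics(dice=dice, sensitivity=sens, specificity=spec)


def roc_sweep(zmap: ZMap, truth: Volume3D, taus: Sequence[float],
              high_side: bool = False) -> DetectionMetrics:
    """TPR/FPR at each threshold plus trapezoidal AUC over sorted FPR.

    The AUC integrates the full sweep of the continuous z statistic
    (every distinct value), so it reflects the ranking quality of z
    rather than only the handful of requested thresholds; the ``roc``
    list reports the operating points at the requested taus.
    """
    valid = zmap.valid.data > 0
    t = (truth.data > 0) & valid
    if not t.any() or t.all():
        raise ValidationError("truth must contain both classes inside the valid region")
    z = zmap.z.data[valid]
    y = (truth.data > 0)[valid]
    points = []
    for tau in taus:
        hit = (z > abs(tau)) if high_side else (z < tau)
        tpr = float((hit & y).sum() / y.sum())
        fpr = float((hit & ~y).sum() / (~y).sum())
        points.append((float(tau), tpr, fpr))
    # rank-based AUC of the continuous statistic (low z ranks as lesion-like);
    # midranks handle ties
    score = z if high_side else -z
    uniq, inv, counts = np.unique(score, return_inverse=True, return_counts=True)
    cum = np.cumsum(counts)
    mid = cum - (counts - 1) / 2.0
    ranks = mid[inv]
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # operating-point metrics at the first requested threshold
    sd = score_detection(detect_by_threshold(zmap, taus[0], high_side=high_side),
                         truth, valid=zmap.valid)
    return DetectionMetrics(dice=sd.dice, sensitivity=sd.sensitivity,
                            specificity=sd.specificity, roc=points, auc=float(auc))


def loocv_detection(cases: Sequence[tuple[ZMap, Volume3D | None, Volume3D]],
                    detector: "ThresholdDetector | ClassifierDetector") -> dict:
    """Leave-one-out evaluation of a detector over a cohort.

    Exactly N folds; each case is the test set once.  Trainable
    detectors are refit on the other N-1 cases per fold; the threshold
    detector ignores the training fold.
    """
    n = len(cases)
    if n < 2:
        raise ValidationError("need at least 2 cases for leave-one-out")
    per_case = []
    folds = []
    for i in range(n):
        train = [cases[j] for j in range(n) if j != i]
        zmap, adc, truth = cases[i]
        mask = detector.fit_predict(train, zmap, adc)
        per_case.append(score_detection(mask, truth).dice)
        folds.append((tuple(j for j in range(n) if j != i), i))
    return {"per_case_dice": per_case, "mean_dice": float(np.mean(per_case)),
            "folds": folds}


@dataclass(frozen=True)
class ThresholdDetector:
    """Stateless detector: threshold at tau plus optional morphology."""

    tau: float = -2.0
    opening_radius: int = 0
    closing_radius: int = 0
    min_component: int = 1
    high_side: bool = False

    def fit_predict(self, train, zmap: ZMap, adc: Volume3D | None) -> Volume3D:
        mask = detect_by_threshold(zmap, self.tau, high_side=self.high_side)
        return postprocess_morphology(mask, self.opening_radius,
                                      self.closing_radius, self.min_component)


@dataclass(frozen=True)
class ClassifierDetector:
    """Trainable detector wrapping the voxel classifier (optionally adaptive)."""

    channels: tuple[str, ...] = ("z", "adc")
    neighborhood_radius: int = 1
    adapt: bool = False
    confidence: float = 0.75
    seed: int = 0

    def fit_predict(self, train, zmap: ZMap, adc: Volume3D | None) -> Volume3D:
        model = fit_voxel_classifier(train, channels=self.channels,
                                     neighborhood_radius=self.neighborhood_radius,
                                     seed=self.seed)
        if self.adapt:
            mask, _, _ = adapt_to_target(model, zmap, adc, confidence=self.confidence)
            return mask
        prob = model.predict_proba(zmap, adc)
        valid = zmap.valid.data > 0
        return zmap.z.with_data(((prob.data > 0.5) & valid).astype(np.float64))
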