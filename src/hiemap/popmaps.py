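"""Population lesion-frequency atlases and voxel-wise lesion-symptom mapping.

The frequency atlas averages binary lesion masks over a cohort: a value
of 0.1 at a voxel means 10% of patients were lesioned there.  VLSM
tests, at every sufficiently-lesioned voxel, whether lesion presence is
associated with a clinical variable — a group label (e.g. treated vs
untreated) or an outcome (binary or continuous) — and controls the
family-wise error across voxels with max-statistic permutation: the
observed per-voxel statistic is compared against the permutation
distribution of the *maximum* statistic over all tested voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hiemap.core_io import ValidationError, Volume3D, require_same_grid

__all__ = [
    "LesionFrequencyAtlas",
    "VLSMResult",
    "build_frequency_atlas",
    "compare_subcohorts",
    "vlsm_outcome",
]

#: Voxels lesioned in fewer than this many patients overall are not tested.
MIN_LESION_COUNT = 5


@dataclass(frozen=True)
class LesionFrequencyAtlas:
    freq: Volume3D
    n_patients: int


@dataclass(frozen=True)
class VLSMResult:
    stat: Volume3D
    p_corr: Volume3D           # family-wise corrected p (1.0 at untested voxels)
    p_uncorr: Volume3D
    sig_mask: Volume3D
    tested: Volume3D
    n_perms: int
    alpha: float
    min_lesion_count: int
    seed: int
    statistic: str
    empty_tested_set: bool = False


def _mask_matrix(masks: list[Volume3D]) -> np.ndarray:
    ref = masks[0]
    for m in masks[1:]:
        require_same_grid(ref, m, "lesion masks")
    return np.stack([(m.data > 0).ravel() for m in masks])


def build_frequency_atlas(masks: list[Volume3D]) -> LesionFrequencyAtlas:
    """Per-voxel fraction of the cohort lesioned at that location."""
    if not masks:
        raise ValidationError("need at least 1 mask")
    M = _mask_matrix(masks)
    freq = M.mean(axis=0).reshape(masks[0].shape)
    return LesionFrequencyAtlas(freq=masks[0].with_data(freq), n_patients=len(masks))


def _prop_score_stat(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Chi-square score statistic, per voxel, for the 2x2 table of
    group/outcome label y against lesion presence M (patients x voxels)."""
    n = y.size
    n1 = M.sum(axis=0).astype(np.float64)          # lesioned patients per voxel
    n0 = n - n1
    k1 = y @ M                                     # positives among lesioned
    k0 = y.sum() - k1
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, k1 / n1, 0.0)
        p0 = np.where(n0 > 0, k0 / n0, 0.0)
        pbar = (k1 + k0) / n
        var = pbar * (1 - pbar) * (1 / np.where(n1 > 0, n1, np.inf)
                                   + 1 / np.where(n0 > 0, n0, np.inf))
        stat = np.where(var > 0, (p1 - p0) ** 2 / var, 0.0)
    return stat


def _t_stat(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute Welch t statistic per voxel: outcome y in lesioned vs
    non-lesioned patients."""
    n1 = M.sum(axis=0).astype(np.float64)
    n0 = M.shape[0] - n1
    s1 = y @ M
    s0 = y.sum() - s1
    sq1 = (y ** 2) @ M
    sq0 = (y ** 2).sum() - sq1
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(n1 > 0, s1 / n1, 0.0)
        m0 = np.where(n0 > 0, s0 / n0, 0.0)
        v1 = np.where(n1 > 1, (sq1 - n1 * m1 ** 2) / (n1 - 1), 0.0)
        v0 = np.where(n0 > 1, (sq0 - n0 * m0 ** 2) / (n0 - 1), 0.0)
        se2 = np.where(n1 > 0, v1 / n1, np.inf) + np.where(n0 > 0, v0 / n0, np.inf)
        stat = np.where(se2 > 0, np.abs(m1 - m0) / np.sqrt(se2), 0.0)
    stat[~np.isfinite(stat)] = 0.0
    return stat


def _maxT_permutation(M: np.ndarray, y: np.ndarray, stat_fn, n_perms: int,
                      seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed stats plus corrected/uncorrected permutation p-values.

    p = (1 + #{perm >= observed}) / (1 + n_perms), so p is never zero;
    the corrected p uses the permutation distribution of the maximum
    statistic across tested voxels (family-wise control).
    """
    rng = np.random.default_rng(seed)
    obs = stat_fn(M, y)
    exceed_max = np.zeros_like(obs)
    exceed_vox = np.zeros_like(obs)
    for _ in range(n_perms):
        yp = rng.permutation(y)
        s = stat_fn(M, yp)
        exceed_max += s.max() >= obs
        exceed_vox += s >= obs
    p_corr = (1.0 + exceed_max) / (1.0 + n_perms)
    p_uncorr = (1.0 + exceed_vox) / (1.0 + n_perms)
    return obs, p_corr, p_uncorr


def _run_vlsm(masks: list[Volume3D], y: np.ndarray, stat_fn, statistic: str,
              n_perms: int, alpha: float, seed: int,
              min_lesion_count: int) -> VLSMResult:
    shape = masks[0].shape
    M_full = _mask_matrix(masks)
    counts = M_full.sum(axis=0)
    tested_flat = counts >= min_lesion_count
    ref = masks[0]

    stat = np.zeros(M_full.shape[1])
    p_corr = np.ones(M_full.shape[1])
    p_uncorr = np.ones(M_full.shape[1])
    empty = not tested_flat.any()
    if not empty:
        M = M_full[:, tested_flat]
        obs, pc, pu = _maxT_permutation(M, y, stat_fn, n_perms, seed)
        stat[tested_flat] = obs
        p_corr[tested_flat] = pc
        p_uncorr[tested_flat] = pu
    sig = (p_corr < alpha) & tested_flat
    return VLSMResult(
        stat=ref.with_data(stat.reshape(shape)),
        p_corr=ref.with_data(p_corr.reshape(shape)),
        p_uncorr=ref.with_data(p_uncorr.reshape(shape)),
        sig_mask=ref.with_data(sig.reshape(shape).astype(np.float64)),
        tested=ref.with_data(tested_flat.reshape(shape).astype(np.float64)),
        n_perms=n_perms, alpha=alpha, min_lesion_count=min_lesion_count,
        seed=seed, statistic=statistic, empty_tested_set=empty,
    )


def compare_subcohorts(masks_a: list[Volume3D], masks_b: list[Volume3D],
                       n_perms: int = 10_000, alpha: float = 0.05, seed: int = 0,
                       min_lesion_count: int = MIN_LESION_COUNT) -> VLSMResult:
    """Voxel-wise comparison of lesion frequency between two sub-cohorts.

    Per voxel, a chi-square score statistic on the difference of lesion
    proportions between the groups; group labels are permuted
    ``n_perms`` times and family-wise corrected with the max statistic.
    Only voxels lesioned in at least ``min_lesion_count`` patients
    overall are tested.
    """
    if not masks_a or not masks_b:
        raise ValidationError("both sub-cohorts must be nonempty")
    masks = list(masks_a) + list(masks_b)
    group = np.array([1.0] * len(masks_a) + [0.0] * len(masks_b))
    # group membership plays the role of the outcome in the 2x2 score test
    return _run_vlsm(masks, group, _prop_score_stat, "chi2-score-proportions",
                     n_perms, alpha, seed, min_lesion_count)


def vlsm_outcome(masks: list[Volume3D], outcome: np.ndarray,
                 n_perms: int = 10_000, alpha: float = 0.05, seed: int = 0,
                 min_lesion_count: int = MIN_LESION_COUNT) -> VLSMResult:
    """Voxel-wise lesion-symptom mapping against a clinical outcome.

    Binary outcomes use the 2x2 chi-square score statistic (lesion
    presence x outcome); continuous outcomes use an absolute Welch t
    statistic comparing outcome in lesioned vs non-lesioned patients.
    Outcome labels are permuted with max-statistic family-wise
    correction; significance defaults to p < 0.05 after 10,000
    permutations.
    """
    y = np.asarray(outcome, dtype=np.float64)
    if y.size != len(masks):
        raise ValidationError("outcome length must equal the number of masks")
    is_binary = np.isin(y, (0.0, 1.0)).all()
    if is_binary:
        if len(np.unique(y)) < 2:
            raise ValidationError("binary outcome has a single class")
        return _run_vlsm(masks, y, _prop_score_stat, "chi2-score-2x2",
                         n_perms, alpha, seed, min_lesion_count)
    return _run_vlsm(masks, y, _t_stat, "welch-t", n_perms, alpha, seed,
                     min_lesion_count)
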