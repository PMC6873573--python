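"""Radiomic feature extraction, outcome derivation and expert-score encoding.

Two complementary feature families feed outcome prediction:

* lesion-based features — anatomy (which regions/tracts are injured and
  how much), geometry (volume, diameters, surface, sphericity),
  first-order intensity statistics and second-order textures (GLCM,
  GLRLM) of ADC and Z values inside the detected lesion;
* lesion-free features — per-region and per-tract intensity statistics
  of ADC and Z over the whole brain plus left/right asymmetries, so
  patients without a detectable lesion still get an informative vector.

The module also encodes the NICHD-NRN ordinal expert severity score
from regional injury flags and derives binary 2-year outcomes from
BSID-III scores and documentation flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage, stats

from hiemap.core_io import (
    OutcomeRecord,
    RegionLabelMap,
    ValidationError,
    Volume3D,
    require_same_grid,
)

__all__ = [
    "RegionInjuryFlags",
    "nichd_score",
    "derive_outcomes",
    "intensity_stats",
    "texture_features",
    "lesion_anatomy_features",
    "lesion_geometry_features",
    "lesion_feature_vector",
    "lesion_free_feature_vector",
]

ENTROPY_BINS = 32
GLCM_LEVELS = 16
ASYM_EPS = 1e-12

#: The 13 unique 3-D unit displacement directions (symmetric accumulation
#: makes the opposite 13 redundant).
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

NICHD_LEVELS = ("0", "1A", "1B", "2A", "2B", "3")


@dataclass(frozen=True)
class RegionInjuryFlags:
    """Regional injury pattern feeding the NICHD-NRN severity score."""

    bgt: int = 0    # basal ganglia / thalamus infarction
    alic: int = 0   # anterior limb of internal capsule
    plic: int = 0   # posterior limb of internal capsule
    ws: int = 0     # watershed infarction
    cerebral_lesions: str = "none"  # none | minimal | extensive
    hemispheric_devastation: int = 0

    def __post_init__(self) -> None:
        if self.cerebral_lesions not in ("none", "minimal", "extensive"):
            raise ValidationError(f"unknown cerebral_lesions {self.cerebral_lesions!r}")


def nichd_score(flags: RegionInjuryFlags) -> str:
    """NICHD-NRN 2012 ordinal severity score from regional injury flags.

    3 hemispheric devastation; 2B deep-gray/capsule/watershed infarction
    plus any other cerebral lesions; 2A such infarction alone; 1B
    extensive cerebral lesions without it; 1A minimal cerebral lesions
    only; 0 normal.
    """
    infarct = flags.bgt or flags.alic or flags.plic or flags.ws
    if flags.hemispheric_devastation:
        return "3"
    if infarct:
        return "2B" if flags.cerebral_lesions != "none" else "2A"
    if flags.cerebral_lesions == "extensive":
        return "1B"
    if flags.cerebral_lesions == "minimal":
        return "1A"
    return "0"


def derive_outcomes(bsid_cognitive: float | None = None,
                    bsid_language: float | None = None,
                    bsid_motor: float | None = None,
                    documented_delay: int | None = None,
                    documented_motor_abnormality: int | None = None,
                    documented_cerebral_palsy: int | None = None,
                    documented_visual_hearing: int | None = None,
                    deceased_at_discharge: int | None = None) -> OutcomeRecord:
    """Derive binary 2-year outcomes from BSID-III scores and documentation.

    Developmental delay is positive when any BSID-III domain score is
    <= 85 (boundary inclusive) or delay is documented; motor impairment
    when the motor score is <= 85 or a motor abnormality is documented.
    Missing inputs propagate to missing outputs — absence of
    documentation is never read as a negative finding.
    """
    scores = (bsid_cognitive, bsid_language, bsid_motor)
    for s in scores:
        if s is not None and not (50.0 <= s <= 150.0):
            raise ValidationError(f"BSID score {s} outside [50, 150]")

    def _or_rule(score_hit: bool | None, flag: int | None) -> int | None:
        # tri-state OR: 1 dominates, then missing, then 0
        if score_hit or flag == 1:
            return 1
        if score_hit is None and flag is None:
            return None
        if score_hit is None or flag is None:
            return None
        return 0

    known = [s for s in scores if s is not None]
    any_low: bool | None
    if known and any(s <= 85.0 for s in known):
        any_low = True
    elif len(known) == 3:
        any_low = False
    else:
        any_low = None  # some domain unknown and no known domain is low

    motor_low: bool | None = None if bsid_motor is None else bsid_motor <= 85.0

    return OutcomeRecord(
        bsid_cognitive=bsid_cognitive,
        bsid_language=bsid_language,
        bsid_motor=bsid_motor,
        developmental_delay=_or_rule(any_low, documented_delay),
        motor_impairment=_or_rule(motor_low, documented_motor_abnormality),
        cerebral_palsy=documented_cerebral_palsy,
        visual_hearing_impairment=documented_visual_hearing,
        deceased_at_discharge=deceased_at_discharge,
    )


def intensity_stats(values: np.ndarray, prefix: str = "",
                    entropy_bins: int = ENTROPY_BINS) -> dict[str, float]:
    """First-order statistics of an intensity sample.

    Percentiles {0, 25, 50, 75, 100} (linear interpolation), mean,
    stdev, Fisher skewness, excess kurtosis, Shannon entropy (base 2)
    over ``entropy_bins`` equal-width bins, and uniformity (sum of
    squared bin probabilities).  A constant sample is a legitimate
    degenerate case: skewness and kurtosis are defined as 0, entropy 0,
    uniformity 1.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValidationError("empty intensity sample")
    out: dict[str, float] = {}
    for q in (0, 25, 50, 75, 100):
        out[f"{prefix}p{q:03d}"] = float(np.percentile(v, q))
    out[f"{prefix}mean"] = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    out[f"{prefix}std"] = sd
    if sd == 0.0:
        out[f"{prefix}skewness"] = 0.0
        out[f"{prefix}kurtosis"] = 0.0
        out[f"{prefix}entropy"] = 0.0
        out[f"{prefix}uniformity"] = 1.0
        return out
    out[f"{prefix}skewness"] = float(stats.skew(v))
    out[f"{prefix}kurtosis"] = float(stats.kurtosis(v))  # excess
    hist, _ = np.histogram(v, bins=entropy_bins)
    pbin = hist / hist.sum()
    nz = pbin[pbin > 0]
    out[f"{prefix}entropy"] = float(-(nz * np.log2(nz)).sum())
    out[f"{prefix}uniformity"] = float((pbin ** 2).sum())
    return out


def _quantize(image: np.ndarray, region: np.ndarray, levels: int) -> np.ndarray:
    vals = image[region]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return np.zeros_like(image, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _glcm(q: np.ndarray, region: np.ndarray, levels: int,
          offsets) -> np.ndarray:
    """Symmetric gray-level co-occurrence matrix accumulated over offsets,
    counting only voxel pairs with both ends inside the region."""
    glcm = np.zeros((levels, levels), dtype=np.float64)
    for off in offsets:
        src = [slice(max(0, -o), min(s, s - o)) for o, s in zip(off, q.shape)]
        dst = [slice(max(0, o), min(s, s + o)) for o, s in zip(off, q.shape)]
        both = region[tuple(src)] & region[tuple(dst)]
        a = q[tuple(src)][both]
        b = q[tuple(dst)][both]
        np.add.at(glcm, (a, b), 1.0)
        np.add.at(glcm, (b, a), 1.0)  # symmetric accumulation
    return glcm


def _glcm_features(glcm: np.ndarray, prefix: str) -> dict[str, float]:
    total = glcm.sum()
    if total == 0:
        return {f"{prefix}contrast": 0.0, f"{prefix}energy": 1.0,
                f"{prefix}homogeneity": 1.0, f"{prefix}correlation": 0.0}
    P = glcm / total
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = float(((i - j) ** 2 * P).sum())
    energy = float((P ** 2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    sd_i = np.sqrt(float(((i - mu_i) ** 2 * P).sum()))
    sd_j = np.sqrt(float(((j - mu_j) ** 2 * P).sum()))
    if sd_i > 0 and sd_j > 0:
        correlation = float((((i - mu_i) * (j - mu_j) * P).sum()) / (sd_i * sd_j))
    else:
        correlation = 0.0  # constant region, degenerate
    return {f"{prefix}contrast": contrast, f"{prefix}energy": energy,
            f"{prefix}homogeneity": homogeneity, f"{prefix}correlation": correlation}


def _runs_along_axis(q: np.ndarray, region: np.ndarray, axis: int) -> list[int] | np.ndarray:
    """Run lengths of constant gray level along one axis, inside the region."""
    q = np.moveaxis(q, axis, -1)
    region = np.moveaxis(region, axis, -1)
    lengths = []
    lines = q.reshape(-1, q.shape[-1])
    masks = region.reshape(-1, region.shape[-1])
    for line, m in zip(lines, masks):
        run = 0
        prev = None
        for val, inside in zip(line, m):
            if inside and (prev is None or val == prev):
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 1 if inside else 0
            prev = val if inside else None
        if run:
            lengths.append(run)
    return np.asarray(lengths, dtype=np.float64)


def _glrlm_features(q: np.ndarray, region: np.ndarray, prefix: str) -> dict[str, float]:
    out = {}
    per_axis_lre = []
    all_runs = []
    for axis, name in enumerate("xyz"):
        runs = _runs_along_axis(q, region, axis)
        all_runs.append(runs)
        if runs.size:
            per_axis_lre.append(float((runs ** 2).mean()))
            out[f"{prefix}long_run_emphasis_{name}"] = float((runs ** 2).mean())
        else:
            out[f"{prefix}long_run_emphasis_{name}"] = 0.0
    runs = np.concatenate([r for r in all_runs if r.size]) if any(r.size for r in all_runs) \
        else np.asarray([1.0])
    out[f"{prefix}short_run_emphasis"] = float((1.0 / runs ** 2).mean())
    out[f"{prefix}long_run_emphasis"] = float((runs ** 2).mean())
    # run-length non-uniformity, normalized by run count
    lengths, counts = np.unique(runs, return_counts=True)
    out[f"{prefix}run_length_nonuniformity"] = float((counts ** 2).sum() / counts.sum())
    return out


def texture_features(image: Volume3D, region: Volume3D, prefix: str = "",
                     levels: int = GLCM_LEVELS,
                     offsets=GLCM_OFFSETS) -> dict[str, float]:
    """GLCM and GLRLM texture features of an image inside a region.

    The image is quantized to ``levels`` equal-width gray levels over
    the region's intensity range.  GLCM is accumulated symmetrically
    over the 13 unique 3-D unit directions (by default); GLRLM runs are
    measured along each axis.  A constant region degenerates to a
    single co-occurrence cell: energy 1, contrast 0.
    """
    require_same_grid(image, region, "image and region")
    mask = region.data > 0
    if mask.sum() < 2:
        raise ValidationError("texture region must contain at least 2 voxels")
    q = _quantize(image.data, mask, levels)
    out = _glcm_features(_glcm(q, mask, levels, offsets), prefix + "glcm_")
    out.update(_glrlm_features(q, mask, prefix + "glrlm_"))
    return out


def lesion_anatomy_features(mask: Volume3D, labels: RegionLabelMap,
                            tracts: RegionLabelMap | None = None,
                            prefix: str = "lesion.anatomy.") -> dict[str, float]:
    """Where the lesion sits: per-region injured fractions, whole-brain
    injured fraction, lesion mass-center (world mm), left/right injured
    volume ratios per declared pair, and per-tract lesion percentages.

    An empty mask yields zero fractions and missing (NaN) mass-center,
    flagged by the caller via the NaN values themselves.
    """
    require_same_grid(mask, labels, "mask and label map")
    m = mask.data > 0
    lab = labels.labels
    brain = lab > 0
    n_brain = int(brain.sum())
    out: dict[str, float] = {}
    out[f"{prefix}whole_brain_fraction"] = float((m & brain).sum() / max(n_brain, 1))

    if m.any():
        idx = np.argwhere(m)
        center_vox = idx.mean(axis=0)
        world = labels.affine @ np.append(center_vox, 1.0)
        for axis, name in enumerate("xyz"):
            out[f"{prefix}mass_center_{name}"] = float(world[axis])
    else:
        for name in "xyz":
            out[f"{prefix}mass_center_{name}"] = float("nan")

    region_frac = {}
    for rid in labels.region_ids:
        inside = lab == rid
        frac = float((m & inside).sum() / max(int(inside.sum()), 1))
        region_frac[rid] = frac
        out[f"{prefix}region_fraction.{labels.names[rid]}"] = frac
    for left, right in labels.pairs:
        lv, rv = region_frac.get(left, 0.0), region_frac.get(right, 0.0)
        out[f"{prefix}lr_ratio.{labels.names[left]}_{labels.names[right]}"] = \
            lv / rv if rv > 0 else (1.0 if lv == 0 else float("inf"))
        out[f"{prefix}lr_asym.{labels.names[left]}_{labels.names[right]}"] = \
            (lv - rv) / (lv + rv + ASYM_EPS)

    if tracts is not None:
        require_same_grid(mask, tracts, "mask and tract map")
        n_lesion = int(m.sum())
        for tid in tracts.region_ids:
            inside = tracts.labels == tid
            hit = int((m & inside).sum())
            out[f"{prefix}tract_fraction.{tracts.names[tid]}"] = \
                hit / max(int(inside.sum()), 1)
            out[f"{prefix}tract_distribution.{tracts.names[tid]}"] = \
                hit / n_lesion if n_lesion else 0.0
    return out


def _surface_area(m: np.ndarray, spacing) -> float:
    """Total boundary surface by counting exposed voxel faces."""
    sx, sy, sz = spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        pad = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.abs(np.diff(pad.astype(np.int8), axis=axis))
        area += fa * float(diff.sum())
    return area


def _mesh_surface_area(m: np.ndarray, spacing) -> float:
    """Marching-cubes mesh area: close to the true surface for smooth
    shapes, where raw face counting overestimates by up to ~50%."""
    from skimage import measure

    padded = np.pad(m.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    return float(measure.mesh_surface_area(verts, faces))


def lesion_geometry_features(mask: Volume3D,
                             prefix: str = "lesion.geometry.") -> dict[str, float]:
    """Shape descriptors of the lesion mask (aggregate over components).

    Volume (mm^3), axis-aligned maximum diameters (mm), total surface
    area by exposed-face counting (mm^2), sphericity
    pi^(1/3)*(6V)^(2/3)/A, compactness (volume over bounding-box
    volume), surface-to-volume ratio, largest axial (z-slice)
    cross-section area (mm^2), and the number of connected components.
    Two sphericity variants are emitted: ``sphericity`` uses the
    face-counted area (exact closed forms for cubes), while
    ``sphericity_mesh`` uses a marching-cubes mesh area, which is the
    right estimator for smooth shapes — the staircase bias of face
    counting caps a perfect digital sphere's sphericity near 0.67.
    """
    m = mask.data > 0
    if not m.any():
        raise ValidationError("geometry features undefined for an empty mask")
    sx, sy, sz = mask.spacing
    vol = float(m.sum()) * mask.voxel_volume
    idx = np.argwhere(m)
    extents = idx.max(axis=0) - idx.min(axis=0) + 1
    diam = (extents[0] * sx, extents[1] * sy, extents[2] * sz)
    area = _surface_area(m, mask.spacing)
    mesh_area = _mesh_surface_area(m, mask.spacing)
    sphericity = float(np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area)
    sphericity_mesh = float(np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / mesh_area)
    bbox_vol = float(diam[0] * diam[1] * diam[2])
    structure = np.ones((3, 3, 3), dtype=bool)
    _, n_comp = ndimage.label(m, structure=structure)
    axial = m.sum(axis=(0, 1)).max() * sx * sy  # largest z-slice cross-section
    return {
        f"{prefix}volume_mm3": vol,
        f"{prefix}max_diameter_x_mm": float(diam[0]),
        f"{prefix}max_diameter_y_mm": float(diam[1]),
        f"{prefix}max_diameter_z_mm": float(diam[2]),
        f"{prefix}surface_area_mm2": area,
        f"{prefix}largest_axial_cross_section_mm2": float(axial),
        f"{prefix}sphericity": sphericity,
        f"{prefix}sphericity_mesh": sphericity_mesh,
        f"{prefix}compactness": vol / bbox_vol,
        f"{prefix}surface_to_volume": area / vol,
        f"{prefix}n_components": float(n_comp),
    }


def lesion_feature_vector(adc: Volume3D, zmap, mask: Volume3D,
                          labels: RegionLabelMap,
                          tracts: RegionLabelMap | None = None) -> dict[str, float]:
    """Full lesion-based feature row (anatomy + geometry + intensity +
    texture of ADC and Z inside the lesion).

    An empty lesion returns an all-NaN row of the same names, routing
    the patient to the lesion-free prediction branch.
    """
    m = mask.data > 0
    if not m.any():
        # NaN row with the same inventory: probe a two-voxel lesion in-brain
        inside = np.argwhere(labels.labels > 0)
        probe = np.zeros(mask.shape)
        probe[tuple(inside[0])] = 1.0
        probe[tuple(inside[1])] = 1.0
        probe_row = lesion_feature_vector(adc, zmap, mask.with_data(probe),
                                          labels, tracts)
        return {name: float("nan") for name in probe_row}
    out = lesion_anatomy_features(mask, labels, tracts)
    out.update(lesion_geometry_features(mask))
    out.update(intensity_stats(adc.data[m], prefix="lesion.histogram.adc."))
    out.update(intensity_stats(zmap.z.data[m], prefix="lesion.histogram.z."))
    if m.sum() >= 2:
        out.update(texture_features(adc, mask, prefix="lesion.texture.adc."))
        out.update(texture_features(zmap.z, mask, prefix="lesion.texture.z."))
    return out


_FEATURE_NAME_CACHE: list[str] | None = None


def lesion_feature_names() -> list[str]:
    """Deterministic inventory of the lesion-based feature names,
    derived from a canonical two-voxel probe lesion."""
    global _FEATURE_NAME_CACHE
    if _FEATURE_NAME_CACHE is None:
        from hiemap.atlas import ZMap
        from hiemap.synthetic import PhantomSpec, make_parcellation
        spec = PhantomSpec(shape=(16, 16, 12))
        brain_mask, label_map = make_parcellation(spec)
        data = np.zeros(spec.shape)
        c = tuple(s // 2 for s in spec.shape)
        data[c] = 1.0
        data[c[0] + 1, c[1], c[2]] = 1.0
        mask = Volume3D(data, spacing=spec.spacing)
        vol = Volume3D(np.random.default_rng(0).random(spec.shape),
                       spacing=spec.spacing)
        zmap = ZMap(z=vol, valid=brain_mask)
        row = lesion_feature_vector(vol, zmap, mask, label_map)
        _FEATURE_NAME_CACHE = list(row)
    return list(_FEATURE_NAME_CACHE)


def lesion_free_feature_vector(adc: Volume3D, zmap, labels: RegionLabelMap,
                               tracts: RegionLabelMap | None = None) -> dict[str, float]:
    """Lesion-free feature row: per-region (and per-tract) intensity
    statistics of ADC and Z, region volumes, and left/right asymmetry of
    every paired feature.  No lesion detection is needed.
    """
    lab = labels.labels
    out: dict[str, float] = {}
    brain = lab > 0
    out.update(intensity_stats(adc.data[brain], prefix="free.region.brain.adc."))
    out.update(intensity_stats(zmap.z.data[brain], prefix="free.region.brain.z."))
    voxvol = adc.voxel_volume

    per_region: dict[int, dict[str, float]] = {}
    for rid in labels.region_ids:
        inside = lab == rid
        name = labels.names[rid]
        if not inside.any():
            continue
        stats_r = {}
        stats_r.update(intensity_stats(adc.data[inside], prefix="adc."))
        stats_r.update(intensity_stats(zmap.z.data[inside], prefix="z."))
        stats_r["volume_mm3"] = float(inside.sum()) * voxvol
        per_region[rid] = stats_r
        for key, val in stats_r.items():
            out[f"free.region.{name}.{key}"] = val

    for left, right in labels.pairs:
        if left not in per_region or right not in per_region:
            continue
        lname = labels.names[left]
        rname = labels.names[right]
        for key in per_region[left]:
            lv, rv = per_region[left][key], per_region[right][key]
            out[f"free.asym.{lname}_{rname}.{key}"] = (lv - rv) / (abs(lv) + abs(rv) + ASYM_EPS)

    if tracts is not None:
        for tid in tracts.region_ids:
            inside = tracts.labels == tid
            if not inside.any():
                continue
            name = tracts.names[tid]
            out.update(intensity_stats(adc.data[inside], prefix=f"free.tract.{name}.adc."))
            out.update(intensity_stats(zmap.z.data[inside], prefix=f"free.tract.{name}.z."))
    return out
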