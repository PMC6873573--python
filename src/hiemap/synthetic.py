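"""Synthetic phantom cohorts with known ground truth.

The generator emulates the structure of a neonatal ADC study: spatially
varying normal diffusivity (region-wise mean/stdev), focal lesions with
abnormally low (ischemic) or high (vasogenic) diffusivity expressed in
sigma units, multiplicative/additive site effects, imperfect rater
annotations with stated sensitivity/specificity, and an outcome model
linking lesion burden in an eloquent region to binary and continuous
2-year outcomes.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from hiemap.core_io import (
    OutcomeRecord,
    RegionLabelMap,
    ValidationError,
    Volume3D,
)

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "SiteEffect",
    "OutcomeModelSpec",
    "PatientCase",
    "make_parcellation",
    "population_atlas",
    "make_controls",
    "make_patient",
    "simulate_raters",
]

# Plausible neonatal ADC band, units 1e-6 mm^2/s.
ADC_BAND = (800.0, 1800.0)

DEFAULT_SHAPE = (32, 32, 24)
DEFAULT_REGION_MEANS = (1050.0, 1050.0, 1200.0, 1200.0, 1350.0, 1350.0)
DEFAULT_REGION_SDS = (60.0, 60.0, 60.0, 60.0, 60.0, 60.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and normal-tissue statistics of the phantom brain.

    The default is a 32x32x24 grid at 1 mm isotropic with a 6-region
    parcellation that is mirror-symmetric about the x midline (three
    left/right pairs), with region mean ADC values inside the plausible
    neonatal band of 800-1800 x 1e-6 mm^2/s.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions: int = 6
    region_mean_adc: tuple[float, ...] = DEFAULT_REGION_MEANS
    region_sd_adc: tuple[float, ...] = DEFAULT_REGION_SDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions % 2 != 0:
            raise ValidationError("n_regions must be even (mirror-symmetric pairs)")
        if len(self.region_mean_adc) != self.n_regions:
            raise ValidationError("region_mean_adc length must equal n_regions")
        if len(self.region_sd_adc) != self.n_regions:
            raise ValidationError("region_sd_adc length must equal n_regions")
        if any(sd <= 0 for sd in self.region_sd_adc):
            raise ValidationError("region_sd_adc must be strictly positive")
        lo, hi = ADC_BAND
        if any(not (lo <= m <= hi) for m in self.region_mean_adc):
            raise ValidationError(f"region means must lie in the neonatal band {ADC_BAND}")


@dataclass(frozen=True)
class LesionSpec:
    """One focal lesion, specified as a deviation in sigma units.

    ``z_offset < 0`` produces an ischemic (low-ADC) lesion, ``> 0`` a
    vasogenic (high-ADC) one.  Specifying the lesion in sigma units makes
    its ground-truth Z value known by construction.
    """

    center: tuple[int, int, int]
    radius_mm: float
    z_offset: float
    shape: str = "sphere"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValidationError("lesion radius must be positive")
        if self.shape not in ("sphere", "blob"):
            raise ValidationError(f"unknown lesion shape {self.shape!r}")


@dataclass(frozen=True)
class SiteEffect:
    """Per-site intensity transform v -> scale*v + offset."""

    scale: float = 1.0
    offset: float = 0.0
    site_id: str = "site0"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError("site scale must be positive")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.scale * values + self.offset


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Outcome generator: logistic adverse-outcome risk and a linear
    Bayley motor score, both driven by the lesion fraction of one
    designated eloquent region (e.g. the corticospinal tract)."""

    eloquent_region: int = 5
    beta0: float = -4.0
    beta1: float = 8.0
    bayley_base: float = 100.0
    bayley_slope: float = -60.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    def adverse_probability(self, lesion_fraction: float) -> float:
        x = self.beta0 + self.beta1 * lesion_fraction
        return float(1.0 / (1.0 + np.exp(-x)))


@dataclass(frozen=True)
class PatientCase:
    """A simulated patient with its ground truth."""

    volume: Volume3D
    true_mask: Volume3D
    outcome: OutcomeRecord
    site_id: str
    lesion_fraction: float  # of the eloquent region
    adverse_probability: float = field(default=np.nan)


def _brain_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoidal brain mask and mirror-symmetric parcellation labels."""
    nx, ny, nz = spec.shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = nx * 0.45, ny * 0.45, nz * 0.45
    brain = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    n_pairs = spec.n_regions // 2
    # Slabs along z, each split left/right about the x midline.
    slab = np.minimum((z * n_pairs) // max(nz, 1), n_pairs - 1)
    left = x < cx  # world x below midline under the identity RAS affine
    labels = np.where(left, 2 * slab + 1, 2 * slab + 2)
    labels = np.where(brain, labels, 0).astype(np.int64)
    return brain, labels


def make_parcellation(spec: PhantomSpec) -> tuple[Volume3D, RegionLabelMap]:
    """Brain mask and symmetric parcellation for a phantom spec."""
    brain, labels = _brain_geometry(spec)
    names = {}
    laterality = {}
    pairs = []
    for p in range(spec.n_regions // 2):
        l_id, r_id = 2 * p + 1, 2 * p + 2
        names[l_id] = f"region{p}_left"
        names[r_id] = f"region{p}_right"
        laterality[l_id] = "left"
        laterality[r_id] = "right"
        pairs.append((l_id, r_id))
    mask = Volume3D(brain.astype(np.float64), spacing=spec.spacing)
    label_map = RegionLabelMap(labels=labels, names=names, laterality=laterality,
                               pairs=pairs, spacing=spec.spacing)
    return mask, label_map


def _region_param_volumes(spec: PhantomSpec,
                          labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = np.zeros(spec.shape)
    sd = np.ones(spec.shape)
    for rid in range(1, spec.n_regions + 1):
        inside = labels == rid
        mean[inside] = spec.region_mean_adc[rid - 1]
        sd[inside] = spec.region_sd_adc[rid - 1]
    return mean, sd


def population_atlas(spec: PhantomSpec):
    """Analytic normative atlas with the phantom's exact population
    mean/stdev per voxel (no sampling noise), for noise-free experiments
    where ground-truth Z values must hold exactly."""
    from hiemap.atlas import NormativeAtlas

    brain_mask, label_map = make_parcellation(spec)
    mean, sd = _region_param_volumes(spec, label_map.labels)
    brain = brain_mask.data > 0
    mean = np.where(brain, mean, 0.0)
    sd = np.where(brain, sd, 0.0)
    ref = brain_mask
    return NormativeAtlas(mu=ref.with_data(mean), sigma=ref.with_data(sd),
                          support=brain_mask, n_controls=2)


def make_controls(spec: PhantomSpec, n: int, seed: int | None = None
                  ) -> tuple[list[Volume3D], Volume3D, RegionLabelMap]:
    """Draw ``n`` control volumes voxel-wise ~ Normal(region mean, region sd).

    Returns the controls, the shared brain mask and the parcellation.
    At least two controls are required, otherwise the atlas stdev is
    undefined.
    """
    if n < 2:
        raise ValidationError("need at least 2 controls (atlas stdev undefined)")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    brain_mask, label_map = make_parcellation(spec)
    mean, sd = _region_param_volumes(spec, label_map.labels)
    brain = brain_mask.data > 0
    controls = []
    for _ in range(n):
        vals = rng.normal(mean, sd)
        vals[~brain] = 0.0
        controls.append(Volume3D(vals, spacing=spec.spacing))
    return controls, brain_mask, label_map


def _rasterize_lesion(spec: PhantomSpec, les: LesionSpec, brain: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    nx, ny, nz = spec.shape
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = les.center
    sx, sy, sz = spec.spacing
    coords = [(x - cx) * sx, (y - cy) * sy, (z - cz) * sz]
    if les.shape == "blob":
        # irregular lesion: sphere with a random axis stretched
        axis = int(rng.integers(0, 3))
        coords[axis] = coords[axis] / (1.0 + 0.5 * rng.random())
    d2 = coords[0] ** 2 + coords[1] ** 2 + coords[2] ** 2
    this = d2 <= les.radius_mm ** 2
    if not np.all(brain[this]):
        raise ValidationError(f"lesion at {les.center} extends outside the brain mask")
    return this


def make_patient(spec: PhantomSpec,
                 lesions: Sequence[LesionSpec] = (),
                 site: SiteEffect | None = None,
                 outcome_model: OutcomeModelSpec | None = None,
                 seed: int = 0, noise: bool = True) -> PatientCase:
    """Simulate one patient: control-like tissue, lesions, site effect, outcome.

    Inside each lesion the voxel value is shifted by ``z_offset * sigma``
    of its region *before* the site transform ``v -> scale*v + offset``
    is applied, so that after Z-mapping against a matched-site atlas the
    lesion's mean Z equals ``z_offset`` in expectation.  With
    ``noise=False`` the tissue is set exactly to its region mean (a
    noise-free phantom), making lesion Z values exact by construction.
    """
    site = site or SiteEffect()
    outcome_model = outcome_model or OutcomeModelSpec()
    rng = np.random.default_rng(seed)
    brain_mask, label_map = make_parcellation(spec)
    brain = brain_mask.data > 0
    mean, sd = _region_param_volumes(spec, label_map.labels)
    if outcome_model.eloquent_region not in label_map.names:
        raise ValidationError(
            f"eloquent region {outcome_model.eloquent_region} not in parcellation")

    vals = rng.normal(mean, sd) if noise else mean.copy()
    singles = [_rasterize_lesion(spec, les, brain, rng) for les in lesions]
    signs = np.zeros(spec.shape)
    for les, single in zip(lesions, singles):
        sign = np.sign(les.z_offset)
        if sign != 0 and np.any(single & (signs != 0) & (signs != sign)):
            raise ValidationError("overlapping lesions with conflicting signs")
        signs[single] = np.where(sign != 0, sign, signs[single])
        vals[single] += les.z_offset * sd[single]
    lesion = np.zeros(spec.shape, dtype=bool)
    for single in singles:
        lesion |= single
    vals = site.apply(vals)
    vals[~brain] = 0.0

    eloquent = label_map.labels == outcome_model.eloquent_region
    frac = float((lesion & eloquent).sum() / max(eloquent.sum(), 1))
    p_adverse = outcome_model.adverse_probability(frac)
    adverse = int(rng.random() < p_adverse)
    bayley = outcome_model.bayley_base + outcome_model.bayley_slope * frac \
        + rng.normal(0.0, outcome_model.noise_sd)
    bayley = float(np.clip(bayley, 50.0, 150.0))
    outcome = OutcomeRecord(bsid_motor=bayley, motor_impairment=adverse,
                            developmental_delay=adverse)
    return PatientCase(
        volume=Volume3D(vals, spacing=spec.spacing),
        true_mask=Volume3D(lesion.astype(np.float64), spacing=spec.spacing),
        outcome=outcome,
        site_id=site.site_id,
        lesion_fraction=frac,
        adverse_probability=p_adverse,
    )


def simulate_raters(truth: Volume3D, n_raters: int, sens: float, spec: float,
                    seed: int = 0, brain_mask: Volume3D | None = None
                    ) -> list[Volume3D]:
    """Simulate independent expert annotations of a true lesion mask.

    Each rater marks a lesion voxel positive with probability ``sens``
    and a background voxel positive with probability ``1 - spec``,
    independently per voxel.  A rater who finds nothing returns a blank
    (all-zero) mask, matching clinical practice for lesion-free scans.
    """
    if not (0 < sens <= 1) or not (0 < spec <= 1):
        raise ValidationError("sens and spec must lie in (0, 1]")
    t = truth.data > 0
    rng = np.random.default_rng(seed)
    region = np.ones_like(t) if brain_mask is None else brain_mask.data > 0
    masks = []
    for _ in range(n_raters):
        u = rng.random(t.shape)
        ann = np.where(t, u < sens, u < (1.0 - spec)) & region
        masks.append(truth.with_data(ann.astype(np.float64)))
    return masks
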