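"""Voxel-wise normative atlas construction and Z deviation mapping.

From ``n`` control diffusivity volumes the atlas stores the per-voxel
sample mean mu(v) and sample standard deviation sigma(v) (divisor n-1).
A patient image y is converted to a deviation map

    z(u) = (y(u) - mu(v)) / sigma(v)

at every voxel inside the atlas support intersected with the patient's
brain mask.  With the sample-stdev convention, z-mapping the atlas's own
controls gives per-voxel mean exactly 0 and sample variance exactly 1 —
a self-consistency property the tests enforce.  Because z is invariant
to any affine intensity transform applied jointly to the controls and
the patient, Z maps are comparable across scanners and sites.

Patient-to-atlas spatial correspondence is a pluggable interface; the
default is the identity (inputs already co-registered), and deformable
registration is delegated to external tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from hiemap.core_io import ValidationError, Volume3D, require_same_grid

__all__ = ["NormativeAtlas", "ZMap", "build_atlas", "compute_z_map"]

#: sigma floor, relative to the global mean mu: voxels below it leave the support.
SIGMA_FLOOR_REL = 1e-6


@dataclass(frozen=True)
class NormativeAtlas:
    """Per-voxel normal diffusivity model: mean, stdev and support mask."""

    mu: Volume3D
    sigma: Volume3D
    support: Volume3D
    n_controls: int
    n_floored: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValidationError("atlas needs at least 2 controls")
        inside = self.support.data > 0
        if not np.all(self.sigma.data[inside] > 0):
            raise ValidationError("sigma must be positive inside the support")


@dataclass(frozen=True)
class ZMap:
    """Deviation-from-normal map; ``valid`` flags where z is defined."""

    z: Volume3D
    valid: Volume3D

    def __post_init__(self) -> None:
        inside = self.valid.data > 0
        if not np.all(np.isfinite(self.z.data[inside])):
            raise ValidationError("z must be finite inside the valid region")


def build_atlas(controls: Sequence[Volume3D], brain_mask: Volume3D,
                sigma_floor_rel: float = SIGMA_FLOOR_REL) -> NormativeAtlas:
    """Build the voxel-wise mean/stdev atlas from control volumes.

    Voxels whose stdev falls below ``sigma_floor_rel`` times the global
    mean diffusivity are excluded from the support (and counted) rather
    than producing arbitrarily large Z values downstream.
    """
    if len(controls) < 2:
        raise ValidationError("need at least 2 controls")
    ref = controls[0]
    for c in controls[1:]:
        require_same_grid(ref, c, "control volumes")
    require_same_grid(ref, brain_mask, "controls and brain mask")
    mask = brain_mask.data > 0
    if not mask.any():
        raise ValidationError("brain mask is empty")

    stack = np.stack([c.data for c in controls])
    mu = stack.mean(axis=0)
    sigma = stack.std(axis=0, ddof=1)
    mu[~mask] = 0.0
    sigma[~mask] = 0.0

    floor = sigma_floor_rel * float(np.abs(mu[mask]).mean())
    degenerate = mask & (sigma <= floor)
    support = mask & ~degenerate
    n_floored = int(degenerate.sum())
    if not support.any():
        raise ValidationError("degenerate atlas: every in-mask voxel fell below the sigma floor")
    return NormativeAtlas(
        mu=ref.with_data(mu),
        sigma=ref.with_data(sigma),
        support=ref.with_data(support.astype(np.float64)),
        n_controls=len(controls),
        n_floored=n_floored,
    )


def compute_z_map(patient: Volume3D, atlas: NormativeAtlas,
                  patient_mask: Volume3D | None = None,
                  registration: Callable[[Volume3D], Volume3D] | None = None) -> ZMap:
    """Convert a patient volume into a Z deviation map against the atlas.

    ``registration`` maps the patient onto the atlas grid; the default
    identity requires the grids to already match.  The valid region is
    the atlas support intersected with the patient's brain mask; outside
    it z is stored as 0 but flagged invalid, never silently trusted.
    """
    if registration is not None:
        patient = registration(patient)
    require_same_grid(patient, atlas.mu, "patient and atlas")
    valid = atlas.support.data > 0
    if patient_mask is not None:
        require_same_grid(patient_mask, atlas.mu, "patient mask and atlas")
        valid = valid & (patient_mask.data > 0)
    if not valid.any():
        raise ValidationError("empty valid region: atlas support and patient mask do not overlap")
    z = np.zeros(patient.shape)
    z[valid] = (patient.data[valid] - atlas.mu.data[valid]) / atlas.sigma.data[valid]
    return ZMap(z=patient.with_data(z), valid=patient.with_data(valid.astype(np.float64)))
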