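"""Volume, label-map and cohort-table data model with NIfTI/CSV I/O.

All volumes are carried as :class:`Volume3D`: a 3-D scalar array plus
voxel spacing and a 4x4 voxel-to-world affine.  Volumes are canonicalized
to RAS axis order on load so that "left hemisphere" always means world
x below the midline, which laterality features rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "RegionLabelMap",
    "CohortTable",
    "OutcomeRecord",
    "ValidationError",
    "read_volume",
    "write_volume",
    "check_same_grid",
    "load_cohort",
]

#: Relative tolerance on voxel spacings when deciding two grids match.
SPACING_RTOL = 1e-6
#: Absolute tolerance on affine entries when deciding two grids match.
AFFINE_ATOL = 1e-4

BSID_RANGE = (50.0, 150.0)

BSID_COLUMNS = ("bsid_cognitive", "bsid_language", "bsid_motor")
BINARY_OUTCOME_COLUMNS = (
    "developmental_delay",
    "cerebral_palsy",
    "motor_impairment",
    "visual_hearing_impairment",
    "deceased_at_discharge",
)


class ValidationError(ValueError):
    """Raised when an input violates a documented data invariant."""


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar grid with voxel spacing and an affine into world space.

    Parameters
    ----------
    data:
        3-D array of finite reals (float64).  NaN/Inf are rejected unless
        covered by ``missing_mask``.
    spacing:
        Voxel edge lengths ``(sx, sy, sz)`` in millimetres; strictly positive.
    affine:
        4x4 voxel-index to world-coordinate map.
    space_tag:
        ``"atlas"`` for images already in the common atlas space,
        ``"native"`` otherwise.
    missing_mask:
        Optional boolean array marking voxels where NaN is permitted.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    space_tag: str = "atlas"
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=np.float64))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValidationError(f"expected a 3-D volume, got shape {data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        bad = ~np.isfinite(data)
        if self.missing_mask is not None:
            bad = bad & ~np.asarray(self.missing_mask, dtype=bool)
        n_bad = int(bad.sum())
        if n_bad:
            raise ValidationError(
                f"{n_bad} non-finite voxel(s) outside the declared missing-data mask"
            )
        if self.space_tag not in ("atlas", "native"):
            raise ValidationError(f"unknown space_tag {self.space_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same grid, new voxel values."""
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass(frozen=True)
class RegionLabelMap:
    """Integer parcellation on a :class:`Volume3D` grid.

    Label 0 is reserved for background.  ``laterality`` assigns each label
    to the left or right hemisphere or the midline; left/right labels are
    declared in ``pairs`` so asymmetry features know which regions mirror
    each other.
    """

    labels: np.ndarray
    names: Mapping[int, str]
    laterality: Mapping[int, str] = field(default_factory=dict)
    pairs: Sequence[tuple[int, int]] = ()
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, labels.astype(np.int64)):
                raise ValidationError("labels must be integers")
            labels = labels.astype(np.int64)
        if labels.min() < 0:
            raise ValidationError("labels must be non-negative (0 = background)")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=np.float64))
        present = set(int(v) for v in np.unique(labels)) - {0}
        missing = present - set(int(k) for k in self.names)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} have no name entry")
        for left, right in self.pairs:
            if self.laterality.get(left) != "left" or self.laterality.get(right) != "right":
                raise ValidationError(f"pair ({left}, {right}) not declared left/right")

    @property
    def region_ids(self) -> list[int]:
        return sorted(int(k) for k in self.names)


@dataclass(frozen=True)
class OutcomeRecord:
    """Two-year neurodevelopmental outcomes for one patient.

    BSID-III domain scores live in [50, 150]; binary flags are 0/1.
    ``None`` encodes a genuinely missing value — absence of documentation
    is never coerced to a negative finding.
    """

    bsid_cognitive: float | None = None
    bsid_language: float | None = None
    bsid_motor: float | None = None
    developmental_delay: int | None = None
    cerebral_palsy: int | None = None
    motor_impairment: int | None = None
    visual_hearing_impairment: int | None = None
    deceased_at_discharge: int | None = None

    def __post_init__(self) -> None:
        for name in BSID_COLUMNS:
            v = getattr(self, name)
            if v is not None and not (BSID_RANGE[0] <= v <= BSID_RANGE[1]):
                raise ValidationError(f"{name}={v} outside BSID-III range {BSID_RANGE}")
        for name in BINARY_OUTCOME_COLUMNS:
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValidationError(f"{name}={v} must be 0, 1 or missing")


class CohortTable:
    """Patients-by-variables clinical table keyed by unique patient id.

    Thin wrapper over a pandas DataFrame that enforces unique ids and
    BSID score ranges, and keeps missing cells as NaN (never 0).
    """

    def __init__(self, frame: pd.DataFrame, id_column: str = "patient_id"):
        if id_column not in frame.columns:
            raise ValidationError(f"cohort table needs a {id_column!r} column")
        ids = frame[id_column].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate patient ids: {dupes}")
        frame = frame.copy()
        frame[id_column] = ids
        for col in BSID_COLUMNS:
            if col in frame.columns:
                vals = pd.to_numeric(frame[col], errors="coerce")
                bad = vals.notna() & ((vals < BSID_RANGE[0]) | (vals > BSID_RANGE[1]))
                if bad.any():
                    raise ValidationError(
                        f"{col} outside [50, 150] for ids {list(frame.loc[bad, id_column])}"
                    )
                frame[col] = vals
        self.frame = frame.set_index(id_column, drop=False)
        self.id_column = id_column

    @property
    def patient_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def outcome(self, patient_id: str) -> OutcomeRecord:
        row = self.frame.loc[patient_id]

        def _get(col: str, as_int: bool = False):
            if col not in row or pd.isna(row[col]):
                return None
            return int(row[col]) if as_int else float(row[col])

        return OutcomeRecord(
            bsid_cognitive=_get("bsid_cognitive"),
            bsid_language=_get("bsid_language"),
            bsid_motor=_get("bsid_motor"),
            developmental_delay=_get("developmental_delay", as_int=True),
            cerebral_palsy=_get("cerebral_palsy", as_int=True),
            motor_impairment=_get("motor_impairment", as_int=True),
            visual_hearing_impairment=_get("visual_hearing_impairment", as_int=True),
            deceased_at_discharge=_get("deceased_at_discharge", as_int=True),
        )


def read_volume(path: str | Path, space_tag: str = "atlas",
                missing_mask: np.ndarray | None = None) -> Volume3D:
    """Read a NIfTI-1 volume and canonicalize its axes to RAS order.

    Raises :class:`ValidationError` when the file contains NaN/Inf voxels
    not covered by ``missing_mask``, reporting the offending voxel count.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read {path} as NIfTI: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, spacing=spacing, affine=np.asarray(img.affine),
                    space_tag=space_tag, missing_mask=missing_mask)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a :class:`Volume3D` to NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def check_same_grid(a, b) -> bool:
    """True iff two volumes share shape, spacing and affine within tolerance.

    Spacings compare with relative tolerance 1e-6; affines with absolute
    tolerance 1e-4.  Every cross-volume operation in the package requires
    this predicate to hold.
    """
    shape_a = a.labels.shape if hasattr(a, "labels") else a.shape
    shape_b = b.labels.shape if hasattr(b, "labels") else b.shape
    if tuple(shape_a) != tuple(shape_b):
        return False
    sa, sb = np.asarray(a.spacing), np.asarray(b.spacing)
    if not np.allclose(sa, sb, rtol=SPACING_RTOL, atol=0.0):
        return False
    return bool(np.allclose(a.affine, b.affine, atol=AFFINE_ATOL, rtol=0.0))


def require_same_grid(a, b, what: str = "volumes") -> None:
    if not check_same_grid(a, b):
        raise ValidationError(f"{what} are not on the same grid")


def load_cohort(path: str | Path, id_column: str = "patient_id") -> CohortTable:
    """Load a cohort CSV (header row, unique patient ids).

    Empty cells become explicit missing values; they are never silently
    interpreted as zero or as a negative finding.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    frame = pd.read_csv(path)
    return CohortTable(frame, id_column=id_column)
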