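"""Domain types and grid geometry shared by every stage of the workflow.

All spatial quantities are in millimetres, in world coordinates. Voxel
indices are 0-based and a voxel's world position is the position of its
*centre*: ``world = origin + index * spacing`` per axis. Grids are
axis-aligned; oblique DICOM orientations are rectified at import.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Grid3D",
    "DoseGrid",
    "StructureMask",
    "PrescriptionSet",
    "DoseStructure",
    "PatientCase",
    "CohortTRE",
    "RecurrenceSphere",
    "ClassificationResult",
    "RISK_ORDER",
    "centroid",
    "resample_mask_to_grid",
    "EmptyMaskError",
]

#: Canonical ordering of risk levels, highest prescribed dose first.
RISK_ORDER = ("high", "intermediate", "low")


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty structure mask."""


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned 3-D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z).
    spacing
        Voxel size in mm along each axis; strictly positive.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must be a 3-vector")

    # -- coordinate transforms ------------------------------------------------

    def index_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel centres at (fractional) indices."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, point) -> np.ndarray:
        """Fractional voxel index of world points (mm)."""
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def containing_index(self, point) -> np.ndarray:
        """Integer index of the voxel containing each world point.

        Half-up rounding of the fractional index: a point on the boundary
        between two voxels belongs to the higher-index one.
        """
        return np.floor(self.world_to_index(point) + 0.5).astype(int)

    def contains_point(self, point) -> bool:
        """True if the point lies within the grid's voxel extent.

        The extent runs from half a voxel before the first centre to half a
        voxel past the last centre along each axis.
        """
        f = self.world_to_index(point)
        return bool(np.all(f >= -0.5) and np.all(f <= np.asarray(self.shape) - 0.5))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))

    def same_geometry(self, other: "Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True)
class DoseGrid:
    """Absorbed-dose lattice in Gy (finite, non-negative)."""

    grid: Grid3D
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("dose values must be finite")
        if np.any(values < 0):
            raise ValueError("dose values must be non-negative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class StructureMask:
    """Named binary mask on a voxel grid (ROI, rGTV, or derived dose structure)."""

    name: str
    grid: Grid3D
    voxels: np.ndarray

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask array shape {voxels.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "voxels", voxels)

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3


@dataclass(frozen=True)
class PrescriptionSet:
    """Prescribed dose per risk level, ordered high > intermediate > low.

    Between one and three levels; labels unique; doses strictly decreasing
    from high to low.
    """

    levels: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        levels = tuple((str(label), float(dose)) for label, dose in self.levels)
        if not 1 <= len(levels) <= 3:
            raise ValueError("prescriptions must contain between 1 and 3 levels")
        labels = [label for label, _ in levels]
        if any(label not in RISK_ORDER for label in labels):
            raise ValueError(f"risk labels must be in {RISK_ORDER}, got {labels}")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate risk labels: {labels}")
        # store in canonical high -> low order
        levels = tuple(sorted(levels, key=lambda lv: RISK_ORDER.index(lv[0])))
        doses = [dose for _, dose in levels]
        if any(d <= 0 for d in doses):
            raise ValueError("prescribed doses must be positive")
        if any(doses[i] <= doses[i + 1] for i in range(len(doses) - 1)):
            raise ValueError(
                f"prescribed doses must strictly decrease high -> low, got {levels}"
            )
        object.__setattr__(self, "levels", levels)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PrescriptionSet":
        """Build from e.g. ``{"high": 53, "intermediate": 40, "low": 36}``."""
        return cls(tuple(mapping.items()))

    def as_dict(self) -> dict:
        return dict(self.levels)

    def dose_for(self, label: str) -> float:
        for lv, dose in self.levels:
            if lv == label:
                return dose
        raise KeyError(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.levels)


@dataclass(frozen=True)
class DoseStructure:
    """A 95%-of-prescription dose structure: voxels receiving >= threshold.

    ``mean_dose`` is the arithmetic mean of the dose over the mask voxels,
    ``None`` when the mask is empty (the plan never reaches the threshold).
    """

    risk_label: str
    threshold: float
    mask: StructureMask
    mean_dose: Optional[float]

    @property
    def is_empty(self) -> bool:
        return self.mask.is_empty


@dataclass(frozen=True)
class CohortTRE:
    """Cohort-level target registration error summary.

    mean/sd over per-patient TREs (sample sd, n-1 denominator, 0 for n=1);
    ``outlier_ids`` are patients flagged by the configured outlier rule.
    """

    per_patient: tuple[tuple[str, float], ...]
    mean_mm: float
    sd_mm: float
    outlier_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.per_patient)


@dataclass(frozen=True)
class RecurrenceSphere:
    """Ball of radius = cohort TRE around the mapped rGTV centroid.

    Represents registration localisation uncertainty: voxels whose centres
    lie within ``radius_mm`` of ``centre``; radius 0 degenerates to the single
    voxel containing the centre.
    """

    centre: tuple[float, float, float]
    radius_mm: float
    mask: StructureMask


@dataclass(frozen=True)
class PatientCase:
    """One patient's inputs, all representable on the planning dose grid."""

    patient_id: str
    dose: DoseGrid
    rgtv_mapped: StructureMask
    prescriptions: PrescriptionSet
    tre_roi_fixed: Optional[StructureMask] = None
    tre_roi_mapped: Optional[StructureMask] = None
    tre_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rgtv_mapped.is_empty:
            raise EmptyMaskError(
                f"case {self.patient_id}: mapped rGTV mask is empty"
            )


@dataclass(frozen=True)
class ClassificationResult:
    """Failure category plus the diagnostics it was derived from.

    The category is re-derivable from the diagnostics: centroid membership
    level plus the sphere pass fraction against that level's structure.
    """

    patient_id: str
    category: str
    centroid_world_mm: tuple[float, float, float]
    centroid_dose: float
    centroid_level: Optional[str]
    sphere_pass_fraction: dict[str, Optional[float]]
    structure_mean_doses: dict[str, Optional[float]]
    structure_thresholds: dict[str, float]
    sphere_radius_mm: float

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "category": self.category,
            "centroid_world_mm": list(self.centroid_world_mm),
            "centroid_dose_gy": self.centroid_dose,
            "centroid_level": self.centroid_level,
            "sphere_pass_fraction": dict(self.sphere_pass_fraction),
            "structure_mean_doses_gy": dict(self.structure_mean_doses),
            "structure_thresholds_gy": dict(self.structure_thresholds),
            "sphere_radius_mm": self.sphere_radius_mm,
        }


# -- operations ---------------------------------------------------------------


def centroid(mask: StructureMask) -> np.ndarray:
    """Unweighted mean of the world coordinates of all voxel centres in the mask.

    Raises
    ------
    EmptyMaskError
        If the mask has no voxels (centroid undefined).
    """
    if mask.is_empty:
        raise EmptyMaskError(f"centroid of empty mask {mask.name!r} is undefined")
    idx = np.argwhere(mask.voxels)
    return mask.grid.index_to_world(idx.mean(axis=0))


def resample_mask_to_grid(mask: StructureMask, target: Grid3D) -> StructureMask:
    """Nearest-neighbour resampling of a binary mask onto a target grid.

    Each target voxel takes the value of the source voxel containing its
    centre. Resampling onto the mask's own grid is the identity. Target
    voxels whose centres fall outside the source extent are 0; if the
    extents do not overlap at all the result is empty and a warning is
    emitted.
    """
    if mask.grid.same_geometry(target):
        return StructureMask(mask.name, target, mask.voxels.copy())

    out = np.zeros(target.shape, dtype=bool)
    # axis-aligned grids: the nearest-source-index map is separable per axis
    axis_maps = []
    axis_valid = []
    for ax in range(3):
        coords = target.axis_coords(ax)
        f = (coords - mask.grid.origin[ax]) / mask.grid.spacing[ax]
        nearest = np.floor(f + 0.5).astype(int)
        valid = (nearest >= 0) & (nearest < mask.grid.shape[ax])
        axis_maps.append(np.clip(nearest, 0, mask.grid.shape[ax] - 1))
        axis_valid.append(valid)

    if any(not v.any() for v in axis_valid):
        warnings.warn(
            f"mask {mask.name!r}: no overlap between source and target extents; "
            "resampled mask is empty",
            stacklevel=2,
        )
        return StructureMask(mask.name, target, out)

    sampled = mask.voxels[np.ix_(*axis_maps)]
    valid = (
        axis_valid[0][:, None, None]
        & axis_valid[1][None, :, None]
        & axis_valid[2][None, None, :]
    )
    out = sampled & valid
    return StructureMask(mask.name, target, out)
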