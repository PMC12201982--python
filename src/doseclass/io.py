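"""File-format adapters, case manifests and workflow configuration.

Native interchange format is NIfTI (dose, binary masks, 4-D displacement
fields) plus JSON case manifests and a YAML config. A DICOM adapter reads
RT Dose (applying ``DoseGridScaling``) and RT Structure Sets (contours
rasterised onto the dose lattice, voxel-centre-in-polygon on the nearest
slice). Only axis-aligned geometries are supported in the core; sign-flipped
DICOM/NIfTI axes are rectified at import and genuinely oblique orientations
are rejected with a clear error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pydicom
import yaml
from matplotlib.path import Path as MplPath

from .core import DoseGrid, Grid3D, PrescriptionSet, StructureMask
from .registration import DisplacementField

__all__ = [
    "load_dose_nifti",
    "save_dose_nifti",
    "load_mask_nifti",
    "save_mask_nifti",
    "load_displacement_field_nifti",
    "save_displacement_field_nifti",
    "load_rtdose",
    "load_rtstruct",
    "CaseManifest",
    "WorkflowConfig",
    "load_cohort_manifest",
]


# -- NIfTI --------------------------------------------------------------------


def _grid_to_affine(grid: Grid3D) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def _grid_and_data_from_nifti(img, tol: float = 1e-4):
    """Rectify a (possibly sign-flipped) diagonal affine into a core grid."""
    affine = img.affine
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > tol * max(1.0, np.max(np.abs(rot))):
        raise ValueError(
            "oblique NIfTI orientation is not supported; resample the volume "
            "to an axis-aligned grid first"
        )
    data = np.asarray(img.dataobj)
    spacing = np.diag(rot).copy()
    origin = affine[:3, 3].copy()
    for ax in range(3):
        if spacing[ax] < 0:  # flip axis so spacing is positive
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
            spacing[ax] = -spacing[ax]
    grid = Grid3D(tuple(data.shape[:3]), tuple(spacing), tuple(origin))
    return grid, data


def load_dose_nifti(path) -> DoseGrid:
    grid, data = _grid_and_data_from_nifti(nib.load(str(path)))
    if data.ndim != 3:
        raise ValueError(f"dose volume must be 3-D, got shape {data.shape}")
    return DoseGrid(grid, np.asarray(data, dtype=float))


def save_dose_nifti(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), _grid_to_affine(dose.grid))
    nib.save(img, str(path))


def load_mask_nifti(path, name: Optional[str] = None) -> StructureMask:
    grid, data = _grid_and_data_from_nifti(nib.load(str(path)))
    if data.ndim != 3:
        raise ValueError(f"mask volume must be 3-D, got shape {data.shape}")
    return StructureMask(name or Path(path).stem.split(".")[0], grid, data > 0.5)


def save_mask_nifti(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8), _grid_to_affine(mask.grid)
    )
    nib.save(img, str(path))


def load_displacement_field_nifti(path) -> DisplacementField:
    """4-D NIfTI vector volume: last axis holds (dx, dy, dz) in mm."""
    grid, data = _grid_and_data_from_nifti(nib.load(str(path)))
    data = np.squeeze(np.asarray(data, dtype=float))
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"displacement field must be 4-D with 3 components, got {data.shape}"
        )
    return DisplacementField(grid, data)


def save_displacement_field_nifti(dvf: DisplacementField, path) -> None:
    img = nib.Nifti1Image(
        dvf.vectors.astype(np.float32), _grid_to_affine(dvf.grid)
    )
    nib.save(img, str(path))


# -- DICOM RT -----------------------------------------------------------------


def load_rtdose(source) -> DoseGrid:
    """Read a DICOM RT Dose into Gy.

    ``source`` may be a path or an open ``pydicom.Dataset``. Stored pixel
    values are multiplied by ``DoseGridScaling``; units must be GY.
    """
    ds = source if isinstance(source, pydicom.Dataset) else pydicom.dcmread(str(source))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ValueError(
            f"expected DICOM modality RTDOSE, got {getattr(ds, 'Modality', None)!r}"
        )
    units = getattr(ds, "DoseUnits", "").upper()
    if units != "GY":
        raise ValueError(f"dose units must be GY, got {units!r}")
    orient = np.asarray(getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    if not np.allclose(np.abs(orient), [1, 0, 0, 0, 1, 0], atol=1e-4):
        raise ValueError("oblique RT Dose orientation is not supported")

    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols) = (z, y, x)
    values = np.transpose(arr, (2, 1, 0))

    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if len(offsets) > 1 and not np.allclose(dz, dz[0], atol=1e-6):
        raise ValueError("non-uniform GridFrameOffsetVector is not supported")
    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
    dzv = float(dz[0]) if len(offsets) > 1 else 1.0
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    origin[2] += float(offsets[0])

    spacing = np.array([dx, dy, dzv])
    for ax, sign in enumerate([orient[0], orient[4], np.sign(dzv) or 1.0]):
        if ax == 2:
            if dzv < 0:
                values = np.flip(values, axis=2)
                origin[2] += dzv * (values.shape[2] - 1)
                spacing[2] = -dzv
            continue
        if sign < 0:
            values = np.flip(values, axis=ax)
            origin[ax] -= spacing[ax] * (values.shape[ax] - 1)

    grid = Grid3D(values.shape, tuple(spacing), tuple(origin))
    return DoseGrid(grid, values)


def load_rtstruct(source, grid: Grid3D, roi_names=None) -> dict[str, StructureMask]:
    """Rasterise RT Structure Set contours onto a grid.

    Each closed planar contour is assigned to the nearest z-slice and voxel
    centres inside the polygon are set. Returns ``{roi_name: mask}`` for the
    requested names (all ROIs when ``roi_names`` is None).
    """
    ds = source if isinstance(source, pydicom.Dataset) else pydicom.dcmread(str(source))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise ValueError(
            f"expected DICOM modality RTSTRUCT, got {getattr(ds, 'Modality', None)!r}"
        )
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in ds.StructureSetROISequence
    }
    wanted = set(roi_names) if roi_names is not None else None

    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    slice_points = np.column_stack([xx.ravel(), yy.ravel()])

    out: dict[str, StructureMask] = {}
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), str(roi.ReferencedROINumber))
        if wanted is not None and name not in wanted:
            continue
        voxels = np.zeros(grid.shape, dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            if getattr(contour, "ContourGeometricType", "CLOSED_PLANAR") != "CLOSED_PLANAR":
                continue
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            k = int(round((pts[:, 2].mean() - grid.origin[2]) / grid.spacing[2]))
            if not 0 <= k < grid.shape[2]:
                continue
            inside = MplPath(pts[:, :2]).contains_points(slice_points)
            voxels[:, :, k] |= inside.reshape(grid.shape[0], grid.shape[1])
        out[name] = StructureMask(name, grid, voxels)
    if wanted is not None and (missing := wanted - set(out)):
        raise ValueError(f"ROIs not found in structure set: {sorted(missing)}")
    return out


# -- manifests and configuration ----------------------------------------------


@dataclass(frozen=True)
class CaseManifest:
    """Paths and metadata for one patient case.

    Exactly one of three TRE inputs must be supplied: a fixed/mapped ROI
    pair, a precomputed ``tre_mm``, or a displacement field plus the
    relapse-space ROI (which the workflow warps itself).
    """

    patient_id: str
    dose_path: str
    rgtv_path: str
    roi_fixed_path: Optional[str] = None
    roi_mapped_path: Optional[str] = None
    tre_mm: Optional[float] = None
    dvf_path: Optional[str] = None
    roi_relapse_path: Optional[str] = None
    prescriptions: Optional[dict] = None

    def __post_init__(self) -> None:
        sources = [
            self.roi_fixed_path is not None and self.roi_mapped_path is not None,
            self.tre_mm is not None,
            self.dvf_path is not None and self.roi_relapse_path is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                f"case {self.patient_id}: exactly one TRE source must be given "
                "(ROI pair, precomputed tre_mm, or displacement field + relapse "
                f"ROI); got {sum(sources)}"
            )
        if sources[2] and self.roi_fixed_path is None:
            raise ValueError(
                f"case {self.patient_id}: the displacement-field TRE source also "
                "needs roi_fixed_path (the planning-CT ROI to compare against)"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "CaseManifest":
        return cls(**d)

    def referenced_paths(self) -> list[str]:
        paths = [self.dose_path, self.rgtv_path]
        for p in (
            self.roi_fixed_path,
            self.roi_mapped_path,
            self.dvf_path,
            self.roi_relapse_path,
        ):
            if p is not None:
                paths.append(p)
        return paths

    def check_paths(self, base: Optional[Path] = None) -> None:
        for p in self.referenced_paths():
            full = (base / p) if base is not None else Path(p)
            if not full.exists():
                raise FileNotFoundError(f"case {self.patient_id}: missing file {full}")


def load_cohort_manifest(path) -> list[CaseManifest]:
    """Read a cohort manifest: JSON ``{"cases": [{...}, ...]}``."""
    path = Path(path)
    data = json.loads(path.read_text())
    cases = [CaseManifest.from_dict(d) for d in data["cases"]]
    base = path.parent
    for case in cases:
        case.check_paths(base)
    return cases


@dataclass(frozen=True)
class WorkflowConfig:
    """Tunable knobs of the classification workflow.

    prescriptions
        Default prescribed dose per risk level (Gy); a case manifest may
        override per patient.
    dose_fraction
        Fraction of the prescription that defines a dose structure
        (default 0.95).
    sphere_pass_threshold
        Minimum fraction of sphere voxels at/above the structure mean for a
        "central" call (default 0.95, inclusive).
    outlier_rule
        ``mean_plus_3sd`` (default) or the literal ``3sd``.
    sphere_radius_from
        ``post_exclusion_mean`` (default): recompute the cohort mean TRE
        after dropping flagged outliers; ``raw_mean`` keeps them in.
    centroid_rule
        ``threshold`` (default) or ``structure_mean`` membership.
    """

    prescriptions: dict = field(
        default_factory=lambda: {"high": 53.0, "intermediate": 40.0, "low": 36.0}
    )
    dose_fraction: float = 0.95
    sphere_pass_threshold: float = 0.95
    outlier_rule: str = "mean_plus_3sd"
    sphere_radius_from: str = "post_exclusion_mean"
    centroid_rule: str = "threshold"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.outlier_rule not in ("mean_plus_3sd", "3sd"):
            raise ValueError(f"unknown outlier_rule {self.outlier_rule!r}")
        if self.sphere_radius_from not in ("post_exclusion_mean", "raw_mean"):
            raise ValueError(f"unknown sphere_radius_from {self.sphere_radius_from!r}")
        if self.centroid_rule not in ("threshold", "structure_mean"):
            raise ValueError(f"unknown centroid_rule {self.centroid_rule!r}")
        if not 0 < self.dose_fraction <= 1:
            raise ValueError("dose_fraction must be in (0, 1]")
        if not 0 <= self.sphere_pass_threshold <= 1:
            raise ValueError("sphere_pass_threshold must be in [0, 1]")
        PrescriptionSet.from_dict(self.prescriptions)  # validate

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def prescription_set(self) -> PrescriptionSet:
        return PrescriptionSet.from_dict(self.prescriptions)

    def config_hash(self) -> str:
        """Short stable hash of the configuration, embedded in reports."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
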