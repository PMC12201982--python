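"""Registration quality assurance: per-patient and cohort TRE, outlier
flagging, and the recurrence-sphere radius.

The deformable registration itself (landmark alignment, rigid, B-spline) is
deliberately outside this package: research teams run their own registration
locally and supply either a precomputed displacement field, an already-mapped
ROI pair, or a per-patient TRE. This module quantifies what the registration
achieved and turns the cohort-level error into the radius of the recurrence
sphere used downstream in classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    CohortTRE,
    EmptyMaskError,
    Grid3D,
    RecurrenceSphere,
    StructureMask,
    centroid,
)

__all__ = [
    "DisplacementField",
    "warp_mask",
    "patient_tre",
    "cohort_tre",
    "build_sphere",
]


@dataclass(frozen=True)
class DisplacementField:
    """Forward displacement field on a planning-space lattice.

    ``vectors[i, j, k]`` is the mm displacement that carries a relapse-space
    point onto its planning-space position; the identity registration has
    all-zero vectors. Warping inverts the field per voxel (see
    :func:`warp_mask`).
    """

    grid: Grid3D
    vectors: np.ndarray

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vector array shape {vectors.shape} != grid shape + (3,) "
                f"{self.grid.shape + (3,)}"
            )
        object.__setattr__(self, "vectors", vectors)

    @classmethod
    def identity(cls, grid: Grid3D) -> "DisplacementField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    @classmethod
    def translation(cls, grid: Grid3D, shift_mm) -> "DisplacementField":
        """Uniform field displacing every point by ``shift_mm``."""
        vec = np.broadcast_to(np.asarray(shift_mm, float), grid.shape + (3,))
        return cls(grid, vec.copy())

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.vectors == 0))


def _grid_world_coords(grid: Grid3D) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-centre world coordinates."""
    axes = [grid.axis_coords(ax) for ax in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def warp_mask(mask: StructureMask, field: DisplacementField) -> StructureMask:
    """Transport a binary mask by a displacement field.

    Output voxels live on the field's grid; a voxel at world position ``x``
    is set when the pulled-back point ``x - v(x)`` falls inside the input
    mask (nearest-neighbour lookup). A uniform field of vector ``t``
    therefore shifts the mask by ``+t``, and the identity field returns the
    input mask unchanged.

    Raises
    ------
    ValueError
        If the field does not cover the mask's grid extent.
    """
    mg, fg = mask.grid, field.grid
    lo_m = np.asarray(mg.origin) - np.asarray(mg.spacing) / 2
    hi_m = lo_m + np.asarray(mg.shape) * np.asarray(mg.spacing)
    lo_f = np.asarray(fg.origin) - np.asarray(fg.spacing) / 2
    hi_f = lo_f + np.asarray(fg.shape) * np.asarray(fg.spacing)
    if np.any(lo_m < lo_f - 1e-9) or np.any(hi_m > hi_f + 1e-9):
        raise ValueError(
            f"displacement field extent does not cover mask {mask.name!r} extent"
        )

    coords = _grid_world_coords(fg) - field.vectors  # pulled-back points
    frac = (coords - np.asarray(mg.origin)) / np.asarray(mg.spacing)
    nearest = np.floor(frac + 0.5).astype(int)
    inside = np.all((nearest >= 0) & (nearest < np.asarray(mg.shape)), axis=-1)
    out = np.zeros(fg.shape, dtype=bool)
    idx = nearest[inside]
    out[inside] = mask.voxels[idx[:, 0], idx[:, 1], idx[:, 2]]
    return StructureMask(mask.name, fg, out)


def patient_tre(roi_fixed: StructureMask, roi_mapped: StructureMask) -> float:
    """Per-patient target registration error in mm.

    Euclidean distance between the centroid of the ROI delineated on the
    planning CT and the centroid of the equivalent ROI mapped from the
    relapse CT into planning space.
    """
    if roi_fixed.is_empty:
        raise EmptyMaskError("fixed (planning-CT) ROI is empty; TRE undefined")
    if roi_mapped.is_empty:
        raise EmptyMaskError("mapped (relapse-CT) ROI is empty; TRE undefined")
    return float(np.linalg.norm(centroid(roi_fixed) - centroid(roi_mapped)))


def cohort_tre(
    tres: list[tuple[str, float]],
    outlier_rule: str = "mean_plus_3sd",
) -> CohortTRE:
    """Cohort mean/sd of per-patient TREs and registration-outlier flags.

    Parameters
    ----------
    tres
        ``(patient_id, tre_mm)`` pairs, one per patient.
    outlier_rule
        ``"mean_plus_3sd"`` (default) flags patients with
        ``tre > mean + 3*sd``; ``"3sd"`` applies the literal
        ``tre > 3*sd`` reading.

    The standard deviation uses the sample (n-1) denominator and is 0 for a
    single patient, so a one-patient cohort never flags an outlier.
    """
    if not tres:
        raise ValueError("cohort_tre requires at least one patient")
    if outlier_rule not in ("mean_plus_3sd", "3sd"):
        raise ValueError(f"unknown outlier_rule {outlier_rule!r}")
    values = np.array([t for _, t in tres], dtype=float)
    if np.any(values < 0):
        raise ValueError("TRE values must be non-negative")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    cut = mean + 3 * sd if outlier_rule == "mean_plus_3sd" else 3 * sd
    outliers = tuple(pid for (pid, t) in tres if sd > 0 and t > cut)
    return CohortTRE(
        per_patient=tuple((str(p), float(t)) for p, t in tres),
        mean_mm=mean,
        sd_mm=sd,
        outlier_ids=outliers,
    )


def build_sphere(
    centre,
    radius_mm: float,
    target: Grid3D,
    name: str = "recurrence_sphere",
) -> RecurrenceSphere:
    """Rasterise the recurrence sphere onto a grid.

    The mask contains every voxel whose centre lies within ``radius_mm``
    (closed ball) of ``centre``, plus always the voxel containing the
    centre, so a radius of 0 yields exactly that single voxel. If the ball
    extends past the grid it is clipped with a warning.
    """
    centre = np.asarray(centre, dtype=float)
    if radius_mm < 0:
        raise ValueError("sphere radius must be non-negative")
    if not target.contains_point(centre):
        raise ValueError(f"sphere centre {tuple(centre)} lies outside the grid extent")

    # separable squared distances from voxel centres to the sphere centre
    d2 = np.zeros(target.shape)
    parts = []
    for ax in range(3):
        parts.append((target.axis_coords(ax) - centre[ax]) ** 2)
    d2 = (
        parts[0][:, None, None]
        + parts[1][None, :, None]
        + parts[2][None, None, :]
    )
    # small relative tolerance so voxels at distance exactly == radius_mm
    # survive floating-point round-off (closed-ball convention)
    mask = d2 <= radius_mm**2 * (1 + 1e-9) + 1e-12
    ci = target.containing_index(centre)
    mask[tuple(ci)] = True

    lo = centre - radius_mm
    hi = centre + radius_mm
    if not (target.contains_point(lo) and target.contains_point(hi)):
        warnings.warn(
            "recurrence sphere extends beyond the dose grid and was clipped",
            stacklevel=2,
        )
    return RecurrenceSphere(
        centre=tuple(float(c) for c in centre),
        radius_mm=float(radius_mm),
        mask=StructureMask(name, target, mask),
    )
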