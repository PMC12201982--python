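"""Self-contained phantom cohorts with known ground truth.

Phantoms are concentric spherical-shell "plans": a low-dose plateau with
nested shells of increasing dose towards a central boost. They are not beam
simulations — the classification consumes only the dose lattice, and shells
give analytically known isodose geometry, so a recurrence can be *planted*
at a location where the decision procedure provably yields a requested
category with margin.

The default phantom follows a three-level simultaneous-integrated-boost
numerology (36/40/53 Gy prescriptions against a 37 Gy plateau, 42 Gy
elective shell and 55 Gy boost). Two gradient sub-shells are added — a
58 Gy core inside the boost and a 46 Gy band inside the elective shell —
because the sphere criterion compares voxel doses with the *mean* dose of a
structure: a perfectly homogeneous region can never keep 95% of voxels at
or above its own mean under noise, and a homogeneous elective region always
sits below the intermediate structure's mean once a boost exists. Real
plans are heterogeneous; the sub-shells supply the minimal gradient that
makes every category reachable.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .classify import CATEGORIES
from .core import (
    DoseGrid,
    Grid3D,
    PatientCase,
    PrescriptionSet,
    StructureMask,
)
from .dose_structures import build_structure_set, threshold_value
from .registration import DisplacementField, warp_mask

__all__ = [
    "PhantomSpec",
    "PlantedCase",
    "TREPatient",
    "make_phantom_dose",
    "plant_recurrence",
    "plant_cohort",
    "make_tre_cohort",
    "ball_mask",
    "ellipsoid_mask",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a nested-shell dose phantom.

    Shells are ``(centre_mm, radius_mm, dose_gy)`` triples; each voxel takes
    the dose of the innermost (highest-dose) shell containing it, else the
    plateau dose. Shell doses must increase strictly inward and shells must
    be geometrically nested. ``noise_sd`` adds i.i.d. Gaussian noise (Gy),
    truncated at zero; with ``noise_sd = 0`` the dose is piecewise constant
    and exactly known.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    plateau_dose: float = 37.0
    shells: tuple[tuple[tuple[float, float, float], float, float], ...] = ()
    prescriptions: PrescriptionSet = field(
        default_factory=lambda: PrescriptionSet.from_dict(
            {"high": 53.0, "intermediate": 40.0, "low": 36.0}
        )
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        grid = self.grid  # validates shape/spacing/origin
        if self.plateau_dose < 0 or self.noise_sd < 0:
            raise ValueError("plateau dose and noise sd must be non-negative")
        shells = self.shells or _default_shells(grid)
        shells = tuple(
            (tuple(float(c) for c in centre), float(r), float(d))
            for centre, r, d in shells
        )
        doses = [d for _, _, d in shells]
        if any(d <= self.plateau_dose for d in doses):
            raise ValueError("shell doses must exceed the plateau dose")
        if sorted(doses) != doses or len(set(doses)) != len(doses):
            raise ValueError("shells must be listed with strictly increasing dose")
        # geometric nesting: each hotter shell must lie inside every cooler one
        for i in range(len(shells) - 1):
            (c_lo, r_lo, _), (c_hi, r_hi, _) = shells[i], shells[i + 1]
            gap = np.linalg.norm(np.subtract(c_hi, c_lo)) + r_hi
            if gap > r_lo + 1e-9:
                raise ValueError(
                    f"shells not nested: shell {i + 1} (r={r_hi}) extends outside "
                    f"shell {i} (r={r_lo})"
                )
        object.__setattr__(self, "shells", shells)

    @property
    def grid(self) -> Grid3D:
        return Grid3D(self.shape, self.spacing, self.origin)


def _default_shells(grid: Grid3D):
    """Concentric default shells centred on the voxel centre nearest the grid middle."""
    centre_idx = tuple((n - 1) // 2 for n in grid.shape)
    centre = tuple(float(c) for c in grid.index_to_world(centre_idx))
    return (
        (centre, 40.0, 42.0),  # elective shell
        (centre, 28.0, 46.0),  # elective gradient band
        (centre, 15.0, 55.0),  # boost
        (centre, 8.0, 58.0),  # boost core
    )


@dataclass(frozen=True)
class PlantedCase:
    """A synthetic patient whose true failure category is known by construction."""

    case: PatientCase
    truth_category: str
    truth_tre_mm: float
    diagnostics: dict


@dataclass(frozen=True)
class TREPatient:
    """One synthetic registration-QA patient: landmark ROI pair plus the field."""

    patient_id: str
    roi_fixed: StructureMask
    roi_mapped: StructureMask
    field: DisplacementField
    true_shift_mm: tuple[float, float, float]


# -- dose synthesis -----------------------------------------------------------


def make_phantom_dose(spec: PhantomSpec) -> DoseGrid:
    """Render the nested-shell dose, deterministic given ``spec.seed``."""
    grid = spec.grid
    values = np.full(grid.shape, spec.plateau_dose, dtype=float)
    for centre, radius, dose in spec.shells:  # increasing dose: inner overwrites
        d2 = _squared_distance_field(grid, centre)
        values[d2 <= radius**2] = dose
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=grid.shape)
        values = np.maximum(values, 0.0)
    return DoseGrid(grid, values)


def _squared_distance_field(grid: Grid3D, centre) -> np.ndarray:
    parts = [(grid.axis_coords(ax) - centre[ax]) ** 2 for ax in range(3)]
    return parts[0][:, None, None] + parts[1][None, :, None] + parts[2][None, None, :]


def ball_mask(grid: Grid3D, centre, radius_mm: float, name: str = "ball") -> StructureMask:
    """Rasterised closed ball: voxel centres within ``radius_mm`` of ``centre``."""
    d2 = _squared_distance_field(grid, np.asarray(centre, float))
    return StructureMask(name, grid, d2 <= radius_mm**2 * (1 + 1e-12))


def ellipsoid_mask(
    grid: Grid3D, centre, radii_mm, name: str = "ellipsoid"
) -> StructureMask:
    """Rasterised axis-aligned ellipsoid (used for synthetic rGTVs)."""
    centre = np.asarray(centre, float)
    radii = np.asarray(radii_mm, float)
    parts = [
        ((grid.axis_coords(ax) - centre[ax]) / radii[ax]) ** 2 for ax in range(3)
    ]
    q = parts[0][:, None, None] + parts[1][None, :, None] + parts[2][None, None, :]
    return StructureMask(name, grid, q <= 1.0 + 1e-12)


# -- recurrence planting ------------------------------------------------------

#: Gy guard between a planted voxel's noise-free dose and any threshold it
#: must stay on the correct side of (where the phantom geometry permits).
_DOSE_GUARD = 1.0
#: default synthetic rGTV semi-axes, mm
_RGTV_RADII = (6.0, 5.0, 4.0)


def plant_recurrence(
    spec: PhantomSpec,
    target_category: str,
    sphere_radius_mm: float = 5.0,
    seed: int = 0,
    rgtv_radii_mm: Sequence[float] = _RGTV_RADII,
) -> PlantedCase:
    """Place an rGTV so the decision procedure provably yields a category.

    Candidate centroid positions are derived from the *noise-free* phantom
    geometry with explicit margins:

    * A — every voxel centre within the sphere radius (plus sub-voxel
      clearance) of the centroid exceeds the high structure's mean dose by
      a guard, so the whole sphere passes.
    * B — the centroid voxel is inside the high structure but within
      ``0.3 x sphere_radius`` of the boundary of the above-mean region, so
      a spherical cap of at least ~25% of the sphere falls below the mean.
    * C / D — the analogous constructions against the intermediate
      structure, with the centroid dose additionally kept a guard below the
      high threshold.
    * E — the centroid voxel sits where the noise-free dose is below both
      decision thresholds.

    The rGTV ellipsoid is centred on a voxel centre, so its rasterised
    centroid is exactly the planted point by symmetry. Raises ``ValueError``
    with the violated geometric constraint when a target is unreachable
    (e.g. C/D without an intermediate prescription level, or a sphere
    radius larger than the shell that must contain it).
    """
    target_category = str(target_category).upper()
    if target_category not in CATEGORIES:
        raise ValueError(f"unknown category {target_category!r}")
    labels = spec.prescriptions.labels
    if target_category in ("C", "D") and "intermediate" not in labels:
        raise ValueError(
            f"category {target_category} requires an intermediate prescription "
            "level, but the prescription set has only "
            f"{labels}"
        )

    grid = spec.grid
    dose = make_phantom_dose(spec)
    rgtv_radii = tuple(float(r) for r in rgtv_radii_mm)
    # placement candidates depend only on the noise-free geometry, not the
    # seed, so they are computed once per (spec, category, radius)
    flat, d0 = _placement_candidates(
        dataclasses.replace(spec, noise_sd=0.0),
        target_category,
        float(sphere_radius_mm),
        rgtv_radii,
    )
    if flat.size == 0:
        raise ValueError(
            f"no placement satisfies the category-{target_category} margins on "
            f"this phantom (sphere radius {sphere_radius_mm} mm may be too large "
            "for the shell geometry)"
        )
    rng = np.random.default_rng(seed)
    idx = np.unravel_index(int(rng.choice(flat)), grid.shape)
    centre = grid.index_to_world(idx)
    centroid_dose0 = float(d0[idx])

    rgtv = ellipsoid_mask(grid, centre, rgtv_radii, name="rgtv_mapped")
    roi_fixed, roi_mapped = _landmark_pair(grid, sphere_radius_mm, rng)
    case = PatientCase(
        patient_id=f"planted_{target_category}_{seed}",
        dose=dose,
        rgtv_mapped=rgtv,
        prescriptions=spec.prescriptions,
        tre_roi_fixed=roi_fixed,
        tre_roi_mapped=roi_mapped,
    )
    return PlantedCase(
        case=case,
        truth_category=target_category,
        truth_tre_mm=float(sphere_radius_mm),
        diagnostics={
            "planted_centre_mm": tuple(float(c) for c in centre),
            "planted_index": tuple(int(i) for i in idx),
            "noise_free_centroid_dose_gy": centroid_dose0,
            "n_candidates": int(flat.size),
        },
    )


@functools.lru_cache(maxsize=64)
def _placement_candidates(clean_spec, category, sphere_r, rgtv_radii):
    """Flat indices of voxels that guarantee ``category`` with margin."""
    grid = clean_spec.grid
    clean = make_phantom_dose(clean_spec)
    d0 = clean.values
    structures0 = {
        s.risk_label: s for s in build_structure_set(clean, clean_spec.prescriptions)
    }
    thr = {
        label: threshold_value(clean_spec.prescriptions.dose_for(label))
        for label in clean_spec.prescriptions.labels
    }
    candidates = _candidate_mask(category, d0, structures0, thr, grid, sphere_r)
    # keep the rGTV and the sphere fully inside the grid
    margin_mm = max(max(rgtv_radii), sphere_r) + max(grid.spacing)
    candidates &= _interior_mask(grid, margin_mm)
    flat = np.flatnonzero(candidates)
    flat.setflags(write=False)
    d0.setflags(write=False)
    return flat, d0


def _candidate_mask(category, d0, structures0, thr, grid, sphere_r):
    """Boolean mask of voxel centres that guarantee the category with margin."""
    spacing = grid.spacing

    def dist_inside(mask):
        # distance (mm) from each inside voxel to the nearest outside voxel
        if not mask.any():
            return np.zeros(mask.shape)
        return ndimage.distance_transform_edt(mask, sampling=spacing)

    have_int = "intermediate" in thr

    if category == "A":
        s = structures0["high"]
        if s.is_empty:
            raise ValueError("high-risk structure is empty on this phantom")
        pass_region = d0 >= s.mean_dose + _DOSE_GUARD
        # EDT measures to outside voxel *centres*; sphere voxels are centres
        # within sphere_r of the candidate, so sub-voxel clearance suffices
        return dist_inside(pass_region) >= sphere_r + 0.75 * max(spacing)
    if category == "B":
        s = structures0["high"]
        if s.is_empty:
            raise ValueError("high-risk structure is empty on this phantom")
        in_high = d0 >= thr["high"] + _DOSE_GUARD
        pass_region = d0 >= s.mean_dose
        near_boundary = dist_inside(pass_region) <= 0.3 * sphere_r
        return in_high & near_boundary
    if category == "C":
        s = structures0["intermediate"]
        if s.is_empty:
            raise ValueError("intermediate-risk structure is empty on this phantom")
        member = (d0 >= thr["intermediate"] + _DOSE_GUARD) & (
            d0 <= thr["high"] - _DOSE_GUARD
        )
        pass_region = d0 >= s.mean_dose + _DOSE_GUARD
        # the sphere may extend into hotter regions; only its extent inside
        # the pass region matters
        return member & (dist_inside(pass_region) >= sphere_r + 0.75 * max(spacing))
    if category == "D":
        s = structures0["intermediate"]
        if s.is_empty:
            raise ValueError("intermediate-risk structure is empty on this phantom")
        member = (d0 >= thr["intermediate"] + _DOSE_GUARD) & (
            d0 <= thr["high"] - _DOSE_GUARD
        )
        pass_region = d0 >= s.mean_dose
        near_boundary = dist_inside(pass_region) <= 0.3 * sphere_r
        return member & near_boundary
    # E: below every decision threshold (guard limited by plateau-threshold gap)
    cuts = [thr[label] for label in ("high", "intermediate") if label in thr]
    guard = min(_DOSE_GUARD, max(min(cuts) - d0.min(), 0.0))
    return d0 <= min(cuts) - guard


def _interior_mask(grid: Grid3D, margin_mm: float) -> np.ndarray:
    out = np.ones(grid.shape, dtype=bool)
    for ax in range(3):
        m = int(math.ceil(margin_mm / grid.spacing[ax]))
        sl = [slice(None)] * 3
        sl[ax] = slice(0, m)
        out[tuple(sl)] = False
        sl[ax] = slice(grid.shape[ax] - m, grid.shape[ax])
        out[tuple(sl)] = False
    return out


def _landmark_pair(grid: Grid3D, shift_mag_mm: float, rng) -> tuple:
    """Fixed/mapped landmark ROI pair whose centroid distance is ~shift_mag_mm."""
    roi_r = 6.0
    # park the landmark near a corner, clear of the shells
    idx = tuple(
        int(math.ceil((roi_r + shift_mag_mm + s) / s)) + 1 for s in grid.spacing
    )
    base = grid.index_to_world(idx)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shift = np.abs(direction) * shift_mag_mm  # point into the grid
    roi_fixed = ball_mask(grid, base, roi_r, name="landmark_fixed")
    roi_mapped = ball_mask(grid, base + shift, roi_r, name="landmark_mapped")
    return roi_fixed, roi_mapped


def plant_cohort(
    spec: PhantomSpec,
    categories: Sequence[str],
    sphere_radius_mm: float = 5.0,
    seed: int = 0,
) -> list[PlantedCase]:
    """Plant one case per requested category, with independent sub-seeds."""
    rng = np.random.default_rng(seed)
    out = []
    for i, cat in enumerate(categories):
        sub = int(rng.integers(0, 2**31 - 1))
        planted = plant_recurrence(
            spec, cat, sphere_radius_mm=sphere_radius_mm, seed=sub
        )
        case = dataclasses.replace(planted.case, patient_id=f"case_{i:03d}_{cat}")
        out.append(dataclasses.replace(planted, case=case))
    return out


# -- registration-QA cohorts --------------------------------------------------


def make_tre_cohort(
    n_patients: int,
    true_shifts_mm: Sequence[Sequence[float]],
    seed: int = 0,
    grid: Optional[Grid3D] = None,
) -> list[TREPatient]:
    """Landmark ROIs plus uniform translation fields with known shifts.

    Each patient gets a spherical landmark ROI and a uniform displacement
    field of the given shift; warping the ROI and measuring the centroid
    distance recovers ``|shift|`` to within half a voxel diagonal, so the
    cohort mean TRE recovers the mean of the shift magnitudes.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if len(true_shifts_mm) != n_patients:
        raise ValueError("need one shift per patient")
    grid = grid or Grid3D((64, 64, 64), (2.0, 2.0, 2.0))
    rng = np.random.default_rng(seed)
    centre_idx = tuple((n - 1) // 2 for n in grid.shape)
    base = grid.index_to_world(centre_idx)
    out = []
    for i, shift in enumerate(true_shifts_mm):
        shift = np.asarray(shift, dtype=float)
        jitter = rng.uniform(-2.0, 2.0, size=3)  # vary landmark position per patient
        roi_fixed = ball_mask(grid, base + jitter, 6.0, name="landmark_fixed")
        dvf = DisplacementField.translation(grid, shift)
        roi_mapped = warp_mask(roi_fixed, dvf)
        roi_mapped = StructureMask("landmark_mapped", grid, roi_mapped.voxels)
        out.append(
            TREPatient(
                patient_id=f"tre_{i:03d}",
                roi_fixed=roi_fixed,
                roi_mapped=roi_mapped,
                field=dvf,
                true_shift_mm=tuple(float(s) for s in shift),
            )
        )
    return out
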