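"""Assign each recurrence to failure category A-E.

Two parameters decide the category: (1) where the mapped rGTV centroid voxel
sits relative to the 95% dose structures, and (2) whether at least 95% of
the recurrence-sphere voxels receive at least the mean dose of the structure
the centroid belongs to.

    centroid in high structure,        sphere passes -> A (central high-dose)
    centroid in high structure,        sphere fails  -> B (peripheral high-dose)
    centroid in intermediate structure, sphere passes -> C (central elective-dose)
    centroid in intermediate structure, sphere fails  -> D (peripheral elective-dose)
    centroid outside both                            -> E (extraneous dose)

The low-risk structure is segmented and reported in the diagnostics but
plays no role in the decision. Membership is decided first; the sphere is
then tested only against that level's structure, so a centroid inside the
high structure whose sphere fails the high criterion is Type B even if the
sphere would pass against the intermediate structure. All comparisons are
inclusive (>=), including a pass fraction of exactly 0.95.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import (
    ClassificationResult,
    DoseGrid,
    DoseStructure,
    EmptyMaskError,
    RecurrenceSphere,
)

__all__ = [
    "sample_dose_at_point",
    "centroid_membership",
    "sphere_pass_fraction",
    "classify",
    "CATEGORIES",
]

CATEGORIES = ("A", "B", "C", "D", "E")

#: Risk levels that participate in the category decision. The low-risk
#: structure is diagnostic only.
_DECISION_LEVELS = ("high", "intermediate")


def sample_dose_at_point(dose: DoseGrid, point) -> float:
    """Dose (Gy) of the voxel containing a world point.

    Nearest-voxel lookup, not interpolation: the classification evaluates
    the centroid *voxel*.
    """
    if not dose.grid.contains_point(point):
        raise ValueError(f"point {tuple(np.asarray(point))} lies outside the dose grid")
    i, j, k = dose.grid.containing_index(point)
    return float(dose.values[i, j, k])


def centroid_membership(
    centroid_dose: float,
    structures: Sequence[DoseStructure],
    rule: str = "threshold",
) -> Optional[str]:
    """Highest-risk decision level whose criterion the centroid dose meets.

    Only the high and intermediate structures are considered; returns None
    when the centroid dose is below both (Type E territory).

    ``rule="threshold"`` (default) tests ``centroid_dose >= threshold``;
    ``rule="structure_mean"`` tests against the structure's mean dose
    instead, the alternative reading in which a centroid counts as inside
    only when it receives at least the structure's mean.
    """
    if rule not in ("threshold", "structure_mean"):
        raise ValueError(f"unknown centroid rule {rule!r}")
    for structure in structures:
        if structure.risk_label not in _DECISION_LEVELS:
            continue
        if structure.is_empty:
            continue
        cut = structure.threshold if rule == "threshold" else structure.mean_dose
        if centroid_dose >= cut:
            return structure.risk_label
    return None


def sphere_pass_fraction(
    dose: DoseGrid, sphere: RecurrenceSphere, structure: DoseStructure
) -> float:
    """Fraction of sphere voxels receiving >= the structure's mean dose."""
    if sphere.mask.is_empty:
        raise EmptyMaskError("recurrence sphere mask is empty")
    if structure.is_empty or structure.mean_dose is None:
        raise EmptyMaskError(
            f"dose structure {structure.risk_label!r} is empty; "
            "the sphere criterion is undefined for that level"
        )
    if not sphere.mask.grid.same_geometry(dose.grid):
        raise ValueError("sphere mask and dose grid geometries differ")
    sphere_doses = dose.values[sphere.mask.voxels]
    return float(np.mean(sphere_doses >= structure.mean_dose))


def classify(
    dose: DoseGrid,
    structures: Sequence[DoseStructure],
    sphere: RecurrenceSphere,
    centroid_mm,
    patient_id: str = "",
    pass_threshold: float = 0.95,
    centroid_rule: str = "threshold",
) -> ClassificationResult:
    """Run the two-parameter decision procedure and return the category.

    Parameters
    ----------
    dose
        Planning dose distribution.
    structures
        Dose structures ordered high -> low (as from
        :func:`~doseclass.dose_structures.build_structure_set`).
    sphere
        Recurrence sphere of radius = cohort TRE around the rGTV centroid.
    centroid_mm
        Mapped rGTV centroid in world mm.
    pass_threshold
        Minimum sphere pass fraction for a "central" call (default 0.95,
        inclusive).
    centroid_rule
        Membership rule, see :func:`centroid_membership`.

    Single-level prescription sets simply make categories C/D unreachable;
    that is a property of the protocol, not an error.
    """
    centroid_mm = np.asarray(centroid_mm, dtype=float)
    centroid_dose = sample_dose_at_point(dose, centroid_mm)
    level = centroid_membership(centroid_dose, structures, rule=centroid_rule)

    by_label = {s.risk_label: s for s in structures}
    fractions: dict[str, Optional[float]] = {}
    for s in structures:
        fractions[s.risk_label] = (
            None if s.is_empty else sphere_pass_fraction(dose, sphere, s)
        )

    if level == "high":
        category = "A" if fractions["high"] >= pass_threshold else "B"
    elif level == "intermediate":
        category = "C" if fractions["intermediate"] >= pass_threshold else "D"
    else:
        category = "E"

    return ClassificationResult(
        patient_id=patient_id,
        category=category,
        centroid_world_mm=tuple(float(c) for c in centroid_mm),
        centroid_dose=centroid_dose,
        centroid_level=level,
        sphere_pass_fraction=fractions,
        structure_mean_doses={s.risk_label: s.mean_dose for s in structures},
        structure_thresholds={s.risk_label: s.threshold for s in structures},
        sphere_radius_mm=sphere.radius_mm,
    )
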