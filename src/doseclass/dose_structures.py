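"""Segment patient-specific 95%-of-prescription dose structures.

For each risk level the threshold is ``fraction x prescribed dose`` (default
fraction 0.95) and the structure is the set of voxels in the planning dose
distribution receiving at least that threshold (inclusive). Structures for
strictly decreasing prescriptions are nested by construction. Thresholds are
kept at full precision internally; the 0.1 Gy rounding seen in clinical
reports is presentation only.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import DoseGrid, DoseStructure, PrescriptionSet, StructureMask

__all__ = [
    "threshold_value",
    "report_dose",
    "segment_dose_structure",
    "build_structure_set",
]


def threshold_value(prescribed_dose: float, fraction: float = 0.95) -> float:
    """Dose threshold (Gy) segmenting a risk region: fraction x prescription.

    Returned at full floating-point precision; use :func:`report_dose` for
    the 0.1 Gy presentation rounding (e.g. 53 Gy -> 50.35 -> "50.4").
    """
    if prescribed_dose <= 0:
        raise ValueError(f"prescribed dose must be positive, got {prescribed_dose}")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return fraction * prescribed_dose


def report_dose(value_gy: float, decimals: int = 1) -> float:
    """Round a dose for reporting, half-up to 0.1 Gy by default.

    Values are first snapped to 1e-9 Gy so binary-float representations of
    exact decimals (0.95 * 53 = 50.349999...994) round the way the exact
    value would (-> 50.4, not 50.3).
    """
    snapped = round(float(value_gy), 9)
    q = 10**decimals
    return float(np.floor(snapped * q + 0.5) / q)


def segment_dose_structure(
    dose: DoseGrid, threshold: float, risk_label: str
) -> DoseStructure:
    """Mask of all voxels with dose >= threshold (inclusive), plus mean dose.

    An empty mask (the plan never reaches the threshold) is permitted and
    flagged with a warning; its mean dose is None.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    voxels = dose.values >= threshold
    mask = StructureMask(f"dose_{risk_label}", dose.grid, voxels)
    if mask.is_empty:
        warnings.warn(
            f"dose structure {risk_label!r}: no voxel reaches {threshold:.2f} Gy; "
            "structure is empty",
            stacklevel=2,
        )
        mean_dose = None
    else:
        mean_dose = float(dose.values[voxels].mean())
    return DoseStructure(
        risk_label=risk_label, threshold=float(threshold), mask=mask, mean_dose=mean_dose
    )


def build_structure_set(
    dose: DoseGrid,
    prescriptions: PrescriptionSet,
    fraction: float = 0.95,
) -> list[DoseStructure]:
    """One dose structure per prescription level, ordered high -> low.

    Strictly decreasing prescriptions give strictly decreasing thresholds,
    so the structures are nested (higher threshold contained in lower) by
    construction.
    """
    structures = []
    for risk_label, prescribed in prescriptions.levels:
        thr = threshold_value(prescribed, fraction)
        structures.append(segment_dose_structure(dose, thr, risk_label))
    return structures
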