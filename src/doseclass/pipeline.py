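"""End-to-end cohort pipeline.

Stage order: (1) per-patient TRE from the supplied ROIs / fields / values;
(2) cohort TRE with outlier exclusion and the recurrence-sphere radius;
(3) per-patient 95% dose structure set; (4) recurrence sphere at the mapped
rGTV centroid; (5) classification; (6) reports — one JSON per patient, a
cohort CSV, and a log. Patients flagged as registration outliers stay in
the report with category ``excluded: registration outlier``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify
from .core import (
    CohortTRE,
    ClassificationResult,
    PatientCase,
    PrescriptionSet,
    centroid,
    resample_mask_to_grid,
)
from .dose_structures import build_structure_set
from .io import (
    CaseManifest,
    WorkflowConfig,
    load_cohort_manifest,
    load_displacement_field_nifti,
    load_dose_nifti,
    load_mask_nifti,
    load_rtdose,
)
from .registration import build_sphere, cohort_tre, patient_tre, warp_mask

__all__ = ["load_case", "run_pipeline", "CohortReport", "EXCLUDED_CATEGORY"]

logger = logging.getLogger("doseclass")

EXCLUDED_CATEGORY = "excluded: registration outlier"


@dataclass(frozen=True)
class CohortReport:
    """Everything the pipeline computed for a cohort."""

    cohort: CohortTRE
    sphere_radius_mm: float
    results: tuple[ClassificationResult, ...]
    excluded_ids: tuple[str, ...]
    failures: tuple[tuple[str, str], ...]  # (patient_id, error message)
    config_hash: str
    version: str = __version__

    def to_frame(self) -> pd.DataFrame:
        """Cohort table, one row per patient (including excluded ones)."""
        tre_by_id = dict(self.cohort.per_patient)
        rows = []
        for r in self.results:
            row = {
                "patient_id": r.patient_id,
                "category": r.category,
                "centroid_dose_gy": r.centroid_dose,
                "centroid_level": r.centroid_level,
                "sphere_radius_mm": r.sphere_radius_mm,
                "tre_mm": tre_by_id.get(r.patient_id),
            }
            for label, thr in r.structure_thresholds.items():
                row[f"threshold_{label}_gy"] = thr
                row[f"mean_dose_{label}_gy"] = r.structure_mean_doses.get(label)
                row[f"pass_fraction_{label}"] = r.sphere_pass_fraction.get(label)
            rows.append(row)
        for pid in self.excluded_ids:
            rows.append(
                {
                    "patient_id": pid,
                    "category": EXCLUDED_CATEGORY,
                    "tre_mm": tre_by_id.get(pid),
                }
            )
        frame = pd.DataFrame(rows)
        frame["config_hash"] = self.config_hash
        return frame.sort_values("patient_id", kind="stable").reset_index(drop=True)


def _load_volume(path: Path):
    if path.suffix.lower() == ".dcm":
        return load_rtdose(path)
    return load_dose_nifti(path)


def load_case(
    manifest: CaseManifest,
    config: WorkflowConfig,
    base_dir: Optional[Path] = None,
) -> PatientCase:
    """Materialise a patient case from a manifest.

    All masks are nearest-neighbour resampled onto the dose grid so every
    later stage works on a single lattice. The TRE input is normalised: a
    displacement-field source is resolved here by warping the relapse-space
    ROI into planning space.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")

    def full(p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base / p

    manifest.check_paths(base)
    dose = _load_volume(full(manifest.dose_path))
    grid = dose.grid

    def mask_on_grid(path, name):
        mask = load_mask_nifti(full(path), name=name)
        return resample_mask_to_grid(mask, grid)

    rgtv = mask_on_grid(manifest.rgtv_path, "rgtv_mapped")

    roi_fixed = roi_mapped = None
    tre_mm = manifest.tre_mm
    if manifest.roi_fixed_path is not None and manifest.roi_mapped_path is not None:
        roi_fixed = mask_on_grid(manifest.roi_fixed_path, "roi_fixed")
        roi_mapped = mask_on_grid(manifest.roi_mapped_path, "roi_mapped")
    elif manifest.dvf_path is not None:
        dvf = load_displacement_field_nifti(full(manifest.dvf_path))
        roi_relapse = load_mask_nifti(full(manifest.roi_relapse_path), name="roi_relapse")
        roi_fixed = mask_on_grid(manifest.roi_fixed_path, "roi_fixed")
        roi_mapped = resample_mask_to_grid(warp_mask(roi_relapse, dvf), grid)

    prescriptions = (
        PrescriptionSet.from_dict(manifest.prescriptions)
        if manifest.prescriptions is not None
        else config.prescription_set
    )
    return PatientCase(
        patient_id=manifest.patient_id,
        dose=dose,
        rgtv_mapped=rgtv,
        prescriptions=prescriptions,
        tre_roi_fixed=roi_fixed,
        tre_roi_mapped=roi_mapped,
        tre_mm=tre_mm,
    )


def _case_tre(case: PatientCase) -> float:
    if case.tre_mm is not None:
        return float(case.tre_mm)
    if case.tre_roi_fixed is None or case.tre_roi_mapped is None:
        raise ValueError(f"case {case.patient_id}: no TRE source available")
    return patient_tre(case.tre_roi_fixed, case.tre_roi_mapped)


def classify_case(
    case: PatientCase, sphere_radius_mm: float, config: WorkflowConfig
):
    """Stages 3-5 for one patient: structures, sphere, category."""
    structures = build_structure_set(
        case.dose, case.prescriptions, fraction=config.dose_fraction
    )
    rgtv_centroid = centroid(case.rgtv_mapped)
    sphere = build_sphere(rgtv_centroid, sphere_radius_mm, case.dose.grid)
    return classify(
        case.dose,
        structures,
        sphere,
        rgtv_centroid,
        patient_id=case.patient_id,
        pass_threshold=config.sphere_pass_threshold,
        centroid_rule=config.centroid_rule,
    )


def run_pipeline(
    cases: Sequence[PatientCase] | str | Path,
    config: Optional[WorkflowConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> CohortReport:
    """Run the full workflow over a cohort.

    ``cases`` is either a sequence of in-memory :class:`PatientCase` objects
    or the path to a cohort manifest JSON. Writes per-patient JSON, a cohort
    CSV and a log file when ``out_dir`` is given. Per-case failures are
    logged and skipped; they are reported in ``CohortReport.failures``.
    """
    config = config or WorkflowConfig()
    if isinstance(cases, (str, Path)):
        manifest_path = Path(cases)
        manifests = load_cohort_manifest(manifest_path)
        loaded = []
        for m in manifests:
            loaded.append(load_case(m, config, base_dir=manifest_path.parent))
        cases = loaded
    if not cases:
        raise ValueError("cohort is empty")

    log_handler = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(out_dir / "doseclass.log")
        log_handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(log_handler)
        logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    try:
        # stage 1: per-patient TRE
        tres = []
        failures = []
        tre_cases = []
        for case in cases:
            try:
                tres.append((case.patient_id, _case_tre(case)))
                tre_cases.append(case)
            except Exception as exc:  # per-case failure: log and skip
                logger.error("case %s failed at TRE stage: %s", case.patient_id, exc)
                failures.append((case.patient_id, str(exc)))

        if not tres:
            raise ValueError("no case provided a usable TRE input")

        # stage 2: cohort TRE, outliers, sphere radius
        cohort = cohort_tre(tres, outlier_rule=config.outlier_rule)
        excluded = set(cohort.outlier_ids)
        if config.sphere_radius_from == "post_exclusion_mean" and excluded:
            kept = [t for pid, t in cohort.per_patient if pid not in excluded]
            if not kept:
                raise ValueError("all patients excluded as registration outliers")
            radius = float(np.mean(kept))
        else:
            radius = cohort.mean_mm
        logger.info(
            "cohort TRE %.2f +/- %.2f mm over %d patients; sphere radius %.2f mm; "
            "%d outlier(s) excluded",
            cohort.mean_mm,
            cohort.sd_mm,
            cohort.n,
            radius,
            len(excluded),
        )

        # stages 3-5 per included patient
        results = []
        for case in tre_cases:
            if case.patient_id in excluded:
                logger.warning(
                    "case %s excluded: registration outlier (TRE %.2f mm)",
                    case.patient_id,
                    dict(cohort.per_patient)[case.patient_id],
                )
                continue
            try:
                results.append(classify_case(case, radius, config))
            except Exception as exc:
                logger.error("case %s failed classification: %s", case.patient_id, exc)
                failures.append((case.patient_id, str(exc)))

        report = CohortReport(
            cohort=cohort,
            sphere_radius_mm=radius,
            results=tuple(results),
            excluded_ids=tuple(sorted(excluded)),
            failures=tuple(failures),
            config_hash=config.config_hash(),
        )

        # stage 6: reports
        if out_dir is not None:
            for r in results:
                payload = r.to_dict()
                payload["config_hash"] = report.config_hash
                payload["version"] = report.version
                (out_dir / f"{r.patient_id}.json").write_text(
                    json.dumps(payload, indent=2, sort_keys=True)
                )
            report.to_frame().to_csv(out_dir / "cohort_report.csv", index=False)
            summary = {
                "version": report.version,
                "config_hash": report.config_hash,
                "config": config.to_dict(),
                "cohort_tre_mean_mm": cohort.mean_mm,
                "cohort_tre_sd_mm": cohort.sd_mm,
                "sphere_radius_mm": radius,
                "n_patients": cohort.n,
                "excluded": list(report.excluded_ids),
                "failures": [list(f) for f in failures],
                "categories": {r.patient_id: r.category for r in results},
            }
            (out_dir / "cohort_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True)
            )
        return report
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()
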