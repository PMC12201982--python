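"""Segment 95%-of-prescription dose structures from a planning dose.

Builds the default three-level phantom plan (53/40/36 Gy prescriptions to
the high/intermediate/low risk regions) and segments one dose structure per
level: every voxel receiving at least 95% of that level's prescription.
"""

from doseclass import (
    PhantomSpec,
    build_structure_set,
    make_phantom_dose,
    report_dose,
)

spec = PhantomSpec()
dose = make_phantom_dose(spec)
print(f"plan: {dose.grid.shape} voxels at {dose.grid.spacing} mm")

structures = build_structure_set(dose, spec.prescriptions)
for s in structures:
    prescribed = spec.prescriptions.dose_for(s.risk_label)
    print(
        f"{s.risk_label:>12}-risk: {prescribed:g} Gy prescribed -> "
        f"threshold {report_dose(s.threshold):.1f} Gy, "
        f"{s.mask.voxel_count} voxels ({s.mask.volume_mm3 / 1000:.0f} cm3), "
        f"mean dose {s.mean_dose:.1f} Gy"
    )

# The three structures are nested: every voxel above the high threshold is
# also above the intermediate and low thresholds, so the high-risk volume is
# the smallest. The mean dose of each structure is what the recurrence
# sphere is later compared against.
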