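"""Classify a recurrence into failure categories A-E.

Plants one recurrence per category on the default phantom and runs the
two-parameter decision procedure: (1) which dose structure contains the
mapped rGTV centroid voxel, and (2) whether at least 95% of the
recurrence-sphere voxels receive the mean dose of that structure.
"""

from doseclass import (
    PhantomSpec,
    build_sphere,
    build_structure_set,
    centroid,
    classify,
    make_phantom_dose,
    plant_recurrence,
)

NAMES = {
    "A": "central high-dose",
    "B": "peripheral high-dose",
    "C": "central elective-dose",
    "D": "peripheral elective-dose",
    "E": "extraneous dose",
}

spec = PhantomSpec(noise_sd=0.3, seed=1)
dose = make_phantom_dose(spec)
structures = build_structure_set(dose, spec.prescriptions)

for truth in "ABCDE":
    planted = plant_recurrence(spec, truth, sphere_radius_mm=5.0, seed=11)
    rgtv_centroid = centroid(planted.case.rgtv_mapped)
    sphere = build_sphere(rgtv_centroid, planted.truth_tre_mm, dose.grid)
    res = classify(dose, structures, sphere, rgtv_centroid)
    frac = res.sphere_pass_fraction.get(res.centroid_level)
    frac_txt = "-" if frac is None else f"{frac:.2f}"
    print(
        f"planted {truth} -> Type {res.category} ({NAMES[res.category]}): "
        f"centroid {res.centroid_dose:5.1f} Gy in "
        f"{res.centroid_level or 'no'} structure, "
        f"sphere pass fraction {frac_txt}"
    )

# A high centroid dose with a fully-passing sphere is a central failure
# (A/C); a failing sphere with the centroid still inside the structure is a
# peripheral failure (B/D); a centroid outside both the high and
# intermediate structures is an extraneous failure (E).
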