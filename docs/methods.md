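# Methods

## The workflow

`doseclass` implements a dose-based classification of locoregional
recurrence. The unit of analysis is one patient: a 3-D planning dose grid
(Gy), a binary mask of the relapse GTV already mapped into planning space,
a prescription table (1–3 risk levels with strictly decreasing doses), and
one of three registration-accuracy inputs (a landmark ROI pair, a
precomputed TRE, or a displacement field plus the relapse-space ROI).

The pipeline runs six stages: per-patient TRE → cohort TRE with outlier
exclusion → 95% dose structures → recurrence sphere → A–E classification →
reports. Every stage is exposed as a plain function so the library can be
used piecemeal.

## Geometry conventions

* World coordinates in mm; voxel indices 0-based; a voxel's world position
  is its **centre**: `world = origin + index * spacing`.
* Grids are axis-aligned. Sign-flipped NIfTI/DICOM axes are rectified at
  import (data flipped, origin adjusted); genuinely oblique orientations
  are rejected rather than silently resampled.
* The voxel containing a point uses half-up rounding of the fractional
  index, so a point exactly on a voxel boundary belongs to the
  higher-index voxel.
* Structure centroids are the **unweighted** mean of member voxel centres
  (the method uses structure geometry, not image intensity), computed on
  the mask's native grid in world coordinates; any discrepancy versus
  computing after resampling is sub-voxel.
* Mask resampling and warping are nearest-neighbour, preserving binarity.
* All dose comparisons are inclusive (≥): a voxel exactly at a threshold
  is inside the structure, a sphere pass fraction of exactly 0.95 passes.

## Dose structures

For prescription *D* and fraction *f* (default 0.95) the threshold is
*fD*, kept at full floating-point precision internally. Reported values
are rounded half-up to 0.1 Gy after snapping to 10⁻⁹ Gy, so the binary
representation of, e.g., 0.95 × 53 = 50.349999…994 reports as 50.4 as the
exact decimal would. The structure is `{voxels : dose ≥ fD}` — purely
voxelwise, no connected-component filtering (hot spots legitimately belong
to a 95% structure) and no body-contour clipping (none is available to the
workflow; a known limitation for doses that spill outside the patient).
Strictly decreasing prescriptions give nested structures by construction.
An empty structure (plan never reaches the threshold) warns and carries
`mean_dose = None`; the sphere criterion is undefined for that level.

## Registration QA

Per-patient TRE is the Euclidean distance between the centroids of a
landmark ROI delineated on the planning CT and the same ROI mapped from
the relapse CT. The cohort TRE is the arithmetic mean; the standard
deviation uses the sample (n−1) denominator with sd = 0 for a single
patient. The default outlier rule is `tre > mean + 3·sd`; a literal
`tre > 3·sd` variant is available by config (`outlier_rule: 3sd`). The
mean+3σ form is the conventional outlier reading and avoids flagging
typical patients whenever sd ≈ mean/3. Note the usual masking caveat: a
single extreme value inflates the sd, so very small cohorts may not flag
it. By default the recurrence-sphere radius is the cohort mean recomputed
**after** exclusion (`sphere_radius_from: post_exclusion_mean`); the raw
mean is available by config.

Displacement fields store forward displacements (a relapse-space point *p*
maps to *p* + *v*). Warping a mask evaluates the field on the output grid
and pulls back per voxel: `out(x) = mask(x − v(x))`, nearest-neighbour, so
a uniform field of vector *t* shifts a mask by exactly +*t* and the
identity field is a no-op. The registration itself (rigid + B-spline
optimisation) is deliberately out of scope — research groups supply their
own registration output.

## Recurrence sphere and classification

The sphere mask contains every voxel whose centre is within the radius
(closed ball) of the mapped rGTV centroid, always including the containing
voxel, so radius 0 degenerates to the centroid voxel alone and the sphere
criterion collapses to the centroid voxel's own dose. Spheres reaching
past the grid are clipped with a warning.

Membership is decided over the high and intermediate structures only
(the low-risk structure is segmented and reported but the category
definitions never reference it); the highest level whose threshold the
centroid voxel's dose meets wins, empty structures are skipped. The sphere
is then tested **only against that level's structure**: a centroid inside
the high structure whose sphere fails the high criterion is Type B even if
it would pass the intermediate criterion — the only reading consistent
with a two-parameter scheme. Centroid dose uses nearest-voxel lookup, not
interpolation (the criterion is about the centroid *voxel*). An
alternative membership rule comparing the centroid dose against the
structure *mean* instead of the threshold is exposed as
`centroid_rule: structure_mean`; the default follows the category
definitions. Single-level protocols simply make C/D unreachable.

## The phantom generator

Phantoms are concentric spherical-shell plans: a plateau (default 37 Gy)
with nested shells of increasing dose, optional i.i.d. Gaussian noise
(truncated at 0 Gy, no spatial correlation — the simplest perturbation
that stresses the inclusive-threshold logic). Defaults follow a
three-level simultaneous-integrated-boost numerology: prescriptions
53/40/36 Gy against a 42 Gy elective shell (r = 40 mm) and a 55 Gy boost
(r = 15 mm) on a 64³ × 2 mm grid.

Two gradient sub-shells are part of the default geometry: a 58 Gy core
(r = 8 mm) inside the boost and a 46 Gy band (r = 28 mm) inside the
elective shell. They are required by the structure-of-the-mean criterion:
a perfectly homogeneous boost can never hold ≥ 95% of sphere voxels at or
above its own mean once noise exists (half fall below), and a homogeneous
elective region always sits strictly below the intermediate structure's
mean because the embedded boost raises it — making Types A (noisy) and C
(always) unplantable. Real plans are heterogeneous; the sub-shells supply
the minimal gradient that makes all five categories reachable with
provable margins.

`plant_recurrence` derives candidate centroid voxels from the *noise-free*
geometry, not trial-and-error: Euclidean distance transforms give each
voxel's clearance inside the relevant above-mean region; "central"
plantings require clearance ≥ sphere radius (+ sub-voxel slack), so the
whole sphere passes; "peripheral" plantings sit within 0.3 × radius of the
region boundary, so a spherical cap of ≳ 25% of the sphere falls below the
mean; membership constraints keep the noise-free centroid dose ≥ 1 Gy on
the correct side of each threshold wherever the geometry allows (the
plateau sits only 1 Gy below the intermediate threshold, so Type E
retains a 2σ margin at noise σ = 0.5 Gy — the one planting that can
rarely flip under noise). The rGTV is a small ellipsoid (6/5/4 mm
semi-axes) centred on a voxel centre, so its rasterised centroid is
exactly the planted point by symmetry. Unreachable targets (C/D without an
intermediate level, spheres larger than the shell that must contain them)
raise errors naming the violated constraint.

What passing phantom tests does **not** show: robustness to realistic
beam/arc dose gradients, spatially correlated noise, registration errors
that deform rather than translate, multi-focal recurrences, or RTSTRUCT
rasterisation subtleties — the phantom exercises the decision logic and
the plumbing, not treatment-planning realism.

## Numerical choices and problem sizes

* Threshold and pass-fraction comparisons are exact (≥) with no epsilon;
  the only tolerances are the 10⁻⁹ relative slack in ball rasterisation
  (so voxels at distance exactly = radius survive round-off) and the
  half-up index rounding at voxel boundaries.
* Test and acceptance runs use 16³–32³ random phantoms for brute-force
  oracle comparisons, the 64³ default phantom for planting (100 seeds per
  category), and 10–16-patient cohorts for TRE/pipeline checks; the whole
  suite completes in well under a minute on one CPU.
* Candidate-placement masks and the noise-free phantom are memoized per
  spec (frozen, hashable dataclass), making repeated planting cheap.

## Known limitations

* Axis-aligned grids only; oblique acquisitions must be resampled upstream.
* One rGTV per case; no multi-lesion handling.
* RT Dose with non-uniform `GridFrameOffsetVector` is rejected.
* RTSTRUCT rasterisation uses voxel-centre-in-polygon on the nearest
  slice; contours straddling slices are assigned wholly to one slice.
* No DVH machinery beyond the structure mean dose the criterion needs.
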