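"""Independent brute-force re-implementation of the decision procedure.

Pure Python nested loops over plain list-of-lists, no numpy and no code
shared with the package. Used as the oracle that the vectorised
implementation must agree with exactly.
"""

import math


def brute_centroid(voxels, spacing, origin):
    """Mean world coordinate of set voxels; ``voxels`` is [x][y][z] booleans."""
    sx = sy = sz = 0.0
    n = 0
    for i, plane in enumerate(voxels):
        for j, row in enumerate(plane):
            for k, v in enumerate(row):
                if v:
                    sx += origin[0] + i * spacing[0]
                    sy += origin[1] + j * spacing[1]
                    sz += origin[2] + k * spacing[2]
                    n += 1
    if n == 0:
        raise ValueError("empty mask")
    return (sx / n, sy / n, sz / n)


def brute_containing_index(point, spacing, origin):
    return tuple(
        math.floor((point[a] - origin[a]) / spacing[a] + 0.5) for a in range(3)
    )


def brute_structure(dose, threshold):
    """(voxel_count, mean_dose or None) of the >= threshold structure."""
    total = 0.0
    n = 0
    for plane in dose:
        for row in plane:
            for v in row:
                if v >= threshold:
                    total += v
                    n += 1
    return n, (total / n if n else None)


def brute_sphere_voxels(dims, spacing, origin, centre, radius):
    """Voxel indices of the closed ball, always including the centre voxel."""
    out = []
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                dx = origin[0] + i * spacing[0] - centre[0]
                dy = origin[1] + j * spacing[1] - centre[1]
                dz = origin[2] + k * spacing[2] - centre[2]
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    out.append((i, j, k))
    ci = brute_containing_index(centre, spacing, origin)
    if all(0 <= ci[a] < dims[a] for a in range(3)) and ci not in out:
        out.append(ci)
    return out


def brute_classify(
    dose,
    dims,
    spacing,
    origin,
    prescriptions,
    centroid,
    sphere_radius,
    fraction=0.95,
    pass_threshold=0.95,
):
    """Full decision procedure by enumeration.

    ``prescriptions`` is an ordered list of (label, prescribed_dose), high
    first. Returns (category, centroid_dose, level, {label: pass_fraction or
    None}).
    """
    thresholds = [(label, fraction * d) for label, d in prescriptions]
    stats = {label: brute_structure(dose, thr) for label, thr in thresholds}

    ci = brute_containing_index(centroid, spacing, origin)
    centroid_dose = dose[ci[0]][ci[1]][ci[2]]

    level = None
    for label, thr in thresholds:
        if label not in ("high", "intermediate"):
            continue
        if stats[label][0] == 0:
            continue
        if centroid_dose >= thr:
            level = label
            break

    sphere = brute_sphere_voxels(dims, spacing, origin, centroid, sphere_radius)
    fractions = {}
    for label, _ in thresholds:
        n, mean = stats[label]
        if n == 0:
            fractions[label] = None
            continue
        passed = sum(1 for (i, j, k) in sphere if dose[i][j][k] >= mean)
        fractions[label] = passed / len(sphere)

    if level == "high":
        category = "A" if fractions["high"] >= pass_threshold else "B"
    elif level == "intermediate":
        category = "C" if fractions["intermediate"] >= pass_threshold else "D"
    else:
        category = "E"
    return category, centroid_dose, level, fractions
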