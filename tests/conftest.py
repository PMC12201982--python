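import numpy as np
import pytest

from doseclass import (
    Grid3D,
    PhantomSpec,
    build_structure_set,
    make_phantom_dose,
)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_dose(default_spec):
    return make_phantom_dose(default_spec)


@pytest.fixture(scope="session")
def phantom_structures(default_spec, phantom_dose):
    return build_structure_set(phantom_dose, default_spec.prescriptions)


@pytest.fixture
def small_grid():
    return Grid3D((20, 20, 20), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def random_phantom(rng, min_n=16, max_n=32):
    """A random nested-shell phantom on a random small grid.

    Shell doses are drawn continuous so threshold/mean ties have probability
    zero; prescriptions have 1-3 levels loosely tied to the shell doses so
    empty, partial and full structures all occur.
    """
    n = tuple(int(rng.integers(min_n, max_n + 1)) for _ in range(3))
    spacing = tuple(float(rng.uniform(1.0, 3.0)) for _ in range(3))
    origin = tuple(float(rng.uniform(-20, 20)) for _ in range(3))
    grid = Grid3D(n, spacing, origin)
    extent = np.array(n) * np.array(spacing)
    centre = np.array(origin) + extent * rng.uniform(0.35, 0.65, 3) - np.array(spacing) / 2

    plateau = float(rng.uniform(20, 40))
    r_out = float(rng.uniform(0.25, 0.45) * extent.min())
    r_in = float(rng.uniform(0.35, 0.7) * r_out)
    d_out = plateau + float(rng.uniform(3, 10))
    d_in = d_out + float(rng.uniform(3, 15))
    spec = PhantomSpec(
        shape=n,
        spacing=spacing,
        origin=origin,
        plateau_dose=plateau,
        shells=((tuple(centre), r_out, d_out), (tuple(centre), r_in, d_in)),
        noise_sd=float(rng.uniform(0.0, 1.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    n_levels = int(rng.integers(1, 4))
    top = float(rng.uniform(d_out, d_in * 1.1))
    doses = sorted(
        {round(top, 3)}
        | {round(float(rng.uniform(plateau * 0.9, top - 1)), 3) for _ in range(n_levels - 1)},
        reverse=True,
    )[:n_levels]
    labels = ["high", "intermediate", "low"][: len(doses)]
    prescriptions = dict(zip(labels, doses))
    return spec, prescriptions
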