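import numpy as np
import pytest

from mddiff import (
    Criteria,
    PerturbationSpec,
    apply_perturbation,
    imrt_like_field,
    make_grid,
)


@pytest.fixture
def criteria():
    """Clinical-standard criteria: 3% of a 200 cGy prescription, 3 mm."""
    return Criteria.from_percent(3.0, 3.0, 200.0)


def random_imrt_pair(rng, extent=24.0, spacing=1.0):
    """A small random IMRT-like reference plus a perturbed evaluated field.

    Used by property tests: random aperture layout gives flat, penumbra
    and background regimes; the perturbation mixes shift, scaling and
    noise with known parameters.
    """
    n_ap = int(rng.integers(1, 4))
    apertures = []
    for _ in range(n_ap):
        center = tuple(rng.uniform(0.25 * extent, 0.75 * extent, 2))
        width = tuple(rng.uniform(0.2 * extent, 0.6 * extent, 2))
        dose = float(rng.uniform(50, 250))
        apertures.append((center, width, dose))
    ref = imrt_like_field(apertures, penumbra_sigma=float(rng.uniform(1.0, 3.0)),
                          spacing=spacing, extent=extent)
    spec = PerturbationSpec(
        shift=tuple(rng.uniform(-2.5, 2.5, 2)),
        dose_scale=float(rng.uniform(0.92, 1.08)),
        noise_sigma=float(rng.uniform(0.0, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return ref, apply_perturbation(ref, spec), spec


def random_rough_pair(rng, max_side=14):
    """Fully random (non-smooth) grid pair with mismatched geometries."""
    nr = (int(rng.integers(5, max_side)), int(rng.integers(5, max_side)))
    ne = (int(rng.integers(5, max_side)), int(rng.integers(5, max_side)))
    ref = make_grid(
        rng.uniform(0, 220, nr),
        tuple(rng.uniform(0.7, 1.5, 2)),
        tuple(rng.uniform(-1, 1, 2)),
    )
    ev = make_grid(
        rng.uniform(0, 220, ne),
        tuple(rng.uniform(0.7, 1.5, 2)),
        tuple(rng.uniform(-1, 1, 2)),
    )
    return ref, ev
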