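"""Synthetic planar dose fields with controlled, known discrepancies.

No public dataset of measured/calculated IMRT planar doses accompanies
this package, so every experiment runs on generated fields that emulate
the regimes the metrics are designed around: flat plateaus (zero dose
gradient), steep erf-shaped penumbras of several cGy/mm at aperture
edges, and low-dose background. Evaluated distributions are produced by
perturbing a reference with a rigid sub-pixel shift, a multiplicative
dose-scaling error, and additive Gaussian noise — the three discrepancy
modes that dominate real patient-specific QA comparisons.

All randomness sits behind integer seeds; identical seeds give bitwise
identical fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import erf

from .dose_model import DoseGrid, ValidationError, make_grid

__all__ = [
    "PerturbationSpec",
    "CohortCase",
    "ramp_field",
    "imrt_like_field",
    "apply_perturbation",
    "synthetic_cohort",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Parameters of a controlled discrepancy applied to a reference field.

    shift
        Rigid translation (sx, sy) in mm of the dose pattern.
    dose_scale
        Multiplicative dose error (1.03 = +3% everywhere), > 0.
    noise_sigma
        Standard deviation of additive Gaussian noise, cGy, >= 0.
    seed
        Seed for the noise generator.
    """

    shift: tuple[float, float] = (0.0, 0.0)
    dose_scale: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dose_scale > 0:
            raise ValidationError(f"dose_scale: must be > 0, got {self.dose_scale}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma: must be >= 0, got {self.noise_sigma}")


@dataclass(frozen=True)
class CohortCase:
    """One synthetic QA case: a reference/evaluated pair with known severity."""

    case_id: str
    reference: DoseGrid
    evaluated: DoseGrid
    perturbation: PerturbationSpec
    severity: float


def _as_pair(v) -> tuple[float, float]:
    if np.isscalar(v):
        return (float(v), float(v))
    return (float(v[0]), float(v[1]))


def ramp_field(
    slope: float,
    extent: float | tuple[float, float],
    spacing: float | tuple[float, float],
    base_dose: float = 0.0,
) -> DoseGrid:
    """Linear dose ramp D(x, y) = base_dose + slope * x, clipped at 0.

    ``slope`` in cGy/mm along x; flat along y. A zero slope gives a
    uniform field at ``base_dose``.
    """
    if slope < 0:
        raise ValidationError(f"slope: must be >= 0, got {slope}")
    ex, ey = _as_pair(extent)
    dx, dy = _as_pair(spacing)
    x = np.arange(int(round(ex / dx)) + 1) * dx
    ny = int(round(ey / dy)) + 1
    col = np.maximum(base_dose + slope * x, 0.0)
    return make_grid(np.repeat(col[:, None], ny, axis=1), (dx, dy))


def _edge_profile(t: np.ndarray, center: float, width: float, sigma: float) -> np.ndarray:
    # rectangle of unit height convolved with a Gaussian of sd sigma
    s = sigma * np.sqrt(2.0)
    lo, hi = center - width / 2.0, center + width / 2.0
    return 0.5 * (erf((t - lo) / s) - erf((t - hi) / s))


def imrt_like_field(
    apertures: list[tuple],
    penumbra_sigma: float,
    spacing: float | tuple[float, float],
    extent: float | tuple[float, float] = 60.0,
) -> DoseGrid:
    """Sum of Gaussian-blurred rectangular apertures.

    Each aperture is ``(center, width, dose)`` with ``center`` and
    ``width`` scalars (square) or (x, y) pairs, all in mm, ``dose`` in
    cGy. The profile is separable: dose * P(x) * P(y) with erf-shaped
    edges of penumbra scale ``penumbra_sigma`` (mm). For widths much
    larger than the penumbra the central plateau reaches the nominal
    dose; the maximum edge gradient is dose / (penumbra_sigma * sqrt(2*pi)).
    """
    if penumbra_sigma <= 0:
        raise ValidationError(f"penumbra_sigma: must be > 0, got {penumbra_sigma}")
    ex, ey = _as_pair(extent)
    dx, dy = _as_pair(spacing)
    x = np.arange(int(round(ex / dx)) + 1) * dx
    y = np.arange(int(round(ey / dy)) + 1) * dy
    values = np.zeros((x.size, y.size))
    for center, width, dose in apertures:
        cx, cy = _as_pair(center)
        wx, wy = _as_pair(width)
        px = _edge_profile(x, cx, wx, penumbra_sigma)
        py = _edge_profile(y, cy, wy, penumbra_sigma)
        values += float(dose) * px[:, None] * py[None, :]
    return make_grid(np.maximum(values, 0.0), (dx, dy))


def apply_perturbation(grid: DoseGrid, spec: PerturbationSpec) -> DoseGrid:
    """Produce an "evaluated" field by shifting, scaling, and adding noise.

    The dose pattern is translated rigidly by ``spec.shift`` (bilinear
    resampling; the field is edge-extended so the result stays on the
    input geometry), multiplied by ``spec.dose_scale``, then Gaussian
    noise of sd ``spec.noise_sigma`` cGy is added and the result clipped
    at 0. An identity spec returns the input values unchanged.
    """
    sx, sy = spec.shift
    if sx == 0.0 and sy == 0.0:
        values = grid.values.copy()
    else:
        interp = RegularGridInterpolator(
            (grid.x_axis, grid.y_axis),
            grid.values,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
        xmin, xmax, ymin, ymax = grid.extent
        # pattern moves by +s: the new field samples the old one at r - s
        xq = np.clip(grid.x_axis - sx, xmin, xmax)
        yq = np.clip(grid.y_axis - sy, ymin, ymax)
        xx, yy = np.meshgrid(xq, yq, indexing="ij")
        values = interp(np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(grid.shape)
    values = values * spec.dose_scale
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sigma, size=values.shape)
    return make_grid(np.maximum(values, 0.0), grid.spacing, grid.origin)


def _cohort_reference(spacing: float = 1.0) -> DoseGrid:
    """Fixed IMRT-like reference plane used by :func:`synthetic_cohort`.

    Three apertures of different doses on an 80x80 mm plane, modulated by
    a smooth low-gradient dome so plateau doses span a continuum (roughly
    90-210 cGy) rather than a few discrete levels — discrepancy severity
    then maps onto failing area continuously.
    """
    field = imrt_like_field(
        apertures=[
            ((26.0, 40.0), (24.0, 52.0), 210.0),
            ((50.0, 40.0), (16.0, 52.0), 150.0),
            ((64.0, 32.0), (10.0, 30.0), 95.0),
        ],
        penumbra_sigma=2.0,
        spacing=spacing,
        extent=80.0,
    )
    xx, yy = np.meshgrid(field.x_axis, field.y_axis, indexing="ij")
    r2 = (xx - 40.0) ** 2 + (yy - 40.0) ** 2
    dome = np.maximum(1.0 - 0.30 * r2 / 48.0**2, 0.6)
    return make_grid(field.values * dome, field.spacing, field.origin)


def synthetic_cohort(n_cases: int, seed: int, spacing: float = 1.0) -> list[CohortCase]:
    """Reproducible cohort of QA cases of strictly increasing severity.

    Case 0 is a perfect delivery (evaluated identical to the reference);
    cases 1..n-1 combine a dose-scaling error growing from +3.5% to +10%,
    a rigid shift growing from 1 mm to 6 mm, and noise growing from 0.3
    to 1.2 cGy — spanning clearly-passing to clearly-failing deliveries,
    comparable to the spread seen across real patient-specific QA. The
    recorded ``severity`` is k/(n-1) and is strictly increasing.
    """
    if n_cases < 2:
        raise ValidationError(f"n_cases: need at least 2 cases, got {n_cases}")
    reference = _cohort_reference(spacing=spacing)
    cases = []
    for k in range(n_cases):
        if k == 0:
            spec = PerturbationSpec()
        else:
            u = 0.0 if n_cases == 2 else (k - 1) / (n_cases - 2)
            child_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] & 0x7FFFFFFF)
            spec = PerturbationSpec(
                shift=(1.0 + 5.0 * u, 0.6 * u),
                dose_scale=1.035 + 0.065 * u,
                noise_sigma=0.3 + 0.9 * u,
                seed=child_seed,
            )
        evaluated = apply_perturbation(reference, spec)
        cases.append(
            CohortCase(
                case_id=f"QA{k + 1}",
                reference=reference,
                evaluated=evaluated,
                perturbation=spec,
                severity=k / (n_cases - 1),
            )
        )
    return cases
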