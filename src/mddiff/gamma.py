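"""Gamma-index evaluation of 2D dose distributions.

The gamma index at a reference point r_r is the minimum, over evaluated
positions r_e, of the combined dose/distance mismatch

    Gamma(r_r, r_e) = sqrt( |r_e - r_r|^2 / DTA0^2
                            + (D_eval(r_e) - D_ref(r_r))^2 / deltaD0^2 )

with gamma(r_r) = min_{r_e} Gamma; gamma >= 1 fails. The dose criterion
deltaD0 is global (absolute cGy, typically a percentage of the prescribed
dose); the evaluated distribution is bilinearly refined by an integer
``subsample_factor`` before the search, which is restricted to a disc of
``search_radius`` mm around each reference point.

:func:`gamma_map` is the production implementation (vectorized window
search on the refined grid). :func:`gamma_bruteforce` re-derives the same
quantity by plain enumeration of every refined node with hand-written
bilinear interpolation — it exists purely as an independent oracle for
testing and is O(m * n) where m and n are the reference and refined
evaluated point counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dose_model import (
    METRIC_GAMMA,
    Criteria,
    DoseGrid,
    GeometryError,
    MetricMap,
    PassResult,
    ValidationError,
)

__all__ = [
    "GammaOptions",
    "default_search_radius",
    "gamma_map",
    "gamma_bruteforce",
    "gamma_pass_mask",
]


@dataclass(frozen=True)
class GammaOptions:
    """Search parameters for the gamma evaluation.

    search_radius
        Maximum spatial search distance in mm; must be >= DTA0. ``None``
        selects :func:`default_search_radius`.
    subsample_factor
        Integer >= 1; the evaluated grid is bilinearly refined to
        ``spacing / subsample_factor`` before the search.
    """

    search_radius: float | None = None
    subsample_factor: int = 4

    def __post_init__(self) -> None:
        if int(self.subsample_factor) != self.subsample_factor or self.subsample_factor < 1:
            raise ValidationError(
                f"subsample_factor: must be an integer >= 1, got {self.subsample_factor}"
            )
        object.__setattr__(self, "subsample_factor", int(self.subsample_factor))

    def resolve_radius(self, criteria: Criteria, evaluated: DoseGrid) -> float:
        radius = (
            default_search_radius(criteria, evaluated)
            if self.search_radius is None
            else float(self.search_radius)
        )
        if radius < criteria.dta_criterion:
            raise ValidationError(
                f"search_radius: {radius} mm is smaller than the DTA criterion "
                f"{criteria.dta_criterion} mm"
            )
        return radius


def default_search_radius(criteria: Criteria, evaluated: DoseGrid) -> float:
    """max(3*DTA0, DTA0 + 2*max pixel spacing) — wide enough that the
    spatial term alone exceeds 3 at the rim, so the true minimum for any
    point with gamma <~ 3 lies inside the disc."""
    return max(
        3.0 * criteria.dta_criterion,
        criteria.dta_criterion + 2.0 * max(evaluated.spacing),
    )


def _fine_axes(evaluated: DoseGrid, factor: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates of the refined evaluated lattice."""
    nx, ny = evaluated.shape
    fx = evaluated.origin[0] + np.arange((nx - 1) * factor + 1) * (
        evaluated.spacing[0] / factor
    )
    fy = evaluated.origin[1] + np.arange((ny - 1) * factor + 1) * (
        evaluated.spacing[1] / factor
    )
    return fx, fy


def _disc_inside(x: float, y: float, radius: float, evaluated: DoseGrid) -> bool:
    """Whether the search disc around (x, y) lies fully inside the evaluated extent."""
    xmin, xmax, ymin, ymax = evaluated.extent
    tol = 1e-9
    return (
        x - radius >= xmin - tol
        and x + radius <= xmax + tol
        and y - radius >= ymin - tol
        and y + radius <= ymax + tol
    )


def _check_grids(evaluated: DoseGrid, reference: DoseGrid) -> None:
    if evaluated.shape[0] < 2 or evaluated.shape[1] < 2:
        raise GeometryError("gamma evaluation needs an evaluated grid of at least 2x2")
    exmin, exmax, eymin, eymax = evaluated.extent
    rxmin, rxmax, rymin, rymax = reference.extent
    if exmin > rxmax or exmax < rxmin or eymin > rymax or eymax < rymin:
        raise GeometryError("evaluated and reference grids have no overlapping extent")


def gamma_map(
    evaluated: DoseGrid,
    reference: DoseGrid,
    criteria: Criteria,
    options: GammaOptions | None = None,
    op_counter: dict | None = None,
) -> MetricMap:
    """Compute the gamma map on the reference grid.

    Reference points whose search disc is clipped by the evaluated extent
    still receive a gamma from the available candidates but are flagged
    invalid in ``valid_mask`` (so do points with no candidate at all,
    which get value 0 and are never counted).

    ``op_counter`` — optional dict; ``"candidate_evaluations"`` accumulates
    the number of (reference point, refined candidate) pairs examined.
    """
    options = options or GammaOptions()
    _check_grids(evaluated, reference)
    radius = options.resolve_radius(criteria, evaluated)
    fx, fy = _fine_axes(evaluated, options.subsample_factor)
    interp = RegularGridInterpolator(
        (evaluated.x_axis, evaluated.y_axis),
        evaluated.values,
        method="linear",
        bounds_error=False,
        fill_value=None,  # linear extrapolation absorbs end-of-axis rounding
    )
    fxx, fyy = np.meshgrid(fx, fy, indexing="ij")
    fine = interp(np.stack([fxx.ravel(), fyy.ravel()], axis=1)).reshape(
        fxx.shape
    )

    dta2 = criteria.dta_criterion**2
    dd = criteria.dose_diff_criterion
    r2 = radius * radius
    ref_vals = reference.values
    rx, ry = reference.x_axis, reference.y_axis

    out = np.zeros(reference.shape)
    valid = np.zeros(reference.shape, dtype=bool)
    n_candidates = 0

    for i, xr in enumerate(rx):
        i0 = int(np.searchsorted(fx, xr - radius, side="left"))
        i1 = int(np.searchsorted(fx, xr + radius, side="right"))
        if i0 >= i1:
            continue
        dx2 = (fx[i0:i1] - xr) ** 2
        for j, yr in enumerate(ry):
            j0 = int(np.searchsorted(fy, yr - radius, side="left"))
            j1 = int(np.searchsorted(fy, yr + radius, side="right"))
            if j0 >= j1:
                continue
            dy2 = (fy[j0:j1] - yr) ** 2
            d2 = dx2[:, None] + dy2[None, :]
            inside = d2 <= r2
            if not inside.any():
                continue
            window = fine[i0:i1, j0:j1]
            g2 = d2 / dta2 + ((window - ref_vals[i, j]) / dd) ** 2
            g2 = np.where(inside, g2, np.inf)
            out[i, j] = math.sqrt(float(g2.min()))
            valid[i, j] = _disc_inside(xr, yr, radius, evaluated)
            n_candidates += int(inside.sum())

    if op_counter is not None:
        op_counter["candidate_evaluations"] = (
            op_counter.get("candidate_evaluations", 0) + n_candidates
        )
    return MetricMap(out, valid, METRIC_GAMMA)


def _bilinear(evaluated: DoseGrid, x: float, y: float) -> float:
    # hand-written bilinear (with linear extrapolation past the last cell),
    # intentionally independent of scipy for the oracle
    (x0, y0), (dx, dy) = evaluated.origin, evaluated.spacing
    nx, ny = evaluated.shape
    v = evaluated.values
    tx = (x - x0) / dx
    ty = (y - y0) / dy
    i = min(max(int(math.floor(tx)), 0), nx - 2)
    j = min(max(int(math.floor(ty)), 0), ny - 2)
    wx = tx - i
    wy = ty - j
    return (
        (1 - wx) * (1 - wy) * v[i, j]
        + wx * (1 - wy) * v[i + 1, j]
        + (1 - wx) * wy * v[i, j + 1]
        + wx * wy * v[i + 1, j + 1]
    )


def gamma_bruteforce(
    evaluated: DoseGrid,
    reference: DoseGrid,
    criteria: Criteria,
    options: GammaOptions | None = None,
    op_counter: dict | None = None,
) -> MetricMap:
    """Exhaustive-enumeration gamma: identical contract to :func:`gamma_map`.

    Every refined evaluated node within the search radius of every
    reference point is examined, with no windowing, pruning or shortcuts.
    Intended for small grids only.
    """
    options = options or GammaOptions()
    _check_grids(evaluated, reference)
    radius = options.resolve_radius(criteria, evaluated)
    fx, fy = _fine_axes(evaluated, options.subsample_factor)
    fine = [[_bilinear(evaluated, x, y) for y in fy] for x in fx]

    dta2 = criteria.dta_criterion**2
    dd = criteria.dose_diff_criterion
    r2 = radius * radius
    out = np.zeros(reference.shape)
    valid = np.zeros(reference.shape, dtype=bool)
    n_candidates = 0

    for i, xr in enumerate(reference.x_axis):
        for j, yr in enumerate(reference.y_axis):
            dref = reference.values[i, j]
            best = math.inf
            for k, xe in enumerate(fx):
                ddx2 = (xe - xr) ** 2
                for l, ye in enumerate(fy):
                    d2 = ddx2 + (ye - yr) ** 2
                    if d2 > r2:
                        continue
                    n_candidates += 1
                    g2 = d2 / dta2 + ((fine[k][l] - dref) / dd) ** 2
                    if g2 < best:
                        best = g2
            if math.isinf(best):
                continue
            out[i, j] = math.sqrt(best)
            valid[i, j] = _disc_inside(xr, yr, radius, evaluated)

    if op_counter is not None:
        op_counter["candidate_evaluations"] = (
            op_counter.get("candidate_evaluations", 0) + n_candidates
        )
    return MetricMap(out, valid, METRIC_GAMMA)


def gamma_pass_mask(metric_map: MetricMap) -> PassResult:
    """Apply the gamma pass/fail rule: a point fails when gamma >= 1."""
    if metric_map.metric_name != METRIC_GAMMA:
        raise TypeError(
            f"gamma_pass_mask expects a '{METRIC_GAMMA}' map, got "
            f"'{metric_map.metric_name}'"
        )
    n_valid = metric_map.n_valid
    if n_valid == 0:
        raise ValidationError("metric map has no valid points")
    failing = (metric_map.values >= 1.0) & metric_map.valid_mask
    count = int(failing.sum())
    return PassResult(failing, count, count / n_valid)
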