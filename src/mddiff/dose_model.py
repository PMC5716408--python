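"""Core data types for planar dose comparison.

A :class:`DoseGrid` is a regular 2D scalar field of absorbed dose in cGy.
The geometric convention, used consistently by every metric in this
package, is:

* array axis 0 is the physical x direction, axis 1 is y;
* ``values[i, j]`` is the dose at the *center* of pixel ``(i, j)``;
* the pixel-(0,0) center sits at ``origin`` (mm), and centers are spaced
  ``spacing`` (mm) apart along each axis.

Doses are stored in absolute cGy. A dose-difference criterion given as a
percentage is converted once, at :class:`Criteria` construction, into
cGy of the prescribed dose (global normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DoseGrid",
    "Criteria",
    "MetricMap",
    "PassResult",
    "ValidationError",
    "GeometryError",
    "make_grid",
    "pixel_to_physical",
    "resample_to_reference",
]


class ValidationError(ValueError):
    """An input violates a type invariant (negative dose, NaN, bad spacing...)."""


class GeometryError(ValueError):
    """Grids are geometrically incompatible (shape mismatch, zero overlap...)."""


@dataclass(frozen=True)
class DoseGrid:
    """A regular 2D dose distribution.

    Parameters
    ----------
    values
        2D array of dose in cGy, shape ``(nx, ny)``; finite and >= 0.
    spacing
        ``(dx, dy)`` pixel pitch in mm, both strictly positive.
    origin
        ``(x0, y0)`` physical position in mm of the center of pixel (0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"values: expected a 2D array, got ndim={values.ndim}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValidationError(f"values: empty grid of shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("values: dose array contains non-finite entries")
        if np.any(values < 0):
            raise ValidationError("values: dose array contains negative entries")
        spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if not all(np.isfinite(spacing)) or spacing[0] <= 0 or spacing[1] <= 0:
            raise ValidationError(f"spacing: must be strictly positive, got {spacing}")
        origin = (float(self.origin[0]), float(self.origin[1]))
        if not all(np.isfinite(origin)):
            raise ValidationError(f"origin: must be finite, got {origin}")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_axis(self) -> np.ndarray:
        """Physical x coordinates (mm) of pixel centers along axis 0."""
        return self.origin[0] + np.arange(self.shape[0]) * self.spacing[0]

    @property
    def y_axis(self) -> np.ndarray:
        """Physical y coordinates (mm) of pixel centers along axis 1."""
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of pixel centers, mm."""
        x, y = self.x_axis, self.y_axis
        return (float(x[0]), float(x[-1]), float(y[0]), float(y[-1]))

    def same_geometry(self, other: "DoseGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass(frozen=True)
class Criteria:
    """Acceptance criteria shared by the gamma and MDdiff evaluations.

    ``dose_diff_criterion`` is the dose tolerance deltaD0 in cGy (e.g. 3% of
    a 200 cGy prescription = 6 cGy), ``dta_criterion`` the distance-to-
    agreement tolerance DTA0 in mm, and ``prescribed_dose`` the prescription
    in cGy used for percentage-to-absolute conversion.
    """

    dose_diff_criterion: float
    dta_criterion: float
    prescribed_dose: float

    def __post_init__(self) -> None:
        for name in ("dose_diff_criterion", "dta_criterion", "prescribed_dose"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name}: must be strictly positive, got {v}")
            object.__setattr__(self, name, v)

    @classmethod
    def from_percent(
        cls, dose_diff_percent: float, dta_mm: float, prescribed_dose: float
    ) -> "Criteria":
        """Build criteria with the dose tolerance given as % of prescription."""
        if prescribed_dose <= 0:
            raise ValidationError(f"prescribed_dose: must be strictly positive, got {prescribed_dose}")
        return cls(dose_diff_percent / 100.0 * prescribed_dose, dta_mm, prescribed_dose)

    @classmethod
    def parse(cls, dose_diff: str | float, dta_mm: float, prescribed_dose: float) -> "Criteria":
        """Parse a dose criterion given either in cGy or as e.g. ``"3%"``."""
        if isinstance(dose_diff, str) and dose_diff.strip().endswith("%"):
            return cls.from_percent(float(dose_diff.strip()[:-1]), dta_mm, prescribed_dose)
        return cls(float(dose_diff), dta_mm, prescribed_dose)

    @property
    def mddiff_critical_value(self) -> float:
        """Critical value for MDdiff pass/fail: half the dose criterion, cGy."""
        return 0.5 * self.dose_diff_criterion


#: Metric labels recognised by the pass-rule and summary machinery.
METRIC_MDDIFF = "mddiff"
METRIC_GAMMA = "gamma"
METRIC_DOSE_DIFF = "dose_difference"


@dataclass(frozen=True)
class MetricMap:
    """Per-point metric values on the reference grid.

    ``values`` are signed cGy for MDdiff / plain dose difference, unitless
    and >= 0 for gamma. Points where the metric is undefined (e.g. the
    evaluated distribution does not cover them) carry ``valid_mask=False``
    and are excluded from all counts and statistics.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if values.ndim != 2:
            raise ValidationError(f"values: expected 2D array, got ndim={values.ndim}")
        if mask.shape != values.shape:
            raise ValidationError(
                f"valid_mask: shape {mask.shape} does not match values shape {values.shape}"
            )
        if not np.all(np.isfinite(values[mask])):
            raise ValidationError("values: non-finite entries at valid points")
        if self.metric_name == METRIC_GAMMA and np.any(values[mask] < 0):
            raise ValidationError("values: gamma map has negative valid entries")
        values.setflags(write=False)
        mask.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


class PassResult(NamedTuple):
    """Outcome of a pass/fail rule applied to a metric map."""

    failing_mask: np.ndarray
    failing_count: int
    failing_ratio: float


def make_grid(
    values: np.ndarray,
    spacing: tuple[float, float],
    origin: tuple[float, float] = (0.0, 0.0),
) -> DoseGrid:
    """Validate and wrap a dose array into a :class:`DoseGrid`."""
    return DoseGrid(np.asarray(values, dtype=float), tuple(spacing), tuple(origin))


def pixel_to_physical(grid: DoseGrid, index: tuple[int, int]) -> tuple[float, float]:
    """Physical (x, y) in mm of the center of pixel ``index = (i, j)``."""
    i, j = int(index[0]), int(index[1])
    nx, ny = grid.shape
    if not (0 <= i < nx and 0 <= j < ny):
        raise IndexError(f"pixel index {(i, j)} out of range for grid shape {(nx, ny)}")
    return (
        grid.origin[0] + i * grid.spacing[0],
        grid.origin[1] + j * grid.spacing[1],
    )


def resample_to_reference(
    evaluated: DoseGrid, reference: DoseGrid
) -> tuple[DoseGrid, np.ndarray]:
    """Bilinearly interpolate the evaluated dose onto the reference grid.

    Reference pixel centers outside the evaluated extent are *not*
    extrapolated; they are returned as 0 cGy with ``valid_mask=False``.

    Returns
    -------
    (grid, valid_mask)
        The resampled evaluated dose on the reference geometry, and the
        boolean mask of reference points actually covered by the
        evaluated distribution.
    """
    if evaluated.same_geometry(reference):
        return (
            DoseGrid(evaluated.values, reference.spacing, reference.origin),
            np.ones(reference.shape, dtype=bool),
        )

    exmin, exmax, eymin, eymax = evaluated.extent
    rxmin, rxmax, rymin, rymax = reference.extent
    if exmin > rxmax or exmax < rxmin or eymin > rymax or eymax < rymin:
        raise GeometryError(
            "evaluated and reference grids have no overlapping physical extent"
        )

    if evaluated.shape[0] < 2 or evaluated.shape[1] < 2:
        raise GeometryError("evaluated grid must be at least 2x2 for bilinear resampling")

    interp = RegularGridInterpolator(
        (evaluated.x_axis, evaluated.y_axis),
        evaluated.values,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    xx, yy = np.meshgrid(reference.x_axis, reference.y_axis, indexing="ij")
    vals = interp(np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(reference.shape)
    valid = np.isfinite(vals)
    if not valid.any():
        raise GeometryError("no reference pixel center lies inside the evaluated extent")
    vals = np.where(valid, vals, 0.0)
    # interpolation of non-negative data can produce -0.0 / tiny negatives
    vals = np.maximum(vals, 0.0)
    return DoseGrid(vals, reference.spacing, reference.origin), valid
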