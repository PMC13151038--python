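"""Normalized forest growth-dynamics curves.

Stand-level simulators output age series for two attributes that drive the
ecosystem services modeled here: tree crown cover (the surface available for
dry deposition of NOx, ozone and PM2.5) and the annual change of live carbon
above and below ground (the biogenic sequestration rate).  Both series are
normalized by their maximum and summarized by a low-order polynomial in stand
age, so every downstream coefficient is "full-maturity value x g(age)" with
g in [0, 1] for crown cover and in [-1, 1] for carbon — young stands respire
more carbon than they fix, so the carbon curve starts negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeriesError, DomainError, FitError, ValidationError

ATTRIBUTES = ("crown_cover", "live_carbon")


@dataclass
class GrowthSeries:
    """Raw age series of a growth attribute, in native units."""

    attribute: str
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTES:
            raise ValidationError(f"unknown growth attribute '{self.attribute}'")
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.size != self.values.size:
            raise ValidationError("ages and values differ in length")
        if np.any(self.ages < 0):
            raise DomainError("ages must be >= 0")
        if np.any(np.diff(self.ages) <= 0):
            raise ValidationError("ages must be strictly increasing")


@dataclass
class GrowthCurve:
    """Polynomial summary of a normalized growth series.

    ``coefficients`` are in descending powers (numpy.polyval convention);
    degree 5 gives six coefficients.  Evaluation outside ``domain`` holds the
    endpoint value constant, and values are clamped to [0, 1] for crown cover
    and [-1, 1] for live carbon to guard against polynomial wiggle.
    """

    attribute: str
    coefficients: np.ndarray
    domain: tuple[float, float]
    r_squared: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.domain = (float(self.domain[0]), float(self.domain[1]))

    def __call__(self, age):
        return eval_growth(self, age)

    def to_json(self) -> str:
        return json.dumps(
            {
                "attribute": self.attribute,
                "coefficients": self.coefficients.tolist(),
                "domain": list(self.domain),
                "r_squared": self.r_squared,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GrowthCurve":
        d = json.loads(text)
        return cls(
            attribute=d["attribute"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            domain=tuple(d["domain"]),
            r_squared=float(d["r_squared"]),
        )


def fit_growth_curve(series: GrowthSeries, degree: int = 5) -> GrowthCurve:
    """Normalize a growth series by its maximum and fit an OLS polynomial.

    R-squared is computed on the normalized data; a zero-variance (constant)
    target is a degenerate but well-posed case for which R-squared is defined
    as 1.

    Raises
    ------
    FitError
        If the series has fewer than ``degree + 2`` points.
    DegenerateSeriesError
        If the series maximum is not positive (nothing to normalize by).
    """
    if series.ages.size < degree + 2:
        raise FitError(
            f"need at least {degree + 2} points for degree {degree}, got {series.ages.size}"
        )
    vmax = float(np.max(series.values))
    if vmax <= 0:
        raise DegenerateSeriesError("series maximum must be > 0 to normalize")
    y = series.values / vmax
    coeffs = np.polyfit(series.ages, y, degree)
    fitted = np.polyval(coeffs, series.ages)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return GrowthCurve(
        attribute=series.attribute,
        coefficients=coeffs,
        domain=(float(series.ages[0]), float(series.ages[-1])),
        r_squared=r2,
    )


def eval_growth(curve: GrowthCurve, age):
    """Evaluate the growth ratio g(age).

    Ages beyond the fitted domain return the domain-endpoint value (the
    fitted horizon is typically 80 years and extrapolating a quintic is
    meaningless).  Crown-cover values clamp to [0, 1]; live-carbon values to
    [-1, 1].
    """
    arr = np.asarray(age, dtype=float)
    if np.any(arr < 0):
        raise DomainError("age must be >= 0")
    clipped = np.clip(arr, curve.domain[0], curve.domain[1])
    val = np.polyval(curve.coefficients, clipped)
    lo = 0.0 if curve.attribute == "crown_cover" else -1.0
    val = np.clip(val, lo, 1.0)
    return float(val) if np.isscalar(age) else val


def carbon_crossover_age(
    curve: GrowthCurve, step: float = 1.0, tol: float = 1e-9
) -> float | None:
    """Smallest age from which the curve's annual increment stays positive.

    Evaluated on an age lattice of the given step over the fitted domain: the
    result is the first lattice age whose increment and the next increment
    are both positive.  Returns 0 for a curve that increases from the start
    and ``None`` if no such age exists (e.g. a flat curve).
    """
    if curve.attribute != "live_carbon":
        raise ValidationError("crossover is defined for live-carbon curves")
    lo, hi = curve.domain
    ages = np.arange(lo, hi + step / 2, step)
    vals = eval_growth(curve, ages)
    inc = np.diff(vals)
    for k in range(inc.size - 1):
        if inc[k] > tol and inc[k + 1] > tol:  # tol guards fit noise on flat curves
            return float(ages[k])
    return None
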