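"""Biogenic carbon sequestration and its social valuation.

A planted receptor sequesters carbon at the county-average rate Vc (tonnes
CO2/ha/yr, assumed to be the peak-growth rate) scaled by the live-carbon
growth ratio g_carbon(age) — negative for young stands, which respire more
than they fix — and by a scenario-level additionality fraction R that
discounts for forest already standing on convertible land.  Total uptake
(technological capture plus biogenic sequestration) is valued linearly at
the social cost of carbon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .growth import GrowthCurve, eval_growth
from .landscape import ReceptorGrid

#: metric tonnes per US short ton
SHORT_TON_IN_TONNES = 0.90718474

#: county-average peak sequestration rate, tonnes CO2 / ha / yr
DEFAULT_VC = 11.2

#: social cost of carbon, USD per metric tonne (USD 51 per short ton)
DEFAULT_SCC = 56.2


def scc_per_tonne(usd_per_short_ton: float) -> float:
    """Convert a price per US short ton to a price per metric tonne."""
    if usd_per_short_ton < 0:
        raise DomainError("price must be >= 0")
    return usd_per_short_ton / SHORT_TON_IN_TONNES


@dataclass
class CarbonModel:
    """Coefficients of the sequestration model for one landscape.

    ``area_ha`` is the per-receptor plantable area (cell area for the
    receptors eligible for conversion); ``unit_conversion`` collects any
    remaining unit factors from (rate x area) to tonnes/yr (1 when Vc is
    already tonnes/ha/yr and areas are hectares).
    """

    vc: float
    r: float
    area_ha: np.ndarray
    carbon_curve: GrowthCurve
    unit_conversion: float = 1.0

    def __post_init__(self) -> None:
        if self.vc <= 0:
            raise ValidationError("Vc must be > 0")
        if not (0.0 <= self.r <= 1.0):
            raise ValidationError("R must lie in [0, 1]")
        self.area_ha = np.asarray(self.area_ha, dtype=float)

    def receptor_rate(self) -> np.ndarray:
        """Full-maturity sequestration rate per receptor, tonnes CO2/yr."""
        return self.unit_conversion * self.vc * self.r * self.area_ha


@dataclass
class SocialCostCarbon:
    """USD per tonne CO2 removed; optionally a year-indexed series."""

    usd_per_tonne: float = DEFAULT_SCC
    series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.usd_per_tonne <= 0:
            raise ValidationError("social cost of carbon must be > 0")
        if self.series is not None:
            self.series = np.asarray(self.series, dtype=float)

    def at(self, year: int) -> float:
        if self.series is not None and 0 <= year < self.series.size:
            return float(self.series[year])
        return self.usd_per_tonne


def additionality_fraction(grid: ReceptorGrid) -> float:
    """Fraction of full-conversion forest area that is newly created.

    Under full conversion every unconstrained receptor becomes fully
    forested, so the new forest area is the unconstrained area minus the
    forest already standing within it, and R divides that by the total
    forest area of the converted state (the unconstrained area itself).
    Only additional sequestration is then credited.
    """
    unc = grid.unconstrained
    total = float(np.sum(unc)) * grid.area_ha
    if total <= 0:
        raise ValidationError("no unconstrained area: additionality undefined")
    existing = float(np.sum(grid.landcover["forest"][unc])) * grid.area_ha
    return (total - existing) / total


def _validate_planting(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E)
    if not np.all(np.isin(E, (0, 1))):
        raise ValidationError("planting matrix must be binary")
    if np.any(E.sum(axis=0) > 1):
        raise ValidationError("a receptor may be planted at most once")
    return E.astype(float)


def sequestration_rate(E: np.ndarray, model: CarbonModel, n: int) -> float:
    """Biogenic sequestration rate chi_n (tonnes CO2/yr) at year ``n``.

    ``E`` is the binary planting matrix [year, receptor], 1 only at the
    planting year.  Each planted receptor contributes its full-maturity rate
    scaled by g_carbon(n - h) where h is its planting year, so the total is
    a maturity-weighted sum over all standing plantings (linear in E).
    """
    E = _validate_planting(E)
    rates = model.receptor_rate()
    total = 0.0
    for h in range(min(n, E.shape[0] - 1) + 1):
        g = eval_growth(model.carbon_curve, float(n - h))
        total += g * float(E[h] @ rates)
    return total


def sequestration_series(E: np.ndarray, model: CarbonModel, horizon: int) -> np.ndarray:
    """chi_n for n = 0 .. horizon-1 (vectorized over planting cohorts)."""
    E = _validate_planting(E)
    rates = model.receptor_rate()
    cohort = E @ rates  # tonnes/yr at full maturity planted in each year
    g = eval_growth(model.carbon_curve, np.arange(horizon, dtype=float))
    out = np.zeros(horizon)
    H = E.shape[0]
    for h in range(min(H, horizon)):
        if cohort[h] != 0.0:
            out[h:] += cohort[h] * g[: horizon - h]
    return out


@dataclass
class CarbonValue:
    annual_usd: np.ndarray
    total_usd: float
    annualized_usd: float


def value_carbon(uptake_by_year: np.ndarray, scc: SocialCostCarbon) -> CarbonValue:
    """Social value of an annual CO2-uptake series (tonnes/yr -> USD).

    Uptake here is the total removal credited to the system — technological
    capture plus biogenic sequestration.
    """
    uptake = np.asarray(uptake_by_year, dtype=float)
    if np.any(uptake < 0):
        raise DomainError("uptake series must be >= 0")
    prices = np.array([scc.at(n) for n in range(uptake.size)])
    annual = prices * uptake
    total = float(np.sum(annual))
    return CarbonValue(annual_usd=annual, total_usd=total, annualized_usd=total / max(uptake.size, 1))
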