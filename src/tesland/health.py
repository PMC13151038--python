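"""Health impact functions and their monetization.

The epidemiological log-linear concentration-response model gives averted
incidences for a concentration reduction dC at a receptor:

    dY = Y0 * (1 - exp(-beta * dC)) * P

with Y0 the baseline incidence rate, beta the effect estimate and P the
exposed population.  Averted incidences are monetized linearly at a value
per incidence — for all-cause mortality, the value of a statistical life
(VSL).  Uncertainty is propagated by Monte Carlo: beta is drawn from a
Normal with the study's reported mean/SD (independently per pollutant) and
the VSL from a Weibull distribution calibrated to its mean.

Benefits realize gradually as planted stands grow: the full-maturity
monetized benefit of a receptor is scaled by the crown-cover growth ratio
g_crown(age), since dry deposition — the mechanism lowering ambient PM2.5
and ozone — scales with leaf area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma
from scipy.stats import weibull_min

from .errors import DomainError, StructureError, ValidationError
from .growth import GrowthCurve, eval_growth
from .landscape import DeltaFields, PopulationLayer, ReceptorGrid

#: all-cause, all-age mortality effect estimates per unit concentration
#: (PM2.5 per ug/m3, ozone per ppb), mean and SD from the single cohort
#: study covering both pollutants.
DEFAULT_HIFS = {
    "pm25": (0.005826891, 0.000962763),
    "o3": (0.001980263, 0.000500216),
}

#: mean value of a statistical life, 2021 USD
DEFAULT_VSL = 8.7e6

#: default Weibull shape for the VSL distribution; the scale is calibrated
#: so the distribution mean equals the configured VSL.
DEFAULT_VSL_WEIBULL_SHAPE = 1.51


@dataclass
class HealthImpactFunction:
    """Concentration-response effect estimate for one pollutant."""

    pollutant: str  # "pm25" | "o3"
    beta_mean: float
    beta_sd: float
    endpoint: str = "Mortality, All Causes"

    def __post_init__(self) -> None:
        if self.beta_mean <= 0:
            raise ValidationError("beta_mean must be > 0")
        if self.beta_sd < 0:
            raise ValidationError("beta_sd must be >= 0")


def default_impact_functions() -> list[HealthImpactFunction]:
    return [
        HealthImpactFunction(p, mean, sd) for p, (mean, sd) in DEFAULT_HIFS.items()
    ]


@dataclass
class IncidenceValuation:
    """Monetary value per incidence, with an optional Weibull distribution.

    When shape/scale are supplied the Weibull mean must reproduce
    ``mean_value`` within 1%.  :meth:`from_mean` calibrates the scale from a
    shape so this holds exactly.
    """

    mean_value: float
    weibull_shape: float | None = None
    weibull_scale: float | None = None

    def __post_init__(self) -> None:
        if self.mean_value <= 0:
            raise ValidationError("mean_value must be > 0")
        if (self.weibull_shape is None) != (self.weibull_scale is None):
            raise ValidationError("supply both Weibull parameters or neither")
        if self.weibull_shape is not None:
            wmean = self.weibull_scale * _gamma(1.0 + 1.0 / self.weibull_shape)
            if abs(wmean - self.mean_value) > 0.01 * self.mean_value:
                raise ValidationError(
                    f"Weibull mean {wmean:.4g} is off the stated mean {self.mean_value:.4g} by >1%"
                )

    @classmethod
    def from_mean(
        cls, mean_value: float = DEFAULT_VSL, shape: float = DEFAULT_VSL_WEIBULL_SHAPE
    ) -> "IncidenceValuation":
        scale = mean_value / _gamma(1.0 + 1.0 / shape)
        return cls(mean_value=mean_value, weibull_shape=shape, weibull_scale=scale)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.weibull_shape is None:
            return np.full(size, self.mean_value)
        return weibull_min.rvs(
            self.weibull_shape, scale=self.weibull_scale, size=size, random_state=rng
        )


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def delta_incidence(y0, beta, dC, population):
    """Averted incidences/yr: ``Y0 * (1 - exp(-beta*dC)) * P``.

    All arguments broadcast; the result is bounded above by ``Y0 * P``.
    """
    y0 = np.asarray(y0, dtype=float)
    beta = np.asarray(beta, dtype=float)
    dC = np.asarray(dC, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(y0 < 0) or np.any(y0 > 1):
        raise DomainError("y0 must lie in [0, 1]")
    if np.any(beta < 0) or np.any(dC < 0) or np.any(population < 0):
        raise DomainError("beta, dC and population must be >= 0")
    out = y0 * (-np.expm1(-beta * dC)) * population
    return float(out) if out.ndim == 0 else out


def value_health(dY, valuation: IncidenceValuation, unit_value: float | None = None):
    """Monetize averted incidences: ``dY * z``.

    ``unit_value`` overrides the valuation mean (used for Monte Carlo draws).
    """
    dY = np.asarray(dY, dtype=float)
    if np.any(dY < 0):
        raise DomainError("averted incidences must be >= 0")
    z = valuation.mean_value if unit_value is None else unit_value
    out = dY * z
    return float(out) if out.ndim == 0 else out


@dataclass
class BenefitSchedule:
    """Per-receptor, per-stand-age monetized health benefit.

    ``usd[i, a]`` is the annual benefit (USD/yr) a stand of age ``a`` at
    receptor ``i`` delivers; ``incidences[i, a]`` the corresponding averted
    incidences/yr summed over pollutants.  ``full_usd`` / ``full_incidence``
    are the age-independent full-maturity values (g_crown = 1).
    """

    ages: np.ndarray
    usd: np.ndarray
    incidences: np.ndarray
    full_usd: np.ndarray
    full_incidence: np.ndarray
    full_incidence_by_pollutant: dict[str, np.ndarray] = field(default_factory=dict)


def benefit_schedule(
    grid: ReceptorGrid,
    fields: DeltaFields,
    pop: PopulationLayer,
    hifs: list[HealthImpactFunction],
    valuation: IncidenceValuation,
    crown: GrowthCurve,
    horizon: int,
) -> BenefitSchedule:
    """Precompute the growth-scaled benefit schedule for every receptor.

    The full-maturity benefit uses the concentration deltas of the fully
    afforested state; the age dimension applies g_crown(age) as a multiplier
    on the monetized benefit.  Constrained receptors have zero deltas by
    construction and therefore zero benefit at every age.
    """
    n = grid.n_receptors
    if pop.population.size != n or any(v.size != n for v in fields.dC.values()):
        raise StructureError("grid, fields and population are misaligned")
    full_by_p: dict[str, np.ndarray] = {}
    for hif in hifs:
        if hif.pollutant not in fields.dC:
            raise StructureError(f"no concentration delta for pollutant '{hif.pollutant}'")
        full_by_p[hif.pollutant] = delta_incidence(
            pop.y0, hif.beta_mean, fields.dC[hif.pollutant], pop.population
        )
    full_incidence = np.sum(list(full_by_p.values()), axis=0)
    full_usd = value_health(full_incidence, valuation)
    ages = np.arange(horizon + 1, dtype=float)
    g = eval_growth(crown, ages)
    return BenefitSchedule(
        ages=ages,
        usd=np.outer(full_usd, g),
        incidences=np.outer(full_incidence, g),
        full_usd=full_usd,
        full_incidence=full_incidence,
        full_incidence_by_pollutant=full_by_p,
    )


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty propagation
# ---------------------------------------------------------------------------


@dataclass
class ExposureSummary:
    """Crown-weighted exposure aggregates of a fixed land-use plan.

    ``weight[i]`` is the horizon-averaged crown-cover intensity of receptor
    ``i`` under the plan, i.e. ``(1/H) * sum_n sum_{h<=n} E[h,i] *
    g_crown(n-h)``; annualized averted incidences for an effect estimate
    beta_p are ``sum_i weight[i] * Y0_i * (1 - exp(-beta_p dC_p,i)) * P_i``.
    """

    weight: np.ndarray
    dC: dict[str, np.ndarray]
    y0: np.ndarray
    population: np.ndarray

    def averted(self, betas: dict[str, float]) -> float:
        total = 0.0
        for p, beta in betas.items():
            total += float(
                np.sum(
                    self.weight
                    * delta_incidence(self.y0, beta, self.dC[p], self.population)
                )
            )
        return total


@dataclass
class MonteCarloCI:
    """2.5th percentile, mean and 97.5th percentile of sampled quantities."""

    incidence: tuple[float, float, float]
    usd: tuple[float, float, float]
    n_draws: int
    n_negative_beta: int


def monte_carlo_ci(
    exposure: ExposureSummary,
    hifs: list[HealthImpactFunction],
    valuation: IncidenceValuation,
    n_draws: int = 10_000,
    seed: int = 0,
    carbon_usd: float = 0.0,
) -> MonteCarloCI:
    """Propagate effect-estimate and valuation uncertainty on a fixed plan.

    Per draw, each pollutant's beta is sampled from Normal(mean, SD) — with
    negative draws floored at 0 and counted — and the value per incidence
    from the valuation's Weibull.  The plan itself is fixed: uncertainty
    shifts magnitudes, not the optimized land-use pattern.  ``carbon_usd``
    is an additive certain benefit included in the USD percentiles (climate
    benefits carry no sampled uncertainty here).
    """
    if n_draws < 2:
        raise ValidationError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    n_negative = 0
    averted = np.zeros(n_draws)
    for hif in hifs:
        betas = rng.normal(hif.beta_mean, hif.beta_sd, size=n_draws)
        n_negative += int(np.sum(betas < 0))
        betas = np.maximum(betas, 0.0)
        # draws x receptors, summed over receptors
        dY = (
            exposure.y0[None, :]
            * (-np.expm1(-np.outer(betas, exposure.dC[hif.pollutant])))
            * exposure.population[None, :]
        )
        averted += dY @ exposure.weight
    z = valuation.sample(rng, n_draws)
    usd = averted * z + carbon_usd
    lo_i, hi_i = np.percentile(averted, [2.5, 97.5])
    lo_u, hi_u = np.percentile(usd, [2.5, 97.5])
    return MonteCarloCI(
        incidence=(float(lo_i), float(np.mean(averted)), float(hi_i)),
        usd=(float(lo_u), float(np.mean(usd)), float(hi_u)),
        n_draws=n_draws,
        n_negative_beta=n_negative,
    )
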