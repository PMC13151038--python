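import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tesland.errors import DomainError, StructureError, ValidationError
from tesland.growth import GrowthSeries, fit_growth_curve
from tesland.health import (
    DEFAULT_HIFS,
    ExposureSummary,
    HealthImpactFunction,
    IncidenceValuation,
    benefit_schedule,
    delta_incidence,
    monte_carlo_ci,
    value_health,
)


def test_zero_concentration_change_averts_nothing():
    assert delta_incidence(0.008, 0.0058, 0.0, 10_000) == 0.0


def test_frozen_point_value():
    """Direct evaluation at the documented PM2.5 effect estimate."""
    out = delta_incidence(0.008, DEFAULT_HIFS["pm25"][0], 1.0, 10_000)
    assert out == pytest.approx(0.46479, abs=5e-5)


def test_small_signal_taylor_limit(rng):
    """For beta*dC <= 0.01 the response is linear to within 0.5%."""
    for _ in range(200):
        y0 = rng.uniform(1e-4, 0.05)
        beta = rng.uniform(1e-4, 0.01)
        dC = rng.uniform(0.0, 0.01 / beta)
        P = rng.uniform(0, 1e5)
        exact = delta_incidence(y0, beta, dC, P)
        linear = y0 * beta * dC * P
        assert exact == pytest.approx(linear, rel=5.1e-3)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    y0=st.floats(0.0, 1.0),
    beta=st.floats(0.0, 0.1),
    dC=st.floats(0.0, 50.0),
    pop=st.floats(0.0, 1e6),
    bump=st.floats(0.0, 0.5),
)
def test_monotone_and_bounded(y0, beta, dC, pop, bump):
    base = delta_incidence(y0, beta, dC, pop)
    assert 0.0 <= base <= y0 * pop + 1e-9
    assert delta_incidence(y0, beta, dC * (1 + bump), pop) >= base
    assert delta_incidence(y0, beta * (1 + bump), dC, pop) >= base
    assert delta_incidence(y0, beta, dC, pop * (1 + bump)) >= base


def test_negative_inputs_rejected():
    with pytest.raises(DomainError):
        delta_incidence(0.008, -0.001, 1.0, 100)
    with pytest.raises(DomainError):
        delta_incidence(1.5, 0.001, 1.0, 100)


def test_value_health_linearity():
    z = IncidenceValuation(mean_value=8.7e6)
    assert value_health(1.0, z) == pytest.approx(8.7e6)
    assert value_health(0.0, z) == 0.0
    assert value_health(2.5, IncidenceValuation(1e5)) == pytest.approx(2.5e5)
    with pytest.raises(DomainError):
        value_health(-1.0, z)


def test_weibull_calibration_reproduces_mean():
    z = IncidenceValuation.from_mean(8.7e6, shape=1.51)
    draws = z.sample(np.random.default_rng(0), 200_000)
    assert np.mean(draws) == pytest.approx(8.7e6, rel=0.01)


def test_inconsistent_weibull_parameters_rejected():
    with pytest.raises(ValidationError):
        IncidenceValuation(mean_value=8.7e6, weibull_shape=1.51, weibull_scale=1e6)
    with pytest.raises(ValidationError):
        IncidenceValuation(mean_value=8.7e6, weibull_shape=1.51)


@pytest.fixture(scope="module")
def toy_landscape():
    """Two unconstrained receptors, equal deltas, populations 1000 vs 10000."""
    from tesland.landscape import DeltaFields, PopulationLayer, ReceptorGrid

    grid = ReceptorGrid(
        receptor_id=[0, 1, 2],
        x_km=[0.0, 2.5, 5.0],
        y_km=[0.0, 0.0, 0.0],
        spacing_km=2.5,
        landcover={
            "developed": [0.1, 0.1, 0.9],
            "water": [0.0, 0.0, 0.0],
            "forest": [0.2, 0.2, 0.05],
            "agri_grass": [0.7, 0.7, 0.05],
            "barren": [0.0, 0.0, 0.0],
        },
    )
    fields = DeltaFields(
        dC={"pm25": [0.5, 0.5, 0.0], "o3": [1.0, 1.0, 0.0]},
        ddep={"nox": [1.0, 1.0, 0.0], "pm25": [0.5, 0.5, 0.0]},
    )
    pop = PopulationLayer(population=[1000.0, 10000.0, 5000.0], y0=[0.008, 0.008, 0.008])
    ages = np.arange(0.0, 21.0)
    crown = fit_growth_curve(GrowthSeries("crown_cover", ages, 1 - np.exp(-ages / 5)))
    return grid, fields, pop, crown


def test_benefit_schedule_linearity_in_population(toy_landscape):
    grid, fields, pop, crown = toy_landscape
    hifs = [HealthImpactFunction(p, m, sd) for p, (m, sd) in DEFAULT_HIFS.items()]
    z = IncidenceValuation(8.7e6)
    sched = benefit_schedule(grid, fields, pop, hifs, z, crown, horizon=20)
    # equal deltas: benefits scale with population 10:1
    assert sched.full_usd[1] == pytest.approx(10 * sched.full_usd[0], rel=1e-12)
    # constrained receptor has zero deltas, hence zero benefit at every age
    assert np.all(sched.usd[2] == 0.0)
    # growth scaling multiplies the full-maturity benefit
    np.testing.assert_allclose(
        sched.usd[1], sched.full_usd[1] * np.clip(np.polyval(crown.coefficients, np.clip(sched.ages, 0, 20)), 0, 1),
        rtol=1e-9,
    )


def test_benefit_schedule_zero_population_receptor(toy_landscape):
    grid, fields, pop, crown = toy_landscape
    pop.population[0] = 0.0
    hifs = [HealthImpactFunction(p, m, sd) for p, (m, sd) in DEFAULT_HIFS.items()]
    sched = benefit_schedule(grid, fields, pop, hifs, IncidenceValuation(8.7e6), crown, 20)
    assert np.all(sched.usd[0] == 0.0)
    pop.population[0] = 1000.0


def test_benefit_schedule_misaligned_inputs_raise(toy_landscape):
    from tesland.landscape import PopulationLayer

    grid, fields, _, crown = toy_landscape
    bad_pop = PopulationLayer(population=[1.0, 2.0], y0=[0.01, 0.01])
    hifs = [HealthImpactFunction("pm25", 0.005, 0.001)]
    with pytest.raises(StructureError):
        benefit_schedule(grid, fields, bad_pop, hifs, IncidenceValuation(8.7e6), crown, 5)


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------


def _exposure(n=50, seed=5):
    rng = np.random.default_rng(seed)
    return ExposureSummary(
        weight=rng.uniform(0.0, 0.6, n),
        dC={"pm25": rng.uniform(0, 0.8, n), "o3": rng.uniform(0, 2.0, n)},
        y0=np.full(n, 0.0088),
        population=rng.uniform(100, 30000, n),
    )


def _hifs():
    return [HealthImpactFunction(p, m, sd) for p, (m, sd) in DEFAULT_HIFS.items()]


def test_degenerate_distributions_collapse_to_point():
    exp = _exposure()
    hifs = [HealthImpactFunction(p, m, 0.0) for p, (m, _) in DEFAULT_HIFS.items()]
    z = IncidenceValuation(8.7e6)  # no Weibull: degenerate valuation
    ci = monte_carlo_ci(exp, hifs, z, n_draws=2000, seed=1)
    point = exp.averted({p: m for p, (m, _) in DEFAULT_HIFS.items()})
    assert ci.incidence[0] == pytest.approx(point, rel=1e-9)
    assert ci.incidence[2] == pytest.approx(point, rel=1e-9)
    assert ci.usd[0] == pytest.approx(point * 8.7e6, rel=1e-9)


def test_same_seed_reproduces_percentiles():
    exp = _exposure()
    z = IncidenceValuation.from_mean()
    a = monte_carlo_ci(exp, _hifs(), z, n_draws=3000, seed=42)
    b = monte_carlo_ci(exp, _hifs(), z, n_draws=3000, seed=42)
    assert a.incidence == b.incidence
    assert a.usd == b.usd


def test_ci_ordering():
    ci = monte_carlo_ci(_exposure(), _hifs(), IncidenceValuation.from_mean(), 3000, seed=2)
    lo, mean, hi = ci.incidence
    assert lo <= mean <= hi
    lo, mean, hi = ci.usd
    assert lo <= mean <= hi


def test_against_independent_sampler():
    """Percentiles match a from-scratch sampler within Monte Carlo error."""
    exp = _exposure(n=10)
    z = IncidenceValuation.from_mean()
    n = 600_000
    ci = monte_carlo_ci(exp, _hifs(), z, n_draws=n, seed=9)

    rng = stats.norm.rvs  # independent draw path via scipy.stats
    rstate = np.random.RandomState(777)
    averted = np.zeros(n)
    for hif in _hifs():
        betas = np.maximum(
            rng(loc=hif.beta_mean, scale=hif.beta_sd, size=n, random_state=rstate), 0.0
        )
        for b_idx in range(0, n, 8000):  # chunked to bound memory
            chunk = betas[b_idx : b_idx + 8000, None]
            dY = exp.y0 * (1 - np.exp(-chunk * exp.dC[hif.pollutant])) * exp.population
            averted[b_idx : b_idx + 8000] += dY @ exp.weight
    vals = stats.weibull_min.rvs(
        z.weibull_shape, scale=z.weibull_scale, size=n, random_state=rstate
    )
    usd = averted * vals
    for mine, ref in (
        (ci.incidence, np.percentile(averted, [2.5, 50, 97.5])),
        (ci.usd, np.percentile(usd, [2.5, 50, 97.5])),
    ):
        mean_scale = mine[1]
        assert abs(mine[0] - ref[0]) <= 0.02 * mean_scale
        assert abs(mine[2] - ref[2]) <= 0.02 * mean_scale


def test_too_few_draws_rejected():
    with pytest.raises(ValidationError):
        monte_carlo_ci(_exposure(), _hifs(), IncidenceValuation.from_mean(), n_draws=1)
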