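from dataclasses import replace

import numpy as np
import pytest

from brute_force import count_feasible_patterns, enumerate_optimum
from tesland.errors import BuildInfeasibleError, SequencingError, ValidationError
from tesland.optimizer import (
    ScenarioSpec,
    annualize_summary,
    build_model,
    run_scenario_suite,
    solve,
    standard_scenarios,
    verify_solution,
)


def _specs(bundle, gap=1e-6):
    return standard_scenarios(
        bundle.annual_luc_budget, horizon=bundle.horizon,
        plant_cost_per_acre=bundle.plant_cost_per_acre, mip_gap=gap,
    )


def test_tech_only_has_no_binaries_and_matches_closed_form(tiny_bundle):
    """No land-use change: an LP in S whose optimum is the clipped residual
    dispatch (each technology serves one pollutant at positive cost)."""
    p = tiny_bundle.problem
    model = build_model(p, _specs(tiny_bundle)["tech_only"])
    assert model.n_binary == 0
    assert model.n_continuous == len(p.technologies) * tiny_bundle.horizon
    sol = solve(model)
    expected = 0.0
    for t in p.technologies:
        target = (
            p.emissions.uptake_targets.get(t.pollutant)
            if t.pollutant != "co2"
            else p.emissions.emissions["co2"]
        )
        expected += target * t.cost_variable  # S = target / max each year
    expected *= tiny_bundle.horizon
    assert sol.objective_value == pytest.approx(expected, rel=1e-6)
    assert sol.planted_count == 0
    assert max(verify_solution(model, sol).values()) <= 1e-6


def test_variable_counts_match_hand_count(small_bundle):
    """Binaries = unconstrained receptors x years; continuous = techs x years."""
    p = small_bundle.problem
    spec = _specs(small_bundle)["tes"]
    model = build_model(p, spec)
    assert model.n_binary == p.unc_idx.size * spec.horizon
    assert model.n_continuous == len(p.technologies) * spec.horizon


def test_tiny_instance_is_enumerable(tiny_bundle):
    """2 receptors x 3 years: 6 binaries, all patterns countable by hand."""
    p = tiny_bundle.problem
    spec = _specs(tiny_bundle)["tes"]
    model = build_model(p, spec)
    assert model.n_binary == 6
    # at-most-once patterns: (H+1)^n = 16; the budget admits one planting
    # per year, so only simultaneous plantings are excluded (3 patterns)
    assert count_feasible_patterns(p, spec) == 13


@pytest.mark.parametrize("name", ["tes", "tes_plus", "co2_minus"])
def test_milp_equals_brute_force(tiny_bundle, name):
    """MILP optimum == exhaustive enumeration with per-pattern dispatch."""
    spec = _specs(tiny_bundle)[name]
    if name == "co2_minus":
        spec = replace(spec, area_match=1)
    best, _ = enumerate_optimum(tiny_bundle.problem, spec)
    model = build_model(tiny_bundle.problem, spec)
    sol = solve(model)
    assert sol.objective_value == pytest.approx(best, rel=1e-6)


def test_objective_recompute_matches_solver(tiny_bundle):
    for name in ("tech_only", "tes", "tes_plus"):
        model = build_model(tiny_bundle.problem, _specs(tiny_bundle)[name])
        sol = solve(model)
        assert sol.objective_recomputed == pytest.approx(
            sol.objective_value, rel=1e-6, abs=1e-3
        )


def test_feasible_set_containment(tiny_bundle):
    """tes_plus optimum <= the tes plan evaluated under the tes_plus objective."""
    specs = _specs(tiny_bundle)
    m_tes = build_model(tiny_bundle.problem, specs["tes"])
    s_tes = solve(m_tes)
    m_plus = build_model(tiny_bundle.problem, specs["tes_plus"])
    s_plus = solve(m_plus)

    def social_objective(sol):
        led = sol.ledger
        return float(
            (led["private_cost_usd"] - led["health_benefit_usd"] - led["carbon_benefit_usd"]).sum()
        )

    assert social_objective(s_plus) <= social_objective(s_tes) + 1e-6


def test_budget_relaxation_never_hurts(tiny_bundle):
    specs = _specs(tiny_bundle)
    base = specs["tes_plus"]
    relaxed = replace(base, annual_luc_budget=2 * base.annual_luc_budget)
    obj_base = solve(build_model(tiny_bundle.problem, base)).objective_value
    obj_relaxed = solve(build_model(tiny_bundle.problem, relaxed)).objective_value
    assert obj_relaxed <= obj_base + 1e-6


def test_provably_infeasible_target_raises_at_build(tiny_bundle):
    p = tiny_bundle.problem
    spec = _specs(tiny_bundle)["tech_only"]
    bad = replace(p, emissions=replace_emissions(p.emissions, nox=1e9))
    with pytest.raises(BuildInfeasibleError, match="nox"):
        build_model(bad, spec)


def replace_emissions(em, nox=None):
    from tesland.optimizer import FacilityEmissions

    targets = dict(em.uptake_targets)
    if nox is not None:
        targets["nox"] = nox
    return FacilityEmissions(emissions=dict(em.emissions), uptake_targets=targets)


def test_lexicographic_health_minimum(tiny_bundle):
    """Phase 1 reaches the enumerated health minimum; phase 2 keeps it."""
    spec = replace(_specs(tiny_bundle)["co2_minus"], area_match=1)
    model = build_model(tiny_bundle.problem, spec)
    sol = solve(model)
    # health of the extracted plan stays at the phase-1 minimum
    plan_health = float(sol.ledger["health_benefit_usd"].sum())
    assert plan_health == pytest.approx(sol.health_objective_value, rel=1e-6, abs=1.0)
    assert max(verify_solution(model, sol).values()) <= 1e-6


def test_scenario_spec_validation():
    with pytest.raises(ValidationError):
        ScenarioSpec("tes", "min_private_cost", include_luc=True)  # no budget
    with pytest.raises(ValidationError):
        ScenarioSpec("tes", "not_an_objective", include_luc=False)
    with pytest.raises(ValidationError):
        ScenarioSpec("tes", "min_private_cost", include_luc=True,
                     annual_luc_budget=1.0, area_match=3)


def test_suite_ordering_enforced(tiny_bundle):
    specs = _specs(tiny_bundle)
    out_of_order = {k: specs[k] for k in ("tech_only", "co2_minus", "tes")}
    with pytest.raises(SequencingError):
        run_scenario_suite(tiny_bundle.problem, specs=out_of_order)


def test_annualized_social_benefit_decomposes(tiny_bundle):
    """social = SCC x uptake + VSL x averted, exactly, for any solution."""
    p = tiny_bundle.problem
    model = build_model(p, _specs(tiny_bundle)["tes_plus"])
    sol = solve(model)
    s = annualize_summary(model, sol)
    recomposed = (
        p.scc.usd_per_tonne * s.carbon_uptake_annual_t
        + p.valuation.mean_value * s.averted_annual
    )
    assert s.social_benefit_annual_usd == pytest.approx(recomposed, rel=1e-9)


def test_all_constrained_grid_reduces_to_tech_only():
    """A landscape with no available land: the LUC scenario has no binary
    variables and the solution plants nothing."""
    import numpy as np

    from tesland.carbon import CarbonModel, SocialCostCarbon
    from tesland.growth import GrowthSeries, fit_growth_curve
    from tesland.health import HealthImpactFunction, IncidenceValuation
    from tesland.landscape import (
        DeltaFields,
        PopulationLayer,
        ReceptorGrid,
        compute_constraint_mask,
    )
    from tesland.optimizer import FacilityEmissions, TechnologyUnit, TESProblem

    grid = ReceptorGrid(
        receptor_id=[0, 1],
        x_km=[0.0, 2.5],
        y_km=[0.0, 0.0],
        spacing_km=2.5,
        landcover={
            "developed": [0.8, 0.7],
            "water": [0.0, 0.0],
            "forest": [0.1, 0.1],
            "agri_grass": [0.1, 0.2],
            "barren": [0.0, 0.0],
        },
    )
    compute_constraint_mask(grid)
    ages = np.arange(0.0, 9.0)
    crown = fit_growth_curve(GrowthSeries("crown_cover", ages, 1 - np.exp(-ages)))
    carb = fit_growth_curve(GrowthSeries("live_carbon", ages, np.ones(9)))
    problem = TESProblem(
        grid=grid,
        fields=DeltaFields(dC={"pm25": [0, 0], "o3": [0, 0]}, ddep={"nox": [0, 0], "pm25": [0, 0]}),
        population=PopulationLayer([1000.0, 1000.0], [0.008, 0.008]),
        crown_curve=crown,
        carbon_model=CarbonModel(vc=11.2, r=1.0, area_ha=np.full(2, 625.0), carbon_curve=carb),
        hifs=[HealthImpactFunction("pm25", 0.005, 0.001)],
        valuation=IncidenceValuation(8.7e6),
        scc=SocialCostCarbon(56.2),
        technologies=[
            TechnologyUnit("SCR", "nox", 100.0, 1000.0),
            TechnologyUnit("BHF", "pm25", 50.0, 500.0),
            TechnologyUnit("CCS", "co2", 1000.0, 60.0),
        ],
        emissions=FacilityEmissions(
            emissions={"nox": 100.0, "pm25": 50.0, "co2": 800.0},
            uptake_targets={"nox": 90.0, "pm25": 40.0},
        ),
    )
    spec = ScenarioSpec("tes", "min_private_cost", include_luc=True,
                        annual_luc_budget=1e6, horizon=3)
    model = build_model(problem, spec)
    assert model.n_binary == 0
    sol = solve(model)
    assert sol.planted_count == 0
    assert max(verify_solution(model, sol).values()) <= 1e-6
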