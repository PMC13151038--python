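"""Independent brute-force oracle for tiny design instances.

Re-derives every coefficient directly from the problem data and optimizes by
exhaustive enumeration of planting patterns with a closed-form continuous
dispatch per pattern: each technology serves exactly one pollutant, so the
cost-minimal operating level is the clipped residual requirement, and a
technology whose net objective coefficient is negative (capture credited
above its cost) runs flat out.  Nothing here touches the MILP assembly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from tesland.growth import eval_growth
from tesland.optimizer import ACRES_PER_HA, ScenarioSpec, TESProblem


def _coeffs(problem: TESProblem, spec: ScenarioSpec):
    unc = problem.unc_idx
    H = spec.horizon
    lc = problem.grid.landcover
    conv = np.clip(1.0 - lc["forest"] - lc["developed"] - lc["water"], 0, 1)[unc]
    pcost = spec.plant_cost_per_acre * ACRES_PER_HA * problem.grid.area_ha * conv
    gc = np.array([eval_growth(problem.crown_curve, float(a)) for a in range(H)])
    gk = np.array([eval_growth(problem.carbon_model.carbon_curve, float(a)) for a in range(H)])
    crate = (
        problem.carbon_model.unit_conversion
        * problem.carbon_model.vc
        * problem.carbon_model.r
        * problem.carbon_model.area_ha[unc]
    )
    P = problem.population.population[unc]
    Y0 = problem.population.y0[unc]
    inc = np.zeros(unc.size)
    for hif in problem.hifs:
        dC = problem.fields.dC[hif.pollutant][unc]
        inc = inc + Y0 * (1.0 - np.exp(-hif.beta_mean * dC)) * P
    husd = inc * problem.valuation.mean_value
    ddep = {p: problem.fields.ddep[p][unc] for p in ("nox", "pm25")}
    return conv, pcost, gc, gk, crate, husd, ddep


def _pattern_metrics(problem, spec, plant_years, coeffs):
    """Feasibility + per-pattern objective pieces, or None if infeasible."""
    conv, pcost, gc, gk, crate, husd, ddep = coeffs
    H = spec.horizon
    n = len(plant_years)
    # annual budget
    if spec.annual_luc_budget is not None:
        for year in range(H):
            spend = sum(pcost[i] for i in range(n) if plant_years[i] == year)
            if spend > spec.annual_luc_budget * (1 + 1e-9):
                return None
    if spec.area_match is not None:
        if sum(1 for py in plant_years if py is not None) != spec.area_match:
            return None

    techs = problem.technologies
    by_pollutant = {}
    for t in techs:
        by_pollutant.setdefault(t.pollutant, []).append(t)
    assert all(len(v) == 1 for v in by_pollutant.values()), "oracle assumes one tech per pollutant"

    scc = problem.scc.usd_per_tonne
    private = 0.0
    private_social = 0.0  # private cost under the social-credit dispatch
    health = 0.0
    social_credit = 0.0
    for year in range(H):
        eco = {p: 0.0 for p in ("nox", "pm25")}
        chi = 0.0
        h_usd = 0.0
        for i, py in enumerate(plant_years):
            if py is not None and py <= year:
                age = year - py
                eco["nox"] += ddep["nox"][i] * gc[age]
                eco["pm25"] += ddep["pm25"][i] * gc[age]
                chi += crate[i] * gk[age]
                h_usd += husd[i] * gc[age]
        plant_spend = sum(pcost[i] for i in range(n) if plant_years[i] == year)
        private += plant_spend
        private_social += plant_spend
        ccs_social = 0.0
        for p in ("nox", "pm25"):
            t = by_pollutant[p][0]
            req = max(problem.emissions.uptake_targets.get(p, 0.0) - eco[p], 0.0) / t.max_uptake
            if req > 1 + 1e-9:
                return None
            private += req * t.max_uptake * t.cost_variable + t.cost_fixed
            private_social += req * t.max_uptake * t.cost_variable + t.cost_fixed
        t = by_pollutant["co2"][0]
        req = max(problem.emissions.emissions.get("co2", 0.0) - chi, 0.0) / t.max_uptake
        if req > 1 + 1e-9:
            return None
        private += req * t.max_uptake * t.cost_variable + t.cost_fixed
        # social dispatch: run capture flat out when credited above cost
        s_ccs = 1.0 if t.cost_variable < scc else req
        private_social += s_ccs * t.max_uptake * t.cost_variable + t.cost_fixed
        ccs_social = s_ccs * t.max_uptake
        health += h_usd
        social_credit += h_usd + scc * (ccs_social + chi)
    return {
        "private": private,
        "health": health,
        "net_social": private_social - social_credit,
    }


def _patterns(n_receptors: int, horizon: int):
    """All at-most-once planting patterns: per receptor None or a year."""
    choices = [None] + list(range(horizon))
    return itertools.product(choices, repeat=n_receptors)


def enumerate_optimum(problem: TESProblem, spec: ScenarioSpec):
    """Exhaustive optimum for one scenario objective.

    Returns (objective_value, plant_years).  For the lexicographic health
    objective, minimizes total health benefit first, then private cost among
    epsilon-health-minimal patterns, mirroring the two-stage contract.
    """
    unc_n = problem.unc_idx.size if spec.include_luc else 0
    coeffs = _coeffs(problem, spec)
    evaluated = []
    for pattern in _patterns(unc_n, spec.horizon):
        m = _pattern_metrics(problem, spec, pattern, coeffs)
        if m is not None:
            evaluated.append((pattern, m))
    if not evaluated:
        return None, None
    if spec.objective == "min_private_cost":
        pattern, m = min(evaluated, key=lambda pm: pm[1]["private"])
        return m["private"], pattern
    if spec.objective == "min_cost_minus_social":
        pattern, m = min(evaluated, key=lambda pm: pm[1]["net_social"])
        return m["net_social"], pattern
    # lexicographic: health first, then private cost
    hmin = min(m["health"] for _, m in evaluated)
    tol = 1e-6 * max(1.0, abs(hmin))
    pool = [(p, m) for p, m in evaluated if m["health"] <= hmin + tol]
    pattern, m = min(pool, key=lambda pm: pm[1]["private"])
    return m["private"], pattern


def count_feasible_patterns(problem: TESProblem, spec: ScenarioSpec) -> int:
    coeffs = _coeffs(problem, spec)
    return sum(
        1
        for pattern in _patterns(problem.unc_idx.size, spec.horizon)
        if _pattern_metrics(problem, spec, pattern, coeffs) is not None
    )
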