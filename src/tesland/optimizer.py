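"""Spatiotemporal techno-ecological design as a mixed-integer linear program.

Decision variables couple two layers of the system:

* ``E[h, i]`` — binary: receptor ``i`` is planted in year ``h`` (1 only at
  the planting year; at most one planting per receptor; only receptors that
  pass the land-availability rule get variables).
* ``S[n, j]`` — continuous in [0, 1]: operating level of pollution-control
  technology ``j`` (SCR for NOx, baghouse filter for PM2.5, carbon capture
  for CO2) in year ``n``.

Constraints, per year: minimum NOx and PM2.5 uptake across the
techno-ecological system (technology dispatch plus crown-cover-scaled dry
deposition of all standing plantings), carbon neutrality (capture plus
biogenic sequestration covers facility CO2, with young stands debiting the
balance), and an annual land-use-change budget.  An optional area-matching
constraint fixes the total number of planted receptors, used to compare
spatial allocations at identical ecological investment.

All ecological coefficients are precomputed per (receptor, age), so the
concentration-response nonlinearity lives entirely in preprocessing and
every scenario model is strictly linear.  The MILP is solved with the HiGHS
backend of :func:`scipy.optimize.milp`; solutions are re-verified
arithmetically, independent of solver claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import carbon as carbon_mod
from . import health as health_mod
from .errors import (
    BuildInfeasibleError,
    InfeasibleError,
    SequencingError,
    SolveError,
    StructureError,
    ValidationError,
)
from .growth import GrowthCurve, eval_growth
from .landscape import DeltaFields, PopulationLayer, ReceptorGrid

ACRES_PER_HA = 2.471053814671653

DEFAULT_PLANT_COST_PER_ACRE = 376.0

SCENARIO_NAMES = ("tech_only", "tes", "tes_plus", "tes_plus_budgetmatch", "co2_minus")

OBJECTIVES = ("min_private_cost", "min_cost_minus_social", "min_health_lex_cost")


# ---------------------------------------------------------------------------
# problem data
# ---------------------------------------------------------------------------


@dataclass
class TechnologyUnit:
    """One pollution-control technology (linear cost, capped capacity)."""

    name: str
    pollutant: str  # "nox" | "pm25" | "co2"
    max_uptake: float  # tonnes/yr at full operation
    cost_variable: float  # USD per tonne removed
    cost_fixed: float = 0.0  # USD/yr, independent of operating level

    def __post_init__(self) -> None:
        if self.max_uptake <= 0:
            raise ValidationError(f"{self.name}: max_uptake must be > 0")
        if self.cost_variable < 0 or self.cost_fixed < 0:
            raise ValidationError(f"{self.name}: costs must be >= 0")


@dataclass
class FacilityEmissions:
    """Annual facility emissions and minimum uptake targets (tonnes/yr)."""

    emissions: dict[str, float]  # keys: nox, pm25, co2
    uptake_targets: dict[str, float]  # keys: nox, pm25 (co2 target = neutrality)


@dataclass
class ScenarioSpec:
    """One design case: objective variant plus constraint set."""

    name: str
    objective: str
    include_luc: bool
    annual_luc_budget: float | None = None
    area_match: int | None = None
    horizon: int = 60
    plant_cost_per_acre: float = DEFAULT_PLANT_COST_PER_ACRE
    discount_rate: float = 0.0
    mip_gap: float = 1e-4

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValidationError(f"unknown objective '{self.objective}'")
        if self.include_luc and (self.annual_luc_budget is None or self.annual_luc_budget <= 0):
            raise ValidationError("scenarios with land-use change need a positive annual budget")
        if self.area_match is not None and self.name not in ("tes_plus_budgetmatch", "co2_minus"):
            raise ValidationError("area_match is only used by the area-matched scenarios")


def standard_scenarios(
    annual_luc_budget: float,
    horizon: int = 60,
    plant_cost_per_acre: float = DEFAULT_PLANT_COST_PER_ACRE,
    mip_gap: float = 1e-4,
) -> dict[str, ScenarioSpec]:
    """The five canonical design cases.

    ``tech_only``: technological controls only, minimum private cost.
    ``tes``: adds afforestation, still minimizing private cost (physical
    uptake value only).  ``tes_plus``: monetized health and climate
    co-benefits enter the objective.  ``tes_plus_budgetmatch``: same
    objective as ``tes_plus`` but total planted receptors matched to the
    ``tes`` solution.  ``co2_minus``: same planted total, but health
    benefits are lexicographically minimized — the spatial worst case for
    public health at identical ecological investment.
    """
    common = dict(horizon=horizon, plant_cost_per_acre=plant_cost_per_acre, mip_gap=mip_gap)
    return {
        "tech_only": ScenarioSpec("tech_only", "min_private_cost", include_luc=False, **common),
        "tes": ScenarioSpec(
            "tes", "min_private_cost", include_luc=True, annual_luc_budget=annual_luc_budget, **common
        ),
        "tes_plus": ScenarioSpec(
            "tes_plus", "min_cost_minus_social", include_luc=True,
            annual_luc_budget=annual_luc_budget, **common,
        ),
        "tes_plus_budgetmatch": ScenarioSpec(
            "tes_plus_budgetmatch", "min_cost_minus_social", include_luc=True,
            annual_luc_budget=annual_luc_budget, **common,
        ),
        "co2_minus": ScenarioSpec(
            "co2_minus", "min_health_lex_cost", include_luc=True,
            annual_luc_budget=annual_luc_budget, **common,
        ),
    }


@dataclass
class TESProblem:
    """Everything a scenario model needs, validated and mutually aligned."""

    grid: ReceptorGrid
    fields: DeltaFields
    population: PopulationLayer
    crown_curve: GrowthCurve
    carbon_model: carbon_mod.CarbonModel
    hifs: list[health_mod.HealthImpactFunction]
    valuation: health_mod.IncidenceValuation
    scc: carbon_mod.SocialCostCarbon
    technologies: list[TechnologyUnit]
    emissions: FacilityEmissions

    def __post_init__(self) -> None:
        n = self.grid.n_receptors
        if self.fields.n_receptors() != n or self.population.population.size != n:
            raise StructureError("grid, fields and population are misaligned")

    @property
    def unc_idx(self) -> np.ndarray:
        return np.where(self.grid.unconstrained)[0]

    def convertible_fraction(self) -> np.ndarray:
        lc = self.grid.landcover
        return np.clip(1.0 - lc["forest"] - lc["developed"] - lc["water"], 0.0, 1.0)

    def plant_cost(self, per_acre: float = DEFAULT_PLANT_COST_PER_ACRE) -> np.ndarray:
        """Planting cost per receptor: only convertible land is planted."""
        new_area = self.convertible_fraction() * self.grid.area_ha
        return per_acre * ACRES_PER_HA * new_area


@dataclass
class _Coefficients:
    """Precomputed linear coefficients for one (problem, spec) pair."""

    unc_idx: np.ndarray
    plant_cost: np.ndarray  # per unconstrained receptor
    ddep: dict[str, np.ndarray]  # per unconstrained receptor
    carb_rate: np.ndarray  # full-maturity tonnes/yr per unconstrained receptor
    health_usd: np.ndarray  # full-maturity USD/yr per unconstrained receptor
    health_inc: np.ndarray  # full-maturity incidences/yr
    g_crown: np.ndarray  # length H
    g_carb: np.ndarray  # length H
    disc: np.ndarray  # length H


def _coefficients(problem: TESProblem, spec: ScenarioSpec) -> _Coefficients:
    H = spec.horizon
    unc = problem.unc_idx
    sched = health_mod.benefit_schedule(
        problem.grid, problem.fields, problem.population,
        problem.hifs, problem.valuation, problem.crown_curve, horizon=H,
    )
    ages = np.arange(H, dtype=float)
    return _Coefficients(
        unc_idx=unc,
        plant_cost=problem.plant_cost(spec.plant_cost_per_acre)[unc],
        ddep={p: v[unc] for p, v in problem.fields.ddep.items()},
        carb_rate=problem.carbon_model.receptor_rate()[unc],
        health_usd=sched.full_usd[unc],
        health_inc=sched.full_incidence[unc],
        g_crown=eval_growth(problem.crown_curve, ages),
        g_carb=eval_growth(problem.carbon_model.carbon_curve, ages),
        disc=1.0 / (1.0 + spec.discount_rate) ** ages,
    )


# ---------------------------------------------------------------------------
# model build
# ---------------------------------------------------------------------------


@dataclass
class TESModel:
    """Assembled MILP: min c'x s.t. lb <= A x <= ub, x in [0,1], E integer."""

    problem: TESProblem
    spec: ScenarioSpec
    coef: _Coefficients
    c: np.ndarray
    A: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    n_binary: int
    n_continuous: int
    health_row: np.ndarray  # objective row measuring total (discounted) health USD
    constant: float  # objective constant (fixed technology costs)
    row_families: list[tuple[str, int, int]]  # (family, row_start, row_stop)

    @property
    def n_variables(self) -> int:
        return self.c.size


def _lower_toeplitz(g: np.ndarray) -> np.ndarray:
    """T[n, h] = g[n - h] for h <= n, else 0."""
    H = g.size
    T = np.zeros((H, H))
    for h in range(H):
        T[h:, h] = g[: H - h]
    return T


def build_model(problem: TESProblem, spec: ScenarioSpec) -> TESModel:
    """Assemble the scenario MILP.

    Raises :class:`BuildInfeasibleError` for specs that are provably
    infeasible before solving (uptake targets beyond technology capacity, or
    carbon neutrality unreachable even at full capture).
    """
    coef = _coefficients(problem, spec)
    H = spec.horizon
    techs = problem.technologies
    J = len(techs)

    # provable infeasibility: technology alone must cover each target,
    # since ecological uptake starts at zero crown cover.
    for p in ("nox", "pm25"):
        target = problem.emissions.uptake_targets.get(p, 0.0)
        cap = sum(t.max_uptake for t in techs if t.pollutant == p)
        if target > cap * (1 + 1e-9):
            raise BuildInfeasibleError(
                f"uptake target for {p} ({target:.1f} t/yr) exceeds technology capacity ({cap:.1f} t/yr)"
            )
    co2 = problem.emissions.emissions.get("co2", 0.0)
    ccs_cap = sum(t.max_uptake for t in techs if t.pollutant == "co2")
    if co2 > ccs_cap * (1 + 1e-9):
        raise BuildInfeasibleError(
            f"carbon neutrality needs {co2:.1f} t/yr but capture capacity is {ccs_cap:.1f} t/yr"
        )

    n_unc = coef.unc_idx.size if spec.include_luc else 0
    nE = n_unc * H
    nS = H * J
    n_var = nE + nS

    # variable order: E row-major by receptor then year (i*H + h), then S (n*J + j)
    def s_col(n: int, j: int) -> int:
        return nE + n * J + j

    Tc = _lower_toeplitz(coef.g_crown)
    Tk = _lower_toeplitz(coef.g_carb)

    rows: list[sparse.spmatrix] = []
    lbs: list[np.ndarray] = []
    ubs: list[np.ndarray] = []
    families: list[tuple[str, int, int]] = []
    row_cursor = 0

    def add_block(name: str, A_block, lb, ub) -> None:
        nonlocal row_cursor
        A_block = sparse.csr_matrix(A_block)
        rows.append(A_block)
        lbs.append(np.atleast_1d(np.asarray(lb, dtype=float)))
        ubs.append(np.atleast_1d(np.asarray(ub, dtype=float)))
        families.append((name, row_cursor, row_cursor + A_block.shape[0]))
        row_cursor += A_block.shape[0]

    # (a) plant at most once per receptor
    if nE:
        A_once = sparse.kron(sparse.eye(n_unc), np.ones((1, H)))
        A_once = sparse.hstack([A_once, sparse.csr_matrix((n_unc, nS))])
        add_block("at_most_once", A_once, -np.inf * np.ones(n_unc), np.ones(n_unc))

    # (b) per-year pollutant uptake balance
    for p in ("nox", "pm25"):
        target = problem.emissions.uptake_targets.get(p, 0.0)
        A_S = np.zeros((H, nS))
        for j, t in enumerate(techs):
            if t.pollutant == p:
                for n in range(H):
                    A_S[n, n * J + j - 0] = t.max_uptake
        if nE:
            A_E = np.kron(coef.ddep[p][None, :], Tc)  # H x nE
            block = sparse.hstack([sparse.csr_matrix(A_E), sparse.csr_matrix(A_S)])
        else:
            block = sparse.csr_matrix(A_S)
        add_block(f"balance_{p}", block, np.full(H, target), np.full(H, np.inf))

    # (c) carbon neutrality each year: CCS + chi_n >= CO2 emissions
    A_S = np.zeros((H, nS))
    for j, t in enumerate(techs):
        if t.pollutant == "co2":
            for n in range(H):
                A_S[n, n * J + j] = t.max_uptake
    if nE:
        A_E = np.kron(coef.carb_rate[None, :], Tk)
        block = sparse.hstack([sparse.csr_matrix(A_E), sparse.csr_matrix(A_S)])
    else:
        block = sparse.csr_matrix(A_S)
    add_block("co2_neutrality", block, np.full(H, co2), np.full(H, np.inf))

    # (d) annual land-use-change budget
    if nE and spec.annual_luc_budget is not None:
        A_budget = np.kron(coef.plant_cost[None, :], np.eye(H))  # rows = planting year
        A_budget = sparse.hstack([sparse.csr_matrix(A_budget), sparse.csr_matrix((H, nS))])
        add_block(
            "annual_budget", A_budget,
            np.full(H, -np.inf), np.full(H, spec.annual_luc_budget),
        )

    # (e) optional area matching: total planted receptors fixed
    if nE and spec.area_match is not None:
        A_area = sparse.hstack(
            [sparse.csr_matrix(np.ones((1, nE))), sparse.csr_matrix((1, nS))]
        )
        add_block("area_match", A_area, [float(spec.area_match)], [float(spec.area_match)])

    A = sparse.vstack(rows).tocsr() if rows else sparse.csr_matrix((0, n_var))
    lb = np.concatenate(lbs) if lbs else np.zeros(0)
    ub = np.concatenate(ubs) if ubs else np.zeros(0)

    # --- objective ---------------------------------------------------------
    # per-planting lifetime sums of growth ratios, discounted from year h on
    crown_tail = coef.disc[:, None] * Tc  # (n, h)
    carb_tail = coef.disc[:, None] * Tk
    crown_sum = crown_tail.sum(axis=0)  # index h
    carb_sum = carb_tail.sum(axis=0)

    c_private = np.zeros(n_var)
    if nE:
        c_private[:nE] = np.kron(coef.plant_cost, coef.disc)
    for j, t in enumerate(techs):
        for n in range(H):
            c_private[s_col(n, j)] = t.cost_variable * t.max_uptake * coef.disc[n]

    health_row = np.zeros(n_var)
    if nE:
        health_row[:nE] = np.kron(coef.health_usd, crown_sum)

    c_social_credit = np.zeros(n_var)
    if nE:
        c_social_credit[:nE] = health_row[:nE] + problem.scc.usd_per_tonne * np.kron(
            coef.carb_rate, carb_sum
        )
    for j, t in enumerate(techs):
        if t.pollutant == "co2":
            for n in range(H):
                c_social_credit[s_col(n, j)] += (
                    problem.scc.usd_per_tonne * t.max_uptake * coef.disc[n]
                )

    if spec.objective == "min_private_cost":
        c = c_private
    elif spec.objective == "min_cost_minus_social":
        c = c_private - c_social_credit
    else:  # min_health_lex_cost: phase-1 objective; solve() handles phase 2
        c = health_row.copy()

    constant = sum(t.cost_fixed for t in techs) * float(np.sum(coef.disc))

    return TESModel(
        problem=problem,
        spec=spec,
        coef=coef,
        c=c,
        A=A,
        lb=lb,
        ub=ub,
        integrality=np.concatenate([np.ones(nE), np.zeros(nS)]),
        n_binary=nE,
        n_continuous=nS,
        health_row=health_row,
        constant=constant,
        row_families=families,
    )


# ---------------------------------------------------------------------------
# solution container and extraction
# ---------------------------------------------------------------------------


@dataclass
class DesignSolution:
    """Extracted plan with arithmetically recomputed per-year ledgers."""

    spec: ScenarioSpec
    E: np.ndarray  # [H, n_unc] binary
    S: np.ndarray  # [H, J]
    unc_receptor_ids: np.ndarray
    planted_year: np.ndarray  # per unconstrained receptor, -1 if never
    ledger: pd.DataFrame
    objective_value: float
    objective_recomputed: float
    status: str
    mip_gap: float
    health_objective_value: float | None = None  # lexicographic phase-1 optimum

    @property
    def planted_count(self) -> int:
        return int(np.sum(self.planted_year >= 0))


def _run_milp(model: TESModel, c: np.ndarray, mip_gap: float, extra=None):
    constraints = [LinearConstraint(model.A, model.lb, model.ub)]
    if extra is not None:
        A2, lb2, ub2 = extra
        constraints.append(LinearConstraint(A2, lb2, ub2))
    res = milp(
        c=c,
        constraints=constraints,
        integrality=model.integrality,
        bounds=Bounds(0.0, 1.0),
        options={"mip_rel_gap": mip_gap, "presolve": True},
    )
    if res.status == 2:
        raise InfeasibleError(_diagnose_infeasibility(model))
    if res.status == 3:
        raise SolveError("model is unbounded")
    if res.x is None:
        raise SolveError(f"solver returned no solution (status {res.status}: {res.message})")
    return res


def _diagnose_infeasibility(model: TESModel) -> str:
    """Name the first constraint family that cannot be satisfied in isolation."""
    spec, prob = model.spec, model.problem
    H = spec.horizon
    for p in ("nox", "pm25"):
        target = prob.emissions.uptake_targets.get(p, 0.0)
        cap = sum(t.max_uptake for t in prob.technologies if t.pollutant == p)
        eco = float(np.sum(model.coef.ddep[p])) * float(np.max(model.coef.g_crown)) if model.n_binary else 0.0
        if target > cap + eco:
            return f"infeasible: balance_{p} (target {target:.1f} > capacity {cap + eco:.1f})"
    co2 = prob.emissions.emissions.get("co2", 0.0)
    ccs = sum(t.max_uptake for t in prob.technologies if t.pollutant == "co2")
    if co2 > ccs:
        return "infeasible: co2_neutrality in year 0 (no mature stands can exist)"
    if spec.area_match is not None:
        max_cnt = model.n_binary // max(H, 1)
        if spec.area_match > max_cnt:
            return f"infeasible: area_match ({spec.area_match} > {max_cnt} available receptors)"
        if spec.annual_luc_budget is not None:
            cheap = np.sort(model.coef.plant_cost)
            per_year = np.searchsorted(np.cumsum(cheap), spec.annual_luc_budget, side="right")
            if per_year * H < spec.area_match:
                return "infeasible: area_match unreachable under annual_budget"
    return "infeasible: no single constraint family is provably at fault (joint conflict)"


def solve(model: TESModel, mip_gap: float | None = None, seed: int = 0) -> DesignSolution:
    """Solve the scenario MILP and extract a verified solution.

    The solve is deterministic for a fixed model and gap (single-threaded
    HiGHS with canonical variable order); ``seed`` is accepted for interface
    symmetry with the stochastic post-processing and does not alter the
    optimum.  The lexicographic objective runs two sequential solves: health
    benefit is minimized first, then private cost among (epsilon-)health-
    minimal plans.
    """
    del seed  # deterministic solver; randomness only enters Monte Carlo CIs
    gap = model.spec.mip_gap if mip_gap is None else mip_gap
    health_opt = None
    if model.spec.objective == "min_health_lex_cost":
        res1 = _run_milp(model, model.c, gap)
        health_opt = float(res1.fun)
        cap = health_opt + 1e-6 * max(1.0, abs(health_opt))
        extra = (
            sparse.csr_matrix(model.health_row[None, :]),
            np.array([-np.inf]),
            np.array([cap]),
        )
        c_private = _private_cost_vector(model)
        res = _run_milp(model, c_private, gap, extra=extra)
        objective_value = float(res.fun) + model.constant
    else:
        res = _run_milp(model, model.c, gap)
        objective_value = float(res.fun) + (
            model.constant if model.spec.objective != "min_health_lex_cost" else 0.0
        )

    x = np.asarray(res.x)
    H, J = model.spec.horizon, len(model.problem.technologies)
    n_unc_all = model.problem.unc_idx.size
    if model.n_binary:
        E = np.rint(x[: model.n_binary]).reshape(n_unc_all, H).T  # [H, i]
    else:
        E = np.zeros((H, n_unc_all))
    S = np.clip(x[model.n_binary :].reshape(H, J), 0.0, 1.0)
    sol = extract_solution(model, E, S, status=res.message, mip_gap=gap)
    sol.objective_value = objective_value
    sol.health_objective_value = health_opt
    return sol


def _private_cost_vector(model: TESModel) -> np.ndarray:
    coef, spec = model.coef, model.spec
    H, J = spec.horizon, len(model.problem.technologies)
    c = np.zeros(model.n_variables)
    if model.n_binary:
        c[: model.n_binary] = np.kron(coef.plant_cost, coef.disc)
    for j, t in enumerate(model.problem.technologies):
        for n in range(H):
            c[model.n_binary + n * J + j] = t.cost_variable * t.max_uptake * coef.disc[n]
    return c


def extract_solution(
    model: TESModel, E: np.ndarray, S: np.ndarray, status: str = "manual", mip_gap: float = 0.0
) -> DesignSolution:
    """Build per-year ledgers from a plan by direct arithmetic."""
    prob, spec, coef = model.problem, model.spec, model.coef
    H = spec.horizon
    techs = prob.technologies
    Tc = _lower_toeplitz(coef.g_crown)
    Tk = _lower_toeplitz(coef.g_carb)

    cohort_ddep = {p: E @ coef.ddep[p] for p in coef.ddep}  # per planting year
    eco = {p: Tc @ cohort_ddep[p] for p in coef.ddep}
    chi = Tk @ (E @ coef.carb_rate)
    averted = Tc @ (E @ coef.health_inc)
    health_usd = Tc @ (E @ coef.health_usd)

    tech_uptake = {t.name: S[:, j] * t.max_uptake for j, t in enumerate(techs)}
    ccs = np.zeros(H)
    for j, t in enumerate(techs):
        if t.pollutant == "co2":
            ccs += S[:, j] * t.max_uptake
    luc_spend = E @ coef.plant_cost
    tech_cost = sum(
        S[:, j] * t.max_uptake * t.cost_variable + t.cost_fixed for j, t in enumerate(techs)
    )
    private = tech_cost + luc_spend
    total_uptake = ccs + chi
    carbon_usd = prob.scc.usd_per_tonne * total_uptake

    ledger = pd.DataFrame(
        {
            "year": np.arange(H),
            "eco_nox_t": eco["nox"],
            "eco_pm25_t": eco["pm25"],
            "chi_t": chi,
            "ccs_t": ccs,
            "total_co2_uptake_t": total_uptake,
            "luc_spend_usd": luc_spend,
            "tech_cost_usd": np.asarray(tech_cost, dtype=float),
            "private_cost_usd": np.asarray(private, dtype=float),
            "averted_mortalities": averted,
            "health_benefit_usd": health_usd,
            "carbon_benefit_usd": carbon_usd,
            **{f"uptake_{k}_t": v for k, v in tech_uptake.items()},
            **{
                f"S_{t.name}": S[:, j] for j, t in enumerate(techs)
            },
        }
    )

    disc = coef.disc
    if spec.objective == "min_private_cost":
        recomputed = float(np.sum(disc * private))
    elif spec.objective == "min_cost_minus_social":
        recomputed = float(np.sum(disc * (private - health_usd - carbon_usd)))
    else:
        recomputed = float(np.sum(disc * private))

    planted_year = np.full(prob.unc_idx.size, -1, dtype=int)
    for i in range(prob.unc_idx.size):
        hs = np.where(E[:, i] > 0.5)[0]
        if hs.size:
            planted_year[i] = int(hs[0])

    return DesignSolution(
        spec=spec,
        E=E,
        S=S,
        unc_receptor_ids=prob.grid.receptor_id[prob.unc_idx],
        planted_year=planted_year,
        ledger=ledger,
        objective_value=recomputed,
        objective_recomputed=recomputed,
        status=status,
        mip_gap=mip_gap,
    )


def verify_solution(model: TESModel, sol: DesignSolution, tol: float = 1e-6) -> dict[str, float]:
    """Re-check every constraint family arithmetically on the extracted plan.

    Returns the maximum violation per family (0 means satisfied); raises
    nothing, so callers can assert on the values they care about.
    """
    prob, spec, coef = model.problem, sol.spec, model.coef
    H = spec.horizon
    led = sol.ledger
    out: dict[str, float] = {}
    out["binary"] = float(np.max(np.abs(sol.E - np.rint(sol.E)))) if sol.E.size else 0.0
    out["at_most_once"] = float(max(0.0, np.max(sol.E.sum(axis=0)) - 1.0)) if sol.E.size else 0.0
    for p in ("nox", "pm25"):
        target = prob.emissions.uptake_targets.get(p, 0.0)
        supplied = led[f"eco_{p}_t"].to_numpy().copy()
        for j, t in enumerate(prob.technologies):
            if t.pollutant == p:
                supplied += sol.S[:, j] * t.max_uptake
        out[f"balance_{p}"] = float(max(0.0, np.max(target - supplied)))
    co2 = prob.emissions.emissions.get("co2", 0.0)
    out["co2_neutrality"] = float(
        max(0.0, np.max(co2 - led["total_co2_uptake_t"].to_numpy()))
    )
    if spec.annual_luc_budget is not None:
        out["annual_budget"] = float(
            max(0.0, np.max(led["luc_spend_usd"].to_numpy() - spec.annual_luc_budget))
        )
    if spec.area_match is not None:
        out["area_match"] = float(abs(sol.planted_count - spec.area_match))
    out["S_bounds"] = float(max(0.0, np.max(sol.S) - 1.0, -np.min(sol.S))) if sol.S.size else 0.0
    del coef, tol
    return out


# ---------------------------------------------------------------------------
# summaries and suites
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSummary:
    """Annualized accounting of one solved scenario (comparison-table shape)."""

    name: str
    private_cost_annual_usd: float
    averted_annual: float
    additional_averted_annual: float
    carbon_uptake_annual_t: float
    biogenic_share_pct: float
    social_benefit_annual_usd: float
    planted_count: int
    planted_area_ha: float
    averted_ci: tuple[float, float, float] | None = None
    social_ci: tuple[float, float, float] | None = None
    mean_population_planted: float = float("nan")


def exposure_summary(model: TESModel, sol: DesignSolution) -> health_mod.ExposureSummary:
    """Crown-weighted exposure aggregates of the plan, for Monte Carlo CIs."""
    prob, coef = model.problem, model.coef
    H = sol.spec.horizon
    Tc = _lower_toeplitz(coef.g_crown)
    w_unc = (Tc @ sol.E).sum(axis=0) / H  # per unconstrained receptor
    weight = np.zeros(prob.grid.n_receptors)
    weight[prob.unc_idx] = w_unc
    return health_mod.ExposureSummary(
        weight=weight,
        dC=prob.fields.dC,
        y0=prob.population.y0,
        population=prob.population.population,
    )


def annualize_summary(
    model: TESModel,
    sol: DesignSolution,
    baseline_averted_annual: float = 0.0,
    n_draws: int = 0,
    seed: int = 0,
) -> ScenarioSummary:
    """Annualized averages over the horizon (no discounting in reporting).

    ``additional averted mortalities`` is relative to the supplied baseline
    (the technology-only case by convention).  Biogenic share is the
    fraction of total CO2 uptake supplied by land-use change.  When
    ``n_draws`` > 0, 95% CIs are propagated on the fixed plan.
    """
    prob = model.problem
    led = sol.ledger
    H = sol.spec.horizon
    chi_total = float(led["chi_t"].sum())
    ccs_total = float(led["ccs_t"].sum())
    uptake_total = chi_total + ccs_total
    averted_annual = float(led["averted_mortalities"].mean())
    social_annual = (
        prob.scc.usd_per_tonne * uptake_total / H
        + prob.valuation.mean_value * averted_annual
    )
    planted = sol.planted_year >= 0
    conv = prob.convertible_fraction()[prob.unc_idx]
    pops = prob.population.population[prob.unc_idx]
    summary = ScenarioSummary(
        name=sol.spec.name,
        private_cost_annual_usd=float(led["private_cost_usd"].mean()),
        averted_annual=averted_annual,
        additional_averted_annual=averted_annual - baseline_averted_annual,
        carbon_uptake_annual_t=uptake_total / H,
        biogenic_share_pct=100.0 * chi_total / uptake_total if uptake_total > 0 else 0.0,
        social_benefit_annual_usd=social_annual,
        planted_count=int(np.sum(planted)),
        planted_area_ha=float(np.sum(conv[planted]) * prob.grid.area_ha),
        mean_population_planted=float(np.mean(pops[planted])) if np.any(planted) else float("nan"),
    )
    if n_draws > 0:
        exp = exposure_summary(model, sol)
        ci = health_mod.monte_carlo_ci(
            exp,
            prob.hifs,
            prob.valuation,
            n_draws=n_draws,
            seed=seed,
            carbon_usd=prob.scc.usd_per_tonne * uptake_total / H,
        )
        summary.averted_ci = ci.incidence
        summary.social_ci = ci.usd
    return summary


@dataclass
class SuiteResult:
    """Ordered scenario runs plus cross-scenario derived quantities."""

    solutions: dict[str, DesignSolution]
    summaries: dict[str, ScenarioSummary]
    models: dict[str, TESModel] = field(default_factory=dict)

    def best_worst(self) -> tuple[float, float]:
        """(best, worst) additional averted mortalities among the
        area-matched pair that brackets co-benefit performance."""
        best = self.summaries["tes_plus_budgetmatch"].additional_averted_annual
        worst = self.summaries["co2_minus"].additional_averted_annual
        return best, worst

    def fraction_health_benefit_lost(self) -> float:
        best, worst = self.best_worst()
        return 1.0 - worst / best if best > 0 else 0.0


def run_scenario_suite(
    problem: TESProblem,
    specs: dict[str, ScenarioSpec] | None = None,
    annual_luc_budget: float | None = None,
    horizon: int = 60,
    mip_gap: float = 1e-4,
    n_draws: int = 0,
    seed: int = 0,
) -> SuiteResult:
    """Run the design cases in dependency order.

    The technology-only case baselines averted mortalities; the ``tes``
    planted-receptor total parameterizes the area-matched cases, so those
    must come after it (a :class:`SequencingError` is raised otherwise).
    """
    if specs is None:
        if annual_luc_budget is None:
            raise ValidationError("either specs or annual_luc_budget must be given")
        specs = standard_scenarios(annual_luc_budget, horizon=horizon, mip_gap=mip_gap)
    names = list(specs)
    for dep in ("tes_plus_budgetmatch", "co2_minus"):
        if dep in names and ("tes" not in names or names.index("tes") > names.index(dep)):
            raise SequencingError(f"'{dep}' needs the 'tes' scenario to run first (area matching)")
    if "tech_only" in names and names.index("tech_only") != 0:
        names.remove("tech_only")
        names.insert(0, "tech_only")

    solutions: dict[str, DesignSolution] = {}
    summaries: dict[str, ScenarioSummary] = {}
    models: dict[str, TESModel] = {}
    baseline = 0.0
    tes_count: int | None = None
    for name in names:
        spec = specs[name]
        if name in ("tes_plus_budgetmatch", "co2_minus"):
            if tes_count is None:
                raise SequencingError(f"'{name}' requires a solved 'tes' scenario")
            spec = replace(spec, area_match=tes_count)
        model = build_model(problem, spec)
        sol = solve(model, seed=seed)
        if name == "tech_only":
            baseline = float(sol.ledger["averted_mortalities"].mean())
        if name == "tes":
            tes_count = sol.planted_count
        solutions[name] = sol
        summaries[name] = annualize_summary(
            model, sol, baseline_averted_annual=baseline, n_draws=n_draws, seed=seed + 1
        )
        models[name] = model
    return SuiteResult(solutions=solutions, summaries=summaries, models=models)
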