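# Methods

`tesland` designs techno-ecological pollution-control systems for an
industrial point source: it decides *where and when* to afforest receptor
cells around the facility, jointly with the year-by-year operating levels of
engineered controls, so that the system stays carbon-neutral and meets
minimum pollutant-uptake rates, while monetizing the public-health and
climate value the new forest delivers. This note documents the model, its
assumptions, the defaults, and the numerical choices.

## System model

**Landscape.** The spatial domain is a complete rectangular grid of
receptors (default 41 x 41 at 2.5 km spacing, 100 km x 100 km, source at
the origin; cell area 625 ha). Each receptor carries land-cover fractions
(developed, water, forest, agriculture/grass, barren), exposed population,
and a baseline all-cause mortality incidence rate. A receptor is available
for afforestation when `developed + water < 0.5` (strict inequality: a cell
at exactly 50% is treated as unavailable — the conservative reading; the
two classes are pooled rather than tested separately). Per-receptor
concentration reductions (PM2.5, ozone) and dry-deposition increments (NOx,
PM2.5) between the current and the fully afforested land-cover states are
*inputs*, produced offline by a dispersion model; the package never
re-simulates dispersion, and concentration changes are treated as local to
each receptor (no cross-receptor feedback), so total benefits are additive
across receptors.

**Growth dynamics.** Stand-level trajectories of tree crown cover and of
the annual change of live carbon (above plus below ground) over an 80-year
window are normalized by their maximum and summarized by an ordinary
least-squares polynomial of degree 5 in stand age (degree configurable;
both attributes use 5 by default). Crown-cover evaluations clamp to
[0, 1]; live-carbon evaluations clamp to [-1, 1] and are genuinely negative
at young ages — saplings respire more carbon than they fix. Beyond the
fitted domain the endpoint value is held constant rather than extrapolating
the polynomial (a quintic diverges immediately outside its window). The
*crossover age* is the first age from which the curve's annual increments
stay positive, evaluated on a unit-age lattice with a 1e-9 tolerance
against fit noise on flat curves. R-squared of a zero-variance (constant)
target is defined as 1.

**Health impacts.** Averted incidences at receptor *i* follow the
log-linear concentration-response model

    dY_i = Y0_i (1 - exp(-beta_p * dC_{p,i})) * P_i,

summed over pollutants p in {PM2.5, ozone}, endpoint "Mortality, All
Causes", all ages. Default effect estimates: beta = 0.005826891 (SD
0.000962763) per ug/m3 for PM2.5 and 0.001980263 (SD 0.000500216) per ppb
for ozone. Averted incidences are valued at a mean value of a statistical
life of $8.7M (2021 USD). Maturity scaling multiplies the *monetized
full-afforestation benefit* by the crown-cover ratio g_crown(age), rather
than scaling dC inside the exponential; at these concentration deltas the
exponential is within 0.5% of linear, so the distinction is numerically
immaterial, and the multiplicative form keeps the optimization model
strictly linear.

**Carbon.** Biogenic sequestration of a receptor planted in year *h*,
evaluated in year *n*, is `Vc * R * A_i * g_carbon(n - h)` with Vc the
county-average sequestration rate (default 11.2 t CO2/ha/yr, interpreted as
the peak-growth rate), A_i the receptor area, and R a scenario-level
additionality fraction: the newly created forest area under full conversion
of available cells divided by the total forest area of that converted state.
R is a single scalar, as the accounting defines it; a per-receptor
refinement would change receptor ranking only through existing forest,
which already enters the planting cost. Negative young-stand contributions
are debited as printed — the neutrality constraint must absorb them.
Social value of carbon removal is a constant social cost of carbon, default
$56.2 per metric tonne ($51 per short ton; the package converts at
0.90718474 t per short ton). A year-indexed SCC series hook exists but is
off by default. Social carbon benefits value *total* CO2 uptake —
technological capture plus biogenic — not only above-neutrality removal;
this is the only reading consistent with valuing a capture-only system's
uptake, and in the objective the two readings differ by a constant (fixed
facility emissions), so the optimal design is unchanged.

**Optimization.** Decision variables: binary `E[h, i]` (receptor *i*
planted in year *h*; only available receptors get variables; at most one
planting per receptor) and continuous `S[n, j]` in [0, 1] (operating level
of technology *j* — SCR for NOx, baghouse filter for PM2.5, CCS for CO2 —
in year *n*). Constraints per year: NOx and PM2.5 uptake (technology
dispatch plus crown-scaled dry deposition of all standing plantings) at or
above fixed targets; CCS plus biogenic sequestration at or above facility
CO2 emissions (carbon neutrality); planting expenditures within an annual
land-use-change budget (the budget caps LUC only, not technology
operation); and optionally a fixed total count of planted receptors, used
to compare spatial allocations at identical ecological investment. All
ecological coefficients are precomputed per (receptor, age), so every
scenario model is a linear MIP; the concentration-response nonlinearity
lives entirely in preprocessing.

Five scenario objectives:

* `tech_only` — minimize private cost, no land-use change (the baseline
  for "additional averted mortalities");
* `tes` — minimize private cost with land-use change available (physical
  uptake value only);
* `tes_plus` — minimize private cost minus monetized health and climate
  benefits;
* `tes_plus_budgetmatch` — same objective, planted-receptor total fixed to
  the `tes` solution;
* `co2_minus` — lexicographic: minimize total health benefit subject to
  all constraints (same planted total), then minimize private cost among
  epsilon-health-minimal plans (cap at the phase-1 optimum plus 1e-6
  relative). This is the deliberate worst case for spatial health value.

Private cost is linear technology operating cost (per tonne removed, with
an optional fixed annual term) plus $376 per acre of *newly planted* land —
`area x (1 - f_forest - f_developed - f_water)` — in the planting year.
No discounting by default (reported values are plain annualized averages
over the horizon); a discount-rate hook exists. Uncertainty (Normal betas
per pollutant, floored at zero with a logged count; Weibull-distributed
value per incidence calibrated so its mean equals the configured VSL,
default shape 1.51) is propagated by Monte Carlo *after* optimization on
the fixed mean-optimal plan; it shifts benefit magnitudes, not the plan.

## Solver and numerics

The MIP is assembled sparse and solved with HiGHS via
`scipy.optimize.milp`; default relative MIP gap 1e-4 (suite-level runs use
1e-3), deterministic with canonical variable order (receptor-major, then
year) — the `seed` argument only governs Monte Carlo draws. Solutions are
*re-verified arithmetically*: every constraint family is recomputed from
the extracted plan, independent of solver claims, and the objective is
recomputed from the per-year ledgers (agreement within 1e-6 relative).
Provably infeasible specifications (targets beyond capacity, neutrality
beyond capture capacity) are rejected at build time with a diagnostic;
infeasible solves attempt to name the first constraint family at fault.
On instances with few binaries the optimizer is tested against exhaustive
enumeration of planting patterns with closed-form continuous dispatch
(each technology serves one pollutant, so the cost-minimal level is the
clipped residual requirement).

## Synthetic landscapes

The fixture generator emulates the *structure* of a real case without
replicating any county: lognormal rural population with Gaussian urban
bumps; developed fraction correlated with population so dense cells tend
to fail the availability rule; a meandering river band of water-dominated
cells; an exactly-hit target share of constrained receptors (densest cells
plus the river core); ozone deltas proportional to convertible land
fraction (land-availability-driven); PM2.5 deltas and deposition following
a distance-decaying plume kernel skewed toward the dominant wind bearing
(22.5 degrees, i.e. NNE); and growth tables with a respiration dip
bottoming near age 5, net sequestration from the mid-teens, and a
sigmoidal rise toward the peak rate near the end of the 80-year window
(quintic fit R^2 about 0.997). Facility parameters are scaled to the
landscape: CO2 emissions at 55% of the full-maturity biogenic potential,
capture capacity with 30% headroom to absorb the young-stand dip, NOx and
PM2.5 targets an order of magnitude above full ecological deposition (the
dry-deposition pathway is physically small next to stack controls, so
technologies retain most of the load), and an annual planting budget of 5%
of estimated business-as-usual operating cost, which binds and forces
staggered planting. Technology costs: $1600/t NOx (SCR), $900/t PM2.5
(baghouse), $60/t CO2 (capture) — the capture cost sits above the social
cost of carbon so capture is never run for profit.

All randomness flows from a single seed and bundles are written to, and
read back from, the public CSV/JSON formats, so end-to-end tests exercise
I/O. What the fixtures do **not** emulate: real meteorology or chemistry,
spatial autocorrelation of land cover beyond the river band, agricultural
land competition, and the empirical magnitudes of any particular facility —
so passing tests demonstrate correct mechanics and qualitative regimes
(capture-only neutrality early, biogenic growth after the dip, budget
staggering, population-seeking planting under health valuation), not
agreement with any measured landscape.

Test and acceptance runs use a 10 x 10 grid with a 30-year horizon (about
2,600 binaries), the package's chosen compact study condition; the default
generator remains 41 x 41 over 60 years. At the compact condition the
biogenic share of total CO2 uptake is small (a percent-scale contribution)
because stands only reach mid-growth within 30 years; the qualitative
regimes above are unaffected.

## Known limitations

* The lexicographic worst case (`co2_minus`) minimizes health benefit
  first, which also pushes planting as late as possible; its biogenic
  share can be near zero or slightly negative even though its planted area
  matches `tes`. An alternative ordering (cost first) would keep carbon
  performance and is expressible via the spec objects, but is not the
  shipped definition.
* Phase 1 of the lexicographic solve is gap-certified, not exact, so the
  phase-2 health cap inherits the MIP gap.
* Ozone benefits reflect direct deposition only; no photochemistry, no
  morbidity endpoints, no age-stratified population, no income growth in
  valuation, no soil carbon, harvest, disturbance or leakage, no land
  markets or credit allocation.
* Dispersion deltas are static two-state differences; planting a subset of
  a receptor's convertible land is assumed to scale benefits linearly via
  crown cover, and neighboring plantings do not interact.
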