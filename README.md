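# tesland

**Techno-ecological industrial landscape design: where and when to plant
trees around a point source so that carbon neutrality also buys public
health.**

Industrial facilities pursuing net-zero increasingly look to afforestation
as a negative-emission option. Treating the surrounding landscape as a unit
operation — alongside engineered controls such as a selective catalytic
reduction reactor (SCR), a baghouse filter (BHF) and carbon capture and
storage (CCS) — turns "where should the trees go?" into a design problem.
`tesland` implements that problem as a spatiotemporal mixed-integer linear
program for engineers and environmental analysts: binary decisions
`E[h, i]` plant receptor cell *i* in year *h*; continuous decisions
`S[n, j]` set technology operating levels each year; constraints enforce
per-year carbon neutrality, minimum NOx/PM2.5 uptake across the combined
techno-ecological system, and an annual land-use-change budget.

The co-benefits that drive siting are modeled explicitly:

* **Health.** Averted mortalities from the log-linear
  concentration-response model `dY = Y0 (1 − e^{−β ΔC}) P` applied to
  PM2.5 and ozone concentration reductions delivered by dry deposition to
  the growing canopy, monetized at a value of a statistical life
  ($8.7M mean, Weibull-distributed), with Monte Carlo 95% CIs over the
  effect estimates and the valuation.
* **Climate.** Biogenic sequestration
  `χ_n = Vc · R · Σ_{h≤n} Σ_i E[h,i] · A_i · g_carbon(n−h)` with a
  county-average rate Vc, an additionality fraction R that credits only
  newly created forest, and a degree-5 polynomial growth ratio g_carbon
  that is *negative* for young stands (respiration exceeds fixation),
  valued at the social cost of carbon ($56.2/t, i.e. $51 per short ton).

Both benefit streams scale with stand age through normalized growth curves
(crown cover for deposition, live-carbon change for sequestration), so the
optimizer trades planting early (growth takes decades to pay) against
budget limits and technology operating costs.

## Worked example

`examples/05_scenario_suite.py` generates a synthetic 10 × 10 receptor
landscape (2.5 km spacing, clustered population, plume-shaped PM2.5
deltas, 30-year horizon) and compares the five canonical design cases:

```
                                             tech_only                tes        tes_plus tes_plus_budgetmatch          co2_minus
private costs [USD]                         21 million         21 million      21 million           21 million         21 million
additional averted mortalities       0.00 (0.00, 0.00)  0.63 (0.45, 0.81)  1.9 (1.3, 2.5)       1.7 (1.2, 2.3)  0.00 (0.00, 0.00)
carbon uptake [Mt]                                0.25               0.25            0.25                 0.25               0.25
biogenic sequestration [%]                         0.0                1.7             0.8                  1.5               -0.3
total social benefits (million USD)        14 (14, 14)        19 (14, 29)     30 (16, 59)          29 (15, 55)        14 (14, 14)

best/worst averted-mortality ratio: 5703
health benefit lost with carbon-only siting: 100.0%
```

Reading the table: `tech_only` is business as usual (all uptake through
SCR/BHF/CCS; averted mortalities are measured relative to it).  `tes` lets
the optimizer plant trees on available land purely to cut private cost —
it does, and picks up health benefits incidentally.  `tes_plus` adds the
monetized health and climate value to the objective: planting expands
(36 vs 16 receptors) and moves toward populated cells, tripling averted
mortalities for a ~2% private-cost increase.  `tes_plus_budgetmatch` and
`co2_minus` plant the *same number of receptors* under the same budget but
opposite health objectives — they bracket what spatial prioritization
alone is worth, and the bottom lines show it: siting land-use change
without regard to exposure forfeits essentially all of the attainable
health benefit, while carbon accounting stays identical. Every scenario
satisfies per-year carbon neutrality; in early years capture carries the
whole load because young stands are net carbon emitters.

Other examples: `01` landscape generation and the <50% developed-or-water
availability rule, `02` growth-curve fitting and the carbon crossover age,
`03` health valuation with Monte Carlo CIs, `04` a single scenario with
its spatiotemporal planting map. A thin CLI wraps the same library
(`tesland fixtures | run | suite | report`), e.g.:

```bash
tesland fixtures --size small --seed 1 --out /tmp/case
tesland suite --inputs /tmp/case --out /tmp/case/results --draws 2000
```

Inputs are plain CSV/JSON (receptor grid, dispersion-delta fields,
two-column growth tables, facility config); outputs are CSV ledgers,
GeoJSON planting maps (year-coded, null for available-but-unselected
receptors) and a JSON comparison report.

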