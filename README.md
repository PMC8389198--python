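# redgem

Constraint-based analysis of clavulanic-acid (CA) production in
*Streptomyces clavuligerus* with **reduced genome-scale metabolic models**:
model reduction and curation, two-step flux balance analysis with
shadow-price sensitivity, flux variability analysis, coordinate hit-and-run
flux sampling, and quantitative validation against measured exchange rates.

The package is aimed at metabolic engineers and systems biologists who work
with condensed reconstructions of secondary-metabolite producers — networks
small enough for flux sampling and vertex-level analysis, yet faithful to
the central carbon metabolism and the clavam pathway
(glyceraldehyde-3-phosphate + arginine → clavulanic acid, releasing
succinate at the clavaminate-synthase steps).

## The model

A metabolic network with stoichiometric matrix **S** (metabolites ×
reactions) is analysed at pseudo-steady state over the flux polytope

```
P = { v : S v = 0 ,  lb ≤ v ≤ ub } ,
```

fluxes in mmol·gDCW⁻¹·h⁻¹ (growth in h⁻¹), uptakes negative. The core
operations are:

* **FBA** — `max cᵀv` over `P` by LP (HiGHS via SciPy). The dual variable
  λᵢ of metabolite *i*'s balance is its **shadow price** `dZ*/dbᵢ`,
  reported so that *negative* means the metabolite limits the objective,
  *zero* insensitivity, *positive* surplus.
* **Two-step FBA** — maximise CA production to `Z*`, then minimise the
  Manhattan norm `Σⱼ|vⱼ|` subject to `cᵀv = Z*` (split variables
  `v = v⁺ − v⁻`), selecting a parsimonious flux distribution.
* **FVA** — per-reaction `min/max vⱼ` subject to `cᵀv ≥ f·Z*`.
* **CHRR sampling** — near-uniform samples of `P` by coordinate
  hit-and-run in a null-space parameterisation, rounded by the warm-up
  covariance; two conditions are compared per reaction with the
  Kruskal–Wallis rank test (study cutoff *p* < 0.001).
* **Validation** — squared errors `SEᵢ = (Xᵢ − X̂ᵢ)²` between measured
  (`X`) and predicted (`X̂`) fluxes, aggregated as
  `MSE = (1/p) Σ SEᵢ` over the `p` measured fluxes of a scenario.
* **Reduction** — subsystem pruning, dead-end/blocked elimination, lumped
  reactions, biomass-precursor producibility, greedy gap filling, and
  detection/correction of thermodynamically infeasible cycles (closed-
  exchange circulations) with Gibbs-energy directionality evidence.

Models are read and written in SBML Level 3 (+fbc) and a documented JSON
dialect (one object with `metabolites`, `reactions`, `genes`, `objective`;
stoichiometry as `{metabolite_id: coefficient}`, negative = consumed;
bounds default to ±1000 when unstated).

## Worked example

```python
from redgem import (classify_shadow_prices, fba, generate_toy_network,
                    two_step_fba)

model, truth = generate_toy_network()      # 13-reaction CA-pathway analogue
state = model.copy()
mu_max = fba(model, "BIOMASS").objective_value
growth = state.reaction("BIOMASS")
growth.lower_bound = growth.upper_bound = 0.3 * mu_max
state.reaction("EX_succ").upper_bound = 1.0   # cap succinate export

sol = two_step_fba(state)
print(sol.objective_value, sol.sum_abs_flux)
print({m: classify_shadow_prices(sol)[m]
       for m in ("glyc_e", "succ_c", "ca_c")})
```

prints

```
1.0 27.5
{'glyc_e': 'insensitive', 'succ_c': 'surplus', 'ca_c': 'limiting'}
```

CA production is capped at 1.0 mmol·gDCW⁻¹·h⁻¹ — not by the carbon source
(insensitive) but by disposal of the succinate by-product: its positive
shadow price (+1.0) says each unit of succinate absorbed elsewhere would
buy one more unit of CA. The `examples/` directory has one short script
per capability (model I/O, reduction, shadow prices, sampling, published
table validation, the full pipeline).

A thin CLI mirrors the library: `redgem model report`, `redgem reduce`,
`redgem fba|twostep|fva`, `redgem sample`, `redgem validate`,
`redgem shadow`, `redgem synth`, `redgem run --config pipeline.yaml`.

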