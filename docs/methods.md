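# Methods

## Scope and model

`redgem` analyses constraint-based metabolic networks at pseudo-steady
state: fluxes `v` satisfy `S v = 0` with bounds `lb ≤ v ≤ ub`, fluxes in
mmol·gDCW⁻¹·h⁻¹ (growth in h⁻¹), uptake through exchange reactions
negative. The intended use case is a *reduced* genome-scale model of
*S. clavuligerus* — central carbon metabolism plus the clavam pathway, with
peripheral routes lumped — under batch and fed-batch cultivation
constraints, but every operation is generic over any model expressible in
the SBML/JSON dialects.

## Linear programming

All LPs are solved with HiGHS through `scipy.optimize.linprog`, with
solver feasibility/optimality tolerances of 1e-9 requested and all
verification done at 1e-6 (mass balance, bound violations, duality gap).
Default bounds are ±1000 when a file does not state them — wide enough to
be non-binding at physiological flux scales yet keeping every polytope
bounded, which the vertex-enumeration oracle and the sampler both rely on.

**Shadow prices.** The dual λᵢ of metabolite *i*'s balance is reported as
`dZ*/dbᵢ` for the maximisation problem (`S v = b`, `b = 0` at base). Under
this convention a growth- or production-limiting metabolite carries a
*negative* price (requiring net accumulation of it costs objective), an
insensitive one zero, and a by-product whose disposal is the bottleneck a
*positive* price — the interpretation rules used with CPLEX-style duals in
the constraint-based modelling literature. Raw solver duals are kept in
`FluxSolution.raw_duals` for debugging. Shadow prices at degenerate optima
are solver-dependent; the test suite asserts dual values only on
constructed non-degenerate fixtures, where they are verified against
two-point finite differences (`b_i = −ε`, `ε = 1e-4`).

**Two-step FBA.** Step 1 maximises the production objective (CA exchange)
to `Z*`. Step 2 minimises `Σⱼ |vⱼ|` subject to the objective flux staying
at `Z*`, via split variables `v = v⁺ − v⁻`, `v± ≥ 0`; reactions whose
bounds exclude zero (hard growth) keep a two-sided constraint on
`v⁺ − v⁻`. The norm covers the whole flux vector including exchanges —
exchanges are bounded by the scenario, so their inclusion cannot distort
route choice. If step 2 is infeasible at exactly `Z*` (solver tolerance),
it is retried once with `cᵀv ≥ Z* − max(|Z*|,1)·1e-9`, logged. Reported
shadow prices default to the step-1 duals, because the quantity of
interest is the sensitivity of *production*, not of the norm; the step-2
duals are available via `shadow_source="step2"`.

**FVA.** Two LPs per reaction under `cᵀv ≥ Z* − (1−f)|Z*|`
(`fraction_of_optimum = f`, default 1.0; `None` drops the optimality
constraint, which is also how blocked-reaction detection and TIC detection
run). An unbounded direction is reported as ±1e6 with a warning rather
than raising; with the default ±1000 bounds it cannot occur.

## Scenarios

A cultivation state is a `Scenario`: measured growth rate applied as a
*hard* constraint (both bounds), measured uptakes (negative) as *lower*
bounds, measured secretions (positive) as *upper* bounds — the
soft-constraint convention of the published batch/fed-batch comparison
tables, under which a binding constraint legitimately produces SE = 0 for
that flux. Contradictory bounds fail fast naming the reaction.

## Reduction workflow

Reduction runs: (1) subsystem pruning (kept subsystems ∪ protected ∪
objective), then iterated dead-end-metabolite and FVA-blocked removal to a
fixed point; (2) lumped reactions for pathways summarised into a single
net conversion (`LMPD_` prefix); (3) biomass-precursor producibility via
temporary maximised sinks (tolerance 1e-9), with unproducible precursors
dropped from the biomass equation *without renormalising* the remaining
coefficients — the dropped terms are assumed carbon-negligible, so
re-fitting would manufacture precision; (4) greedy gap filling: repeatedly
add the candidate pool reaction enabling the most still-unproducible
targets (ties by pool order). Greedy rather than MILP: additions here
re-connect a handful of producibility chains after pruning, where greedy
is exact in practice and keeps the dependency surface to one LP solver;
the test suite confirms minimality against subset enumeration on two-gap
fixtures. Every structural edit lands in a `ReductionLog` whose replay on
the input reproduces the output exactly.

**Thermodynamically infeasible cycles.** With every exchange closed to
(0, 0), any reaction whose FVA range is not {0} carries a circulation
violating the loop law. Members are grouped into loops via the connected
components of circulation supports (each member's flux pushed to its
extreme). Correction restricts directionality from user-supplied standard
Gibbs energies: ΔG° < −5 kJ·mol⁻¹ → forward-only, > +5 → reverse-only,
inside the ±5 dead band → untouched and listed unresolved. The dead band
reflects typical component-contribution uncertainties; it is a parameter
(`dg_threshold`). A restriction that makes the open model infeasible is
reverted and the reaction marked unresolved. Transport reactions go
through the same machinery — no special class.

## CHRR sampling

The polytope is parameterised on an orthonormal null-space basis of `S`
(`v = v₀ + N u`), so mass balance holds by construction. Warm-up points
are FVA extreme-point solutions (capped by `warmup_points`, default 200);
their covariance in `u`-coordinates provides the rounding transform via a
symmetric eigen-factorisation `T = V·√w`, with eigendirections below
`1e-8·w_max` dropped (these are the degenerate, effectively fixed
dimensions; a hard-growth constraint creates them). This
covariance-rounding is simpler than the maximum-volume-ellipsoid rounding
of the original CHRR formulation and adequate at reduced-model scale — a
deliberate deviation, as the ellipsoid step only matters for
badly-conditioned high-dimensional polytopes. The walk picks a random
rounded coordinate direction, computes the feasible chord from the bounds,
and jumps uniformly; every `steps_per_point`-th state is kept. A single
seeded `numpy` generator drives everything: fixed seed ⇒ bit-identical
sample matrices.

Defaults mirror the study protocol (5000 points, 1848 steps per point).
The test suite and acceptance script run scaled down (500 points, 100
steps; pipeline tests smaller still) to keep the default run in seconds —
the distributional assertions (uniform hypercube marginals at
Kolmogorov–Smirnov distance < 0.05, half-chain stationarity, closed-form
box moments) are sized for those chain lengths.

**Distribution comparison.** Exactly two conditions are compared (as in
the batch vs fed-batch design) with the two-group Kruskal–Wallis test
(tie-corrected H, χ² with 1 df). Significance uses the raw `p < 0.001`
rule of the study protocol; a Benjamini–Hochberg column across reactions
is emitted alongside rather than silently substituted. Identical constant
columns are defined as H = 0, p = 1.

## Validation

`SEᵢ = (Xᵢ − X̂ᵢ)²` per measured flux, `MSE = (1/p)·ΣSEᵢ` over the `p`
rows with measurements (rows flagged unavailable are excluded from `p`).
The published fed-batch table's printed aggregate equals the *sum* of its
SE column, not the mean; `ValidationReport` exposes both `mse` and `sse`
and corrects neither. Measurement uncertainties (± on growth) are carried
as metadata, not folded into SE. Recomputing printed SE cells from rates
printed to three decimals carries a first-order rounding error of
`2|X − X̂|·10⁻³` plus the printed cell's own rounding; the tests use
exactly that propagated tolerance (floored at 0.002).

## Synthetic ground truth

The toy generator emulates the producer's topology at minimal scale
(13 reactions, 10 metabolites): substrate uptake → glycolytic chain → C3
node; a condensation-entry cycle with oxidative branch and a
glyoxylate-shunt analogue; anaplerotic C3→C4; a lumped arginine (C5)
branch; the clavam condensation `C3 + C5 → CA + succinate`; three
exchanges and a lumped biomass reaction (0.5 g3p + 0.3 oaa + 0.2 akg per
unit growth). The stoichiometry yields closed forms: `max CA = uptake/3`
(one substrate unit as C3 precursor, two through the cycle for the C5
precursor) and `max growth = uptake/1.2` — recorded as ground truth and
asserted against the LP. Optional, individually recorded blemishes:
a 2-reaction internal loop (one reversible + one irreversible parallel
conversion, so a single decisive ΔG° dissolves it), orphan dead-end
metabolites, a 3-reaction unreachable branch, a prunable 4-reaction
"minor" subsystem, and redundant 2-step parallel routes for parsimony
tests.

**Scenario emulation.** `generate_scenario` builds the constraint set
(hard growth, sign-assigned exchange bounds) from the *true* fluxes and
perturbs only the *experimental rows* with Gaussian noise of SD σ —
modelling measurement error in the assay rather than in the bound
settings. Under this design the constrained prediction equals the true
flux (the toy polytope is a point once growth and the exchange bounds are
set), so E[SE] = σ² per row and the replicate-mean MSE estimates σ²; with
noiseless rows the MSE is exactly 0. Gaussian noise is the minimal
assumption — the published tables report an uncertainty only for growth.
What passing these tests does *not* show: robustness to model
misspecification (a wrong network), correlated measurement error, or the
respiration-flux mismatches (O₂, CO₂) that dominate the published MSE on
real data.

**Brute-force oracle.** FBA optima on ≤14-reaction networks are
cross-checked by exhaustive vertex enumeration: all active-bound sets of
size `n − rank(S)` whose complementary columns form a basis, solved by
least squares and filtered for feasibility at tolerance 1e-8 (relative to
the bound scale). The oracle shares no code with the LP path.

## Shadow-price analysis across conditions

Per-condition duals are assembled into a complete metabolites × conditions
matrix (intersection of metabolite sets; hole-free by construction on a
shared model). PCA is a column-centred SVD with a deterministic sign
convention (largest-magnitude condition loading positive); explained
variance ratios sum to 1. PCA on a 2-column matrix is acknowledged as
unusual — it is retained because the study design used it for
visualisation, and the |Δ shadow price| ranking (default top 70, ties
lexicographic, invariant under common offsets) is offered as the simpler
equivalent for two conditions. Metabolite ids with either `_c`/`_e` or
`[c]`/`[e]` compartment suffixes are accepted verbatim.

## Pipeline and reproducibility

`run_pipeline` chains, per scenario: constraint application → two-step FBA
→ FVA → CHRR sampling; then cross-scenario Kruskal–Wallis, shadow matrix
+ PCA + top-k, and validation reports. Per-scenario sampler seeds are
derived as `seed·1000 + index (mod 2³¹−1)`. A manifest records seed,
package version and a config hash; a failing stage is recorded in the
manifest with its error and prior outputs are kept. When both conditions
yield identical duals (zero-variance matrix), PCA is recorded as skipped
and the |Δ| ranking still emitted — a legitimate outcome for identical
scenarios, not an error.

## Known limitations

* Shadow prices at degenerate optima (common once measured bounds bind
  simultaneously) are one valid dual vertex, not a unique sensitivity;
  cross-condition comparisons on heavily-constrained small models can be
  flat for that reason.
* Gap filling is greedy, not globally minimal; pathological pools can
  make it overshoot by design.
* The sampler's covariance rounding is not the maximum-volume-ellipsoid
  transform; for near-degenerate large polytopes mixing may be slower
  than reference CHRR implementations.
* TIC grouping by circulation support can merge loops that share
  reactions; for curation purposes (which reactions need directionality
  evidence) this is conservative.
* The `.mat` format of legacy COBRA models is not read natively; convert
  to SBML or the JSON dialect first.
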