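# Methods

## The crowding-constrained flux balance model

`ccrsim` solves flux balance analysis with a molecular-crowding budget
(FBAwMC). A metabolic network with stoichiometric matrix `S` (rows =
internal metabolites, columns = reactions) is assumed at quasi-steady
state, `S·v = 0`, with irreversible fluxes `0 ≤ v_i ≤ ub_i`
(mmol·gDW⁻¹·hr⁻¹) and substrate uptake capped by capacities `U_s`. The
crowding constraint

    Σ_i a_i · v_i ≤ budget      (budget dimensionless, default 1)

models the finite cytoplasmic volume available to enzymes: `a_i`
(hr·gDW·mmol⁻¹) is the enzyme volume demand per unit flux. The objective is
the biomass flux μ (hr⁻¹).

Assumptions and conventions:

- **Reversible reactions are split** into forward/backward copies, each
  inheriting the parent's crowding coefficient, before solving. Enzyme
  demand is direction-independent, and splitting keeps the crowding sum
  linear in non-negative variables, so the whole problem stays a pure LP.
  Split reverse reactions carry the `__rev` id suffix; `merge_split_fluxes`
  restores signed net fluxes.
- **The crowding sum runs over enzyme-catalysed reactions**: internal
  reactions and the biomass reaction (its coefficient represents ribosome
  and biosynthetic-machinery demand, which is what ultimately bounds μ at
  unlimited substrate). Exchange pseudo-reactions are excluded by default;
  `include_exchange_crowding=True` charges transporters too, for studies of
  membrane-space competition.
- **Uptake capacities replace exchange bounds** rather than tightening
  them, so capacity scans can exceed a network's default caps.
- **Degenerate optima are tie-broken parsimoniously**: a second LP stage
  pins the objective at its optimum and minimizes total flux Σv. Reported
  uptake hierarchies are therefore single-valued and solver-independent
  within the stated tolerances (primal feasibility 1e-8, optimality 1e-9,
  recorded on each `FluxState`). Both stages use HiGHS via
  `scipy.optimize.linprog`.

### Verification oracle

`brute_force_oracle` enumerates every candidate vertex of the feasible
polyhedron `{S·v = 0, lb ≤ v ≤ ub, a·v ≤ budget}` directly: all subsets of
`n − rank(S)` inequality constraints are activated in turn, the resulting
linear systems solved with dense least squares, infeasible or rank-deficient
candidates discarded, and the best feasible vertex returned. It shares no
code path with the LP solver, is deliberately exponential, and refuses
instances beyond 12 reactions or 4 free substrate-exchange dimensions. The
test suite checks LP/oracle agreement to 1e-6 on 100 seeded random
instances and on a hand-checkable two-substrate toy whose optimum
(v = (5, 2.5), μ = 7.5 at a = (0.1, 0.2), capacities (5, 5), budget 1)
follows from filling the budget with the cheaper route first.

## The reduced five-substrate network

The packaged fixture (`build_fixture_network`, shipped as
`data/ccr_reduced_network.json`) is a deliberately small stand-in for a
genome-scale reconstruction. Five substrates — glucose and galactose
(6 carbons), maltose (12), lactate and glycerol (3) — are imported and
catabolized to a pyruvate/ATP core:

- per-substrate catabolism: substrate → (carbon-conserving) pyruvate + ATP,
  at a substrate-specific crowding cost;
- **respiration** (OxPhos): pyruvate → 15 ATP + 3 CO₂, high yield, high
  crowding cost (a = 1.2);
- **fermentation**: pyruvate → acetate + CO₂ + 2 ATP, low yield, low
  crowding cost (a = 0.03), with acetate exported;
- acetate reoxidation (a = 0.7) and an anaplerotic acetate → pyruvate route,
  so growth on acetate alone is possible but slow and never worth running
  concurrently with fermentation (its ATP-per-crowding, 8/0.73 ≈ 11, stays
  below respiration's 15/1.2 = 12.5 — no futile loop);
- biomass: 13 pyruvate + 40 ATP per unit growth rate (≈ 39 mmol C·gDW⁻¹,
  about 47% carbon by mass), crowding 0.25.

The crowding coefficients and capacities are package constants with no
measured counterpart; they are fixed by two calibration checks asserted at
construction time and in the test suite:

(a) with the budget removed, the biomass optimum respires only and secretes
    no acetate (overflow must be a crowding phenomenon, not a yield
    artifact);
(b) crowding-limited growth (unlimited uptake, budget 1) is strictly
    ordered glucose ≻ maltose ≻ galactose ≻ lactate ≻ glycerol — the
    biomass-per-unit-crowding ranking that drives the uptake hierarchy.

Calibration also places the interesting regime inside the scanned window:
with default capacities (12, 10, 5, 20, 20 mmol·gDW⁻¹·hr⁻¹ for glucose,
galactose, maltose, lactate, glycerol), the crowding constraint saturates
near D ≈ 0.29 hr⁻¹, substrate shedding begins near 0.48 hr⁻¹, and the
crowding-limited maximum growth rate is ≈ 1.35 hr⁻¹, so the 0.1–0.7 hr⁻¹
dilution scan spans co-utilization, overflow onset, and selective uptake.
The non-preferred substrates carry substantially higher catabolic crowding
costs (galactose 0.12, lactate 0.10, glycerol 0.15 vs glucose 0.02),
standing in for their longer preparatory pathways and costlier transport.
Model outputs on this fixture are **qualitative**: patterns and orderings
are meaningful, absolute fluxes are not.

## Batch simulation (dynamic FBA)

`simulate_batch` advances culture state with an explicit scheme (default
dt = 0.02 hr, default horizon 10 hr). Each step:

1. uptake capacities are set from the configured kinetics — `hard_cap`
   (full capacity while the substrate lasts; the default) or
   `michaelis_menten` (`U·C/(Km+C)`, Km in g·L⁻¹, default 0.05) — and
   additionally capped by what the medium actually contains;
2. the FBAwMC LP yields μ and exchange fluxes;
3. biomass grows exponentially within the step, `X ← X·e^{μ·dt}`, and each
   concentration is updated with the consistent integral
   `ΔC = v · (M/1000) · X·(e^{μ·dt}−1)/μ` (g·L⁻¹, M = molar mass);
4. if a substrate would be overdrawn, the step is re-solved once with that
   uptake bound set to the availability-limited rate, then concentrations
   are clipped at zero.

Initial conditions default to the flask protocol the package emulates:
inoculum OD600 0.035, single substrates at 2.0 g·L⁻¹ (0.2% w/vol), mixed
cultures at 0.4 g·L⁻¹ each (0.04% w/vol). OD600 ↔ biomass uses a single
display constant, 0.4 gDW·L⁻¹ per OD unit; all dynamics run in gDW.
Acetate exchange stays bidirectional throughout, with reuptake capped by
availability and a transporter Vmax (10 mmol·gDW⁻¹·hr⁻¹): diauxic reuptake
after sugar exhaustion *emerges* from the LP when oxidizing accumulated
acetate becomes the best remaining use of the budget; nothing schedules it.

The simulator tracks respired CO₂ so the carbon balance closes: initial
substrate + acetate carbon = residual substrate + acetate + CO₂ + biomass
carbon (from the biomass reaction's precursor stoichiometry). The relative
closure error is ≈ 1e-13 at dt = 0.01 hr (the only losses are the
zero-clips) and is asserted to shrink with dt. The dynamics are
deterministic; `simulate_batch` accepts a `seed` argument only for
interface symmetry with the generators.

Against the analytic solution for a single substrate under a hard cap (LP
solution constant while substrate remains, so dX/dC is constant and
X_final = X0 + μ·1000/(v·M)·C0), the dFBA biomass at exhaustion agrees
within 0.1% at dt = 0.01 hr.

## Chemostat steady states

At steady state μ = D. The substrate-limited closure scales all capacities
by a common λ and bisects (tolerance 1e-8 on μ, expanding the bracket as
needed) until the FBAwMC optimum satisfies μ(λ·U) = D. Joint scaling keeps
the feed composition fixed while varying its richness, which is the natural
single-parameter family for a mixed-feed chemostat; per-substrate
availability profiles can be passed explicitly via `base_capacities`.
Dilution rates above the crowding-limited μ_max raise `WashoutError`
(`dilution_scan` converts it to a flagged row instead of aborting). Feed
and residual *concentrations* are deliberately not modeled — the simulator
works in flux/ratio space, because mapping fluxes back to medium
concentrations would require volumetric biomass data the model does not
produce. No acetate is present in the feed, so acetate reuptake is disabled
at steady state.

Consumption ratios are carbon-weighted: `r_j = v_j·c_j / Σ_k v_k·c_k` with
`c_j` the substrate's carbon atoms per molecule. `ccr_onset` reports the
first scanned D at which the crowding constraint saturates
(lhs ≥ budget − 1e-6).

## Kinetics and gradient analyses

- **Growth rate**: `GR_t = ln(OD_t/OD_{t−1})/Δt` (hr⁻¹), the only
  dimensionally consistent reading of the interval growth statistic; a raw
  ratio variant `(OD_t/OD_{t−1})/Δt` is exposed but not default.
- **Normalization**: substrate divided pointwise by OD (linear
  interpolation onto the substrate grid, no extrapolation), rescaled to
  start at 1. Division by final OD is available as a flag; pointwise is the
  default.
- **One-phase decay**: least squares on
  `y(t) = plateau + (y0−plateau)e^{−Kt}` (scipy `curve_fit`, initial values
  from log-linear regression on `y − min y`, K unbounded). Half-life is
  `ln2/K` — the time to reach the midpoint `(y0+plateau)/2` for any
  plateau. A non-positive fitted K or optimizer failure is reported as
  `converged=False`, never raised; an all-constant series is a `no-decay`
  error. The fit is scale-equivariant (K and half-life invariant under
  `y → c·y`, property-tested).
- **Promoter activity**: pointwise GFP/OD, with induced/uninduced fold
  ratio as a separate helper.
- **Cell density distribution**: after per-layer blank subtraction
  (negatives clipped to zero with a warning),
  `CDD_ρi = OD_ρi / Σ_{i=0..7} OD_ρi` over the default eight-layer gradient
  (1.19, 1.18, 1.16, 1.14, 1.12, 1.10, 1.08, 1.06 g·ml⁻¹; configurable).
  Summaries: modal layer and OD-weighted mean density. An all-zero profile
  is an `empty-gradient` error.

## Synthetic data

Generators draw from a private stream per (seed, generator name) —
`SeedSequence([seed, crc(name)])` — so outputs are byte-reproducible and
adding generators never perturbs existing ones. Noise defaults emulate
plate-reader variability: 2% CV multiplicative lognormal (mean-one) on OD
and concentrations, 0.002 additive Gaussian on gradient layer ODs; all
configurable, none measured.

- `generate_batch_observations` samples OD and substrate concentrations
  every 30 min, from either closed-form truth (logistic OD; substrate
  following the decay law in biomass-normalized space, so the
  normalize-then-fit pipeline recovers K exactly at zero noise) or a
  simulated `BatchTrajectory`.
- `generate_gradient_profile` discretizes a Gaussian cell-mass loading onto
  the gradient layers and returns raw (blank-inflated) ODs with the
  matching blank column, exercising background subtraction downstream.
- `generate_induction_timecourse` produces paired induced/uninduced GFP+OD
  series whose true post-onset per-OD fold change equals `fold`.

What these generators do **not** emulate: lag phases, evaporation and
pipetting drift, autofluorescence and GFP maturation kinetics, gradient
layer mixing, or correlated errors between replicates. Recovery tests
therefore demonstrate estimator correctness under the stated error model,
not robustness to every failure mode of real plate data.

The recovery studies fix the study conditions used throughout the tests and
the acceptance script: decay K = 0.5 hr⁻¹, 20 points over 6 hr, 2% CV, 200
replicates (median relative K error ≈ 1.8%, bound 5%); gradient center
1.13 g·ml⁻¹, spread 0.02, 100 replicates (mean-density bias ≈ 2e-4,
bound 0.005 g·ml⁻¹).

## Problem sizes and runtime

The test suite and `scripts/acceptance.py` run the fixture (28 reactions
after splitting) end-to-end: the 7-point dilution scan (~100 LP solves per
point from the bisection), batch runs at dt = 0.01–0.1 hr over 3–8 hr
horizons, 100-instance solver cross-checks and 200/100-replicate recovery
studies. The whole acceptance script completes in well under a minute on a
single CPU; these sizes were chosen to keep the feedback loop tight while
exercising every regime (slack/saturated crowding, exhaustion, washout).

## Known limitations

- The fixture's crowding coefficients are calibrated constants, not
  measurements; only orderings, onsets and zero/positive patterns transfer
  to real organisms.
- The crowding budget is static; regulation, proteome sectors and
  expression delays are outside scope, so the model cannot show hysteresis
  or transient misallocation.
- dFBA assumes instantaneous metabolic re-optimization each step and no
  lag phase.
- The chemostat closure fixes feed composition up to a scale; nutrient
  ratios that change with D are not represented.
- `load_network(..., format="tsv")` carries topology only; bounds, kinds
  and crowding coefficients must be supplied by the caller or defaulted.
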