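# ccrsim

Constraint-based modeling of **carbon catabolite repression (CCR) as a
consequence of macromolecular crowding**, for systems biologists studying
bacterial substrate preference and overflow metabolism.

When *E. coli* grows on a mixture of carbon sources it famously consumes
glucose first and the poorer substrates later, and at high growth rates it
secretes acetate even with oxygen to spare. `ccrsim` reproduces both
behaviors from a single physical assumption: the cytoplasm has finite room
for enzymes. Flux balance analysis is augmented with a *molecular crowding*
budget,

```
max   v_biomass
s.t.  S·v = 0
      0 ≤ v_i ≤ ub_i,   v_ex ≤ U   (uptake capacities)
      Σ_i a_i · v_i ≤ 1            (crowding constraint)
```

where `a_i` (hr·gDW·mmol⁻¹) is the enzyme volume demand per unit flux of
reaction *i* and the dimensionless budget (default 1) caps total enzyme
occupancy. With the budget removed (`∞`) the model collapses to plain FBA.
Uptake hierarchies, the acetate switch, and their growth-rate dependence are
*outputs* of this LP, not rules coded into the simulators.

The package provides:

- **`ccrsim.network`** — crowding-annotated metabolic networks (JSON schema,
  TSV stoichiometry), reversible-reaction splitting, and a calibrated
  reduced five-substrate network (glucose, galactose, maltose, lactate,
  glycerol feeding a pyruvate/ATP core with a high-yield/high-crowding
  respiratory branch and a low-yield/low-crowding fermentative branch).
- **`ccrsim.fba`** — the crowding-constrained LP with parsimonious
  tie-breaking; **`ccrsim.oracle`** — an exhaustive vertex-enumeration
  cross-check for small instances.
- **`ccrsim.batch`** — dynamic FBA of batch cultures (sequential substrate
  exhaustion, acetate overflow and reuptake).
- **`ccrsim.chemostat`** — steady states across dilution rates D (μ = D),
  carbon-weighted consumption ratios, CCR onset detection.
- **`ccrsim.kinetics`** — growth rates `GR_t = ln(OD_t/OD_{t−1})/Δt`,
  biomass-normalized one-phase-decay uptake fits
  `y(t) = plateau + (y0−plateau)e^(−Kt)`, GFP/OD promoter activity, and the
  density-gradient cell density distribution `CDD_ρi = OD_ρi / Σ OD_ρi`.
- **`ccrsim.synth`** — seeded generators for every input above, with known
  ground truth.

## Worked example

Scan chemostat steady states on the packaged network
(`examples/run_chemostat_scan.py`):

```
D(/hr)  crowding_lhs  acetate(mmol/gDW/hr)  glucose%  glycerol%
  0.1        0.3489                0.0000      23.1       19.2
  0.2        0.6977                0.0000      23.1       19.2
  0.3        1.0000                0.3646      23.1       19.2
  0.4        1.0000                3.0931      23.1       19.2
  0.5        1.0000                5.4124      24.0       15.9
  0.6        1.0000                6.2976      27.5        3.9
  0.7        1.0000                7.1129      31.1        0.0
```

Reading the table: at slow growth (D ≤ 0.2/hr) the crowding constraint is
slack (`lhs < 1`), all five substrates are co-consumed in proportion to
their capacities, and no acetate is secreted. From D ≈ 0.3/hr the enzyme
budget saturates; the cell first switches pyruvate processing toward cheap
fermentation (acetate secretion climbs from 0 to 7.1 mmol·gDW⁻¹·hr⁻¹) and
then sheds the crowding-expensive substrates — glycerol's share of carbon
uptake collapses from 19% to 0 while glucose's rises from 23% to 31%. Run
the same scan with `crowding_budget=math.inf` and the hierarchy and the
acetate switch both disappear.

The batch analogue (`examples/run_batch_cultures.py`) shows the kinetic
face of the same mechanism — exhaustion order glucose (2.20 hr) → maltose →
galactose → lactate → glycerol (4.96 hr), a mixed-culture peak growth rate
of 1.34 hr⁻¹ above every single-substrate peak, and transient acetate that
is re-consumed after the sugars run out.

Each script in `examples/` is a short, self-contained demonstration of one
capability; a thin `ccrsim` command-line wrapper (`ccrsim batch`,
`ccrsim chemostat`, `ccrsim fit-decay`, `ccrsim growth-rate`,
`ccrsim density`, `ccrsim synth …`) exposes the same operations on TSV
inputs and outputs.

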