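# Methods

## Model formalisms

A **kinetic model** is a set of species with initial concentrations (mM),
compartments, and reactions carrying signed stoichiometries and infix rate
laws over species, parameters, and compartment sizes. Rate laws are parsed
with sympy (SBML Level-3 infix; `^` is power; `ln`/`log`/`exp` supported)
and compiled to vectorised callables. Rates are interpreted directly in
concentration units (mM s⁻¹) with unit compartment volumes; models whose
rate laws produce substance rates should be normalised before import.
Boundary species (SBML `boundaryCondition` or `constant`) are held fixed
during integration, which is how sources and sinks keep a steady state
reachable.

A **constraint-based model** is stored as the dense tuple
`{R, M, S, L, U}` plus objective weights `c`, with reaction and metabolite
ids treated as opaque strings. SBML-fbc and BiGG-style JSON are both
accepted, read via COBRApy after an explicit bounds-presence check (a
missing bound is an error, never silently defaulted to ±1000). The Petri-net
projection (metabolites → places, reactions → transitions, arcs weighted by
|stoichiometric coefficient|, H⁺/H₂O not filtered) is exported as Graphviz
DOT text.

## Steady-state simulation

The ODE system is integrated with `scipy.integrate.solve_ivp` (LSODA,
`rtol = 10⁻⁸`, `atol = 10⁻¹⁰`) to `t_end = 3600 s`. Convergence is declared
when `max|d[s]/dt| ≤ 10⁻⁶ mM s⁻¹` over non-boundary species; if the
criterion is missed, the horizon is extended once to `10·t_end` before the
result is flagged unconverged — a single extension distinguishes "slow but
settling" from genuinely divergent systems without hiding the latter.
Solver failures and negative concentrations beyond `10³·atol` raise, with
sub-noise negatives clipped to zero. Fluxes are the rate laws evaluated at
the final state. The integrator tolerances are implementation defaults;
tests check that halving them leaves the steady state unchanged to 10⁻⁶.

**Growth-rate units.** The growth reaction's flux is read as a specific
growth rate in h⁻¹ with no unit conversion. A biomass "flux" is not a
metabolite flux: in genome-scale models the biomass pseudo-reaction's flux
is the specific growth rate by construction, and the chemostat reference
condition (dilution 0.1 h⁻¹) is only consistent with this reading. The
mM s⁻¹ → mmol gDW⁻¹ h⁻¹ conversion applies to mapped metabolite fluxes
only.

## Bound translation

The conversion factor is `c = 1.77·10⁻³ L gDW⁻¹ × 3600 s h⁻¹ = 6.372`.
Intervals are `[c(1−d)f, c(1+d)f]` for categories C0–C3 and the negated,
re-ordered interval for C4. `d = 0` is allowed (pins the flux exactly;
useful for testing); `d ≥ 1` is rejected because the lower bound would
change sign, which the interval model does not define. Negative kinetic
fluxes are rejected — fluxes are positive by convention and inverted
orientation is what C4 is for. Translated bounds *replace* the original
bounds outright rather than intersecting them; the translated intervals are
ordinarily far inside loose defaults, and replacement keeps the translation
idempotent and order-free.

**C1/C2 matching.** The small-species set is exactly {H⁺, H₂O} and the
acid-hydrolysis identification exactly {HCO₃⁻ ↔ CO₂}, matched on common id
spellings (BiGG-style `h_c`, `h2o_c`, `hco3_c`, `co2_c`, and plain-name
variants). Classification is a curation assistant and validator, not an
automatic whole-model matcher.

**C5 surrogate.** For subnetwork entries, the net kinetic
production/consumption across each metabolite shared between the kinetic
subnetwork and the constraint-side reaction is computed from the
steady-state fluxes, scaled by the constraint reaction's stoichiometric
coefficient, averaged over shared metabolites, and pushed through the
standard interval formula (the reversed-orientation formula when the net
flux opposes the constraint reaction). This net-boundary-flux rule is this
package's own construction for mapping structurally different subnetworks;
it is exact for serial chains lumped into one reaction and errors out when
the two sides share no metabolite.

## FBA, FVA, dormancy

FBA and the 2·|R| FVA subproblems are solved with HiGHS via
`scipy.optimize.linprog` (primal/dual feasibility tolerances ~10⁻⁹).
COBRApy/GLPK serves as an independent cross-check in the test suite, and on
fixtures with ≤ 7 reactions both are checked against brute-force vertex
enumeration of the flux polytope. Infeasibility is reported as a status,
never masked with zeros. FVA defaults to `q = 0.999` — sitting exactly on
the optimal face (`q = 1`) can defeat LP solvers numerically — and only
optimum values and min/max fluxes enter reported metrics, so results do not
depend on which optimal vertex a solver happens to return. The dormancy
threshold `ε = 10⁻² mmol gDW⁻¹ h⁻¹` is deliberately four orders of
magnitude above solver noise. FV(r) is clipped at zero against
sub-tolerance inversions between the two independent LP solves.

## Enrichment sweep

Bounds are applied cumulatively in the caller's order (the reference order
follows glucose metabolism; order is never hard-coded). After each addition
FBA and FVA run and the metrics are recorded; the variability baseline is
the original model's FVA at the same `q`. An infeasible addition is data:
the step is recorded with `feasible = False` and the sweep stops, or — in
skip mode — the offending bound is left out and the sweep continues. The
growth-monotonicity property (μ nonincreasing) holds whenever each applied
interval tightens the reaction's previous bounds, which is the designed
regime of the fixtures and the observed regime of the reference analysis;
replacing an already-tight bound with a looser interval can raise μ, which
is why the glucose-capped producer model is constructed once, before the
sweep, rather than mid-sweep.

## Citramalate producer strain

The synthase (id `CIMA` in the constraint model, `CITRA_SYN` in the kinetic
model) uses the Michaelis–Menten law `Vmax·[AcCoA]/([AcCoA]+Km)` with
`Km = 0.495 mM` and `Vmax = 4.06 mM s⁻¹` (per-cell CimA3.7 activity
24.34·10⁻¹⁰ nmol s⁻¹ over a 6·10⁻¹⁶ L cell; 1 nmol L⁻¹ = 10⁻⁶ mM).
Pyruvate is assumed saturating: it appears in the stoichiometry for mass
balance but not in the rate law. Transport
(cytosol → periplasm → extracellular) and exchange reactions are
irreversible outward with bounds [0, 1000]. In the kinetic model
citramalate (and any absent CoA/H⁺/H₂O) is a boundary species, mirroring
the exchange reaction on the constraint side.

Conversion efficiency is `(v_cit·M_cit)/(v_glc·M_glc)` with
`M_cit = 148.11`, `M_glc = 180.16 g mol⁻¹` — the only dimensionally
consistent reading of "grams of product per gram of substrate" from molar
fluxes; the masses are configurable. Enriched producer analyses pair the
bound-translation `d` with the same `d` in the growth interval, and the
kinetic fluxes are taken from the kinetic model *with* the synthase
inserted, so translation and growth fixing describe the same physiological
state.

## Synthetic fixtures

The fixtures emulate the reference study conditions at toy scale: glucose
uptake 0.23 mM s⁻¹ and a growth rate of 0.1 h⁻¹ (chemostat dilution) in the
branch motif; chain rate constants are drawn reproducibly from the seed
(uniform 0.3–3 s⁻¹, a mid-range for central-carbon first-order constants)
and the steady flux is seed-independent by chain conservation. The branch
constraint model's biomass reaction consumes its precursor with
stoichiometric coefficient 6.372 per unit growth — numerically equal to the
unit-conversion factor — so that the kinetic steady state is *exactly*
feasible after translation at any `d ≥ 0`; this plays the role that the
genome-scale biomass equation's precursor demand coefficients play in a
real model. Dead-end reactions in the chain model guarantee a nonzero
dormant count.

What the fixtures do **not** emulate: genome-scale network redundancy
(alternative pathways, cofactor cycling), realistic biomass composition,
and enzyme-level regulation. Passing tests therefore demonstrate the
correctness of the machinery (simulation, translation, LP analyses, and
the bifurcation-resolution mechanism), not genome-scale numerical
predictions: quantities such as the conversion efficiencies reported by the
acceptance script are toy-scale analogues whose *trend* (efficiency highest
without kinetic bounds, decreasing as `d` decreases) matches the
genome-scale behaviour, not their magnitudes. The category-zoo fixture is a
classification target only; its constraint model is deliberately not
flux-balanced.

## Known limitations

* Rate-law support covers the algebraic functions listed in the parser
  table; `piecewise`, delays, and events are not supported.
* The C5 translation is a net-flux surrogate, exact only for flux-conserving
  lumpings; entries whose subnetworks interconvert shared metabolites
  non-conservatively should be curated by hand.
* FVA solves two LPs per reaction from scratch (no warm starts); at
  genome scale a sweep with per-step FVA is minutes, not seconds.
* Replacing bounds (rather than intersecting) assumes curated mappings;
  conflicting assignments for the same reaction are applied last-wins.
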