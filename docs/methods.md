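# Methods

## Scope and model structure

rhizosim simulates one maize plant for 40 days in a 60 × 26 × 150 cm soil
monolith whose properties vary only with depth. The soil is a 1-D column of
uniform layers (default 150 × 1 cm) carrying bulk density, porosity, water
state and nitrate mass; the root system is a 3-D tree of straight segments
grown daily. The two couple through exactly one interface in each direction:
soil → roots through the scalar penetration-resistance field (plus nitrate
available for uptake), and roots → soil through nitrate uptake. Water is not
taken up by roots: the model isolates mechanical impedance and nitrate
dynamics, so soil water matters only through soil strength, transport and
leaching.

A daily macro step runs: surface forcing → water flow → nitrate transport
(→ optional mineralization) → impedance-field refresh → photosynthesis and
reserve draw → carbon allocation → root elongation and branching → nitrate
uptake → stress update → ledgers. All stochastic draws (heading wobble,
branching azimuths, emergence azimuths) come from a single generator seeded
per run, so a (configuration, seed) pair reproduces every output bit for
bit.

## Soil strength

Penetration resistance is computed per layer as

    Q = ρ · [ A*(F − e)²/(1 + e) · (σₛᵖ − ψS*)^f ]²            (kPa)

with ρ bulk density (g cm⁻³), e porosity (1 − ρ/2.65 by default), σₛ the
overburden stress from the weight of overlying layers, ψ ≤ 0 the matric
potential (kPa) and S* = θ/e the degree of saturation. The grouping of the
exponents follows the convention that the water/stress term enters once,
inside the squared bracket; all four constants are configuration entries so
any refitted form with the same symbols is parameter-compatible.

The bundled constants (A* = 170, F = 0.8, p = 0.5, f = 0.5) are calibrated,
not fitted to penetrometer data: they place the uniform 1.0 g cm⁻³ profile
near 0.15–0.3 MPa (mild impedance), a wet plow pan at 3–8 MPa, and keep the
convolved density → relative-elongation response monotone and quasi-linear
over 1.1–1.6 g cm⁻³ at moist field states. Two properties guided the
calibration: the density term must dominate the water term (soils perched
wet above dense layers would otherwise read mechanically *softer* than a
drained loose profile, inverting every compaction contrast), and Q at the
1.6 g cm⁻³ extreme must sit several-fold above the 4000 kPa characteristic
hardness so the phenotype contrast is expressed. Near-saturated and very dry
states push Q outside the quasi-linear range; the response then saturates
and linearity (R² of a linear fit) degrades below 0.95.

Q is interpolated piecewise-linearly in depth between layer midpoints
(interpolating Q, the physical field, not the per-class response), clamped
beyond the column, horizontally uniform and isotropic: impedance scales the
rate of growth, never its direction. A depth profile of Q may also be
supplied directly, bypassing the pedotransfer function.

## Root responses

Elongation of every root class is scaled by R_I = 1 − Q/(Q₅₀ + Q): unity at
zero strength, ½ at Q₅₀, approaching 0 in very hard soil. The axial Q₅₀
applies to primary, seminal and nodal roots; the lateral Q₅₀ to first-order
laterals — the two-way split that defines the four phenotypes
(1000/4000 kPa each way). New growth thickens by D_I = R_I^(−α) (α = 0.4
throughout, configurable); the expanded diameter raises construction carbon
per cm by D_I² but does not improve penetration. Existing segments never
re-thicken: expansion applies to growth laid down while impeded.

## Soil water and nitrate

Water follows the mixed-form Richards equation on the layer grid
(van Genuchten retention, Mualem conductivity), implicit in time with
modified-Picard iteration, a flux upper boundary (rain minus supply-limited
evaporation) and free drainage (unit gradient) below; a no-flux lower
boundary is available and is exercised by the hydrostatic steady-state test.
Three numerical choices matter in compacted profiles, where rain perches
above slow layers: conductivity is regularized to reach Ks at a small
capillary height (−2 cm) because the exact Mualem curve has infinite slope
at saturation; the retention curve continues above saturation with a tiny
linear storage branch (10⁻⁴ cm⁻¹) so the capacity term stays continuous
across the kink; and Picard iterations beyond the sixth are relaxed
(ω = 0.3) to suppress two-cycling around that kink. Substeps (base 0.1 d)
halve on non-convergence down to 10⁻⁵ d, then fail loudly with the state.
Mass balance is tracked per step; over a 40-d run the accumulated defect is
below 10⁻⁴ of boundary throughput (ledger tolerance 10⁻³).

Nitrate moves by explicit finite-volume advection (upwind, CFL-sub-stepped)
plus dispersion (dispersivity 1 cm × flux, diffusion 0.5 cm² d⁻¹ × θ) using
the water solver's time-averaged interface fluxes. Rain carries no solute
in; evaporation leaves solute behind; advective flux through the bottom
accumulates as leached mass. The scheme conserves mass to machine precision
(ledger: initial + mineralized = remaining + leached + uptake), keeps
concentrations non-negative via a per-layer outflow limiter, and moves a
solute band's centroid at exactly the pore-water velocity under steady flux.
Mineralization is a zero-order source, default off.

Layer hydraulics come from a bundled, bulk-density-indexed table for a
Hagerstown-like silt loam (9.4/67.1/23.5 sand/silt/clay). The table is a
synthetic stand-in approximating pedotransfer behaviour: saturated content
tracks porosity minus entrapped air, n declines mildly, and Ks falls
log-linearly from 25 cm d⁻¹ at 1.0 g cm⁻³ to 4 cm d⁻¹ at 1.6 g cm⁻³, enough
to retard percolation and nitrate descent in dense subsoil without
permanently waterlogging the pan under the 3 cm/3 d high-leach rain.

## Root architecture

Axial roots emerge at the seed position on a schedule (primary at day 0,
four seminals over days 1–3, nodal whorls of four at days 8/12/16/20);
laterals emerge every 0.6 cm along axials at 70° from the parent with
uniform-random azimuth, grow determinately for 12 d, and never branch.
Default potential elongation is 4.5 cm d⁻¹ for axials and 1.2 cm d⁻¹ for
laterals; base diameters are 0.10/0.08/0.12/0.03 cm for
primary/seminal/nodal/lateral. Headings evolve by a gravitropic pull toward
vertical plus Gaussian wobble, both scaled by the length grown so
trajectories do not depend on the step size; roots reflect off the four
vertical walls (mirroring the relevant heading component, standing in for
neighbouring plants) and clamp at the surface and column bottom.

Per step, each active tip demands `potential × R_I × stress multiplier ×
dt` of length at construction cost `π/4·(base_diameter·D_I)² × tissue
density × carbon fraction` per cm; if summed demand exceeds the carbon
offered, every tip scales back by the same factor. Newborn laterals take a
half-length first step, since their emergence site is passed mid-step on
average — one of three discretization choices (with length-scaled direction
noise and the logistic shoot demand below) that keep day-40 totals within
~1 % when the macro step is halved.

The axial elongation and branching defaults are faster and denser than
common literature defaults for simulated maize (4.5 vs ~3 cm d⁻¹; 0.6 vs
0.8 cm spacing): at desk scale with a 40-d horizon, slower axials never
carry root length below 75 cm in any scenario, which would erase the
deep-foraging contrast between penetration phenotypes that the factorial
exists to measure. The chosen values keep 40-d rooting depth (~0.9–1.2 m in
loose soil) and total length (~150–350 m) within the envelope reported for
field maize at comparable age.

## Plant carbon and nitrogen economy

Carbon comes from a 0.15 g C seed reserve (drawn at up to 0.03 g C d⁻¹,
with surplus photosynthate returning to the same buffer) and from canopy
photosynthesis `LUE·I₀·(1 − e^(−k·LAI))·area` (LUE 1.4 g C MJ⁻¹, I₀ 10 MJ
m⁻² d⁻¹, k 0.6) over the 0.156 m² footprint. Maintenance respiration (paid
first) uses per-class coefficients on root biomass and 0.015 d⁻¹ on shoot
carbon. Remaining carbon is split between root demand (from the tips) and
shoot demand in proportion to demand when short. Shoot potential growth is
logistic — relative rate 0.25 d⁻¹ with a 25 g C ceiling — representing the
determinate vegetative phase; an unbounded exponential demand would keep
the late run permanently carbon-rationed (and makes day-40 outputs sensitive
to the macro-step size through first-order compounding). Shoot growth
converts to leaf area at 300 cm² per g DW × 0.6 leaf fraction.

Nitrate uptake follows Michaelis–Menten kinetics on segment surface area
(Imax 10 µmol cm⁻² d⁻¹, Km 0.05 µmol cm⁻³) against the solution
concentration of the layer containing the segment midpoint, capped pro rata
so no layer goes negative. The stress index uses optimal and minimal plant N
contents proportional to shoot dry weight (5.5 % and 2 % N); the kernel
credits 1200 µmol of seed N. Stress maps linearly onto multipliers for
photosynthesis, leaf expansion and root growth with floors 0.2/0.2/0.5 —
roots are penalized least, so the root mass fraction rises under N
limitation, the usual allocation response to low fertility.

The N-demand fractions, SLA and the high-leach rain depth (3 cm every 3 d;
low-leach 0.5 cm; evaporation 0.2 cm d⁻¹) were set together so that the
study conditions are realized: the high-leach regimes move the nitrate D50
well below 80 cm by day 40 while the low-leach regime keeps it in the top
20 cm, and nitrate stress in compacted soils emerges around day 20–25
(plow pan ≈ day 20, gradient ≈ day 24 under low N/high leach), earlier and
higher than in the uniform profile. These are parameterization choices, not
fitted values; each is a single config entry.

## Scenario configuration and outputs

`ScenarioConfig` holds one factorial cell (soil profile × phenotype ×
nitrate regime) plus every module's parameter table, serializes to YAML, and
hashes for provenance. `run_simulation` returns daily time series (lengths,
depth quantiles D90-roots and D50-nitrate with linear interpolation inside
the crossing bin, stress, uptake, and the closing water/nitrate/carbon
ledgers), the final grid and architecture, and run provenance;
`run_factorial` sweeps cells × replicates with seeds `base_seed + replicate`
and aggregates replicate means and standard deviations, reporting failed
cells without aborting the sweep. Exports: tidy CSV, RSML 1.0 (nested root
hierarchy, per-node diameter; round-trips through the bundled reader at
10⁻⁶ cm) and legacy-ASCII VTK polylines.

## What the synthetic scenarios do and do not show

Every input is generated: there is no field data in the package. The
scenarios emulate the structure of a compaction × phenotype × fertility
experiment — the direction and ordering of treatment effects under the
model's assumptions — not any particular site. Absolute magnitudes (biomass,
total length, uptake) depend on stand-in parameters (hydraulic table,
pedotransfer constants, economy defaults) whose true values are not
reproduced here; passing tests therefore support the orderings,
conservation properties and response-function identities, and say nothing
about quantitative field prediction. Known limitations: no root water
uptake or water-stress feedback; one plant with mirror-image neighbours; no
second-order laterals, root mortality, or plastic lateral determinacy; soil
properties fixed in time; nitrification and ammonium excluded; the shoot is
non-geometric. Outputs are hypotheses about mechanism, not predictions.
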