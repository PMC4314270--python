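# Methods

## Scope and data model

The package computes, on a regular grid of square cells (default 300 m,
cell area S = 0.09 km²), the chain *biodiversity indices → fire ensemble →
risk surfaces*. Each cell carries a fractional composition ρ over a set of
vegetation units; the residual 1 − Σρ is an unvegetated class. All
operations use either (row, col) with row 0 at the north edge or a flat
row-major cell index. Rasters are ESRI ASCII grids; storing surfaces with
full `repr` precision makes float64 I/O round-trips exact.

## Biodiversity indices

**Diversity.** DVU_u = (a·TS_u/TS_L + b·ES_u/ES_L + c·SES_u/SES_L)/AS_u
mixes three richness ratios — share of all species, of island endemics and
of unit-restricted endemics — and divides by the unit's present extent.
Weights default to a = b = c = 1; they are exposed because a manager
focused on endemism would raise b and c. The index is invariant to scaling
all counts and totals by a common factor, a property the test suite pins.

**Vulnerability.** Vul_u = (PS_u/AS_u)·Time_u. The ratio of potential to
actual extent measures historical regression; the dimensionless
time-to-recover coefficient (normalized so its slowest unit is 1) measures
how long the unit needs to return after a fire. The functional form is
implemented in one function (`unit_vulnerability`) so an alternative —
e.g. ((PS−AS)/AS)·Time — can be substituted without touching anything
else; the packaged attribute table discriminates between the two (the
alternative fails the sclerophyll value by 3%).

**Loss.** Two products are deliberately kept distinct. The *unit-level*
BL_u = DVU_u·Vul_u is the published tabular column. The *cell-level*
BL_i = DNC_i·Vul_i (with DNC the landscape-normalized diversity,
Σ DNC = 1) is what the risk surfaces consume: it weights instantaneous
loss by each cell's share of the landscape's diversity. Vulnerability is
attributed to mixed cells by linear composition weighting, the same rule
used for diversity.

**The packaged attribute table.** Two CSV variants ship. `as_printed`
reproduces the source table verbatim, including its internally
inconsistent maquis rows (the high-altitude row lists more unit-restricted
endemics, 242, than total species, 200). `ses_swapped` exchanges the two
maquis SES entries (21 ↔ 242); only under this variant do the recomputed
diversity values match the published ones (2.16e-4 and 3.44e-3 against
printed 0.00022 and 0.0034), so the swap is judged a typesetting
transposition. User data is never silently altered: SES ≤ ES ≤ TS
violations raise a warning and keep the row. One published vulnerability
value resists reproduction: the middle/low-altitude maquis prints 0.05
where (473/4223)·0.5 = 0.056 — consistent with truncation rather than
rounding of the printed value. The corresponding acceptance test asserts
the stated 5% tolerance on all seven values and therefore fails on exactly
that row; the bound was not loosened.

## Fire spread stand-in

Real applications use an external fire behavior simulator; the built-in
model exists so the pipeline is exercisable and testable end to end. It is
a minimum-travel-time scheme on the directed 8-neighbour graph:

* cell effective rate of spread = composition-weighted mean of unit base
  rates (m/min) × moisture factor ∈ (0, 1];
* edge travel time = edge length / (mean of the two cell rates × wind
  alignment), with alignment = max(0.1, 1 + w·cos(θ − downwind)) and
  w = wind_speed/(wind_speed + 10) — bounded, monotone in wind speed,
  exactly 1 under calm;
* all cells with arrival time within a duration budget burn; Dijkstra runs
  in compiled code (`scipy.sparse.csgraph`), one multi-source sweep per
  batch of ignitions.

Per-cell rate of spread is the speed along the first-arrival edge; fire
line intensity is intensity_coeff × RoS, with the coefficient mixed over
all units in the cell. Severity is I·(1/RoS), residence time being the
reciprocal spread rate; the product is the minimal combination of the two
quantities and lives behind one function so a weighted variant can be
swapped without touching the risk engine.

An optional *edge leakage* mode scorches vegetated non-flammable cells
8-adjacent to the burnt patch (at a small fixed rate, default 0.5 m/min)
without letting them carry fire. This models understorey/edge damage at
secondary–primary interfaces and is what makes interface ignitions carry
measurably higher one-off risk.

A non-flammable ignition returns a degenerate single-cell fire with zero
intensity and spread plus a warning, rather than raising — ensembles over
all candidate cells should not abort on unburnable ones.

**Duration budget.** The default (165 min) was calibrated once so that the
median fire on the default 60×60 synthetic landscape burns ≈ 50 cells
(4.5 km²), a mid-sized event at 300 m resolution; tests that probe local
interface effects use shorter budgets (≈ 40 min, ~3-cell radius) to keep
the contrast local. Stand-in fuel parameters (savanna 25 m/min at
60 kW/m per m/min, maquis 6–10, sclerophyll 5, humid forest 1.5 at
300 kW/m per m/min) encode only the ordering "grassy secondary formations
spread fast at moderate intensity, closed forest barely carries fire but
burns hot"; they are not field-calibrated.

## Ignition surfaces

FIP values are treated as relative weights, never as calibrated per-cell
probabilities: every consumer either normalizes by a sum (burn
probability) or by a maximum (risk surfaces), making all outputs invariant
to a positive rescaling of FIP — a property under test. The "daily" vs
"ten-year average" distinction is a metadata tag; the arithmetic is
identical.

The synthetic generator places mass as background + road term + village
term, each distance-decayed as exp(−d/λ) with λ = 430 m, then rescales to
max 1. Defaults (background 0.005, road weight 1.0, village weight 0.5)
were chosen so that on the default landscape at least 50% of total
ignition mass lies within 500 m of a road and at least 80% within 1 km,
the anthropogenic clustering pattern the surface is meant to emulate
(measured values ≈ 68% / 89%). Distances use an exact Euclidean distance
transform, which is also the independent oracle in the calibration test.

## Risk engine

**One-off impact** supports two modes because whether severity weights the
burnt-area sum is genuinely ambiguous in the method this implements:
`sum_bl` (Oe_j = Σ BL_i over B_j) and `severity_weighted` (each burnt cell
weighted by that fire's max-normalized severity, keeping Oe on BL's
scale). The pipeline default is `severity_weighted`; tests needing exact
hand-computable sums use `sum_bl`. The cell-area factor S_i is omitted
from Oe: it is constant per grid and cancels under the final
normalization.

**Burn probability.** BP_i = Σ_j FIP_j·BAM_ij / Σ_j FIP_j over the
simulated ignition set. Implementation detail: weights are divided by
their maximum before the ratio — mathematically a no-op, but it makes the
uniform-FIP case sum plain 1.0s and therefore reduce *bitwise* to the
classic count/N ratio. A Monte-Carlo test (100,000 FIP-sampled ignitions
replayed through the matrix columns) confirms the weighted ratio is the
exact expectation of empirical burn frequency. When ignitions are
subsampled (`sample` config), the denominator runs over the simulated
columns only, i.e. BP is conditional on the sampled ensemble.

**Normalizations.** OeR and MeR divide by the landscape maximum of the raw
product (the simplest mapping of "normalized to [0, 1]"; min–max could be
substituted in one place). All-zero surfaces stay all-zero rather than
dividing by zero. Every normalization constant used in a pipeline run is
written to `provenance.json`, because [0, 1] surfaces from different runs
are otherwise not comparable.

**Summaries.** Per-unit exceedance curves weight cells by the unit's
composition fraction (so mixed cells contribute partially), and threshold
areas count cells strictly above the threshold times the constant cell
area. Both are validated against exhaustive per-cell enumeration.

## Synthetic landscapes

`generate_landscape` assigns Voronoi patches of random seed points to
units greedily (largest patches first, toward target cover fractions) and
optionally blends boundaries with a (2w+1)-cell moving average, which
preserves per-cell mass and yields linearly mixed interface cells. With
the default patch grain (~36 cells per patch) realized per-unit cover
tracks the requested profile within ~6% relative across seeds. The
`nc_like` preset emulates a savanna-dominant matrix (32% target cover)
with embedded sclerophyll fragments and humid-forest blocks, 2% bare
residual, two roads and three villages; `two_unit_interface` builds the
sharp flammable-zero-loss vs non-flammable-high-loss testbed (boundary
position and FIP noise vary with the seed); `uniform` is the
single-unit, constant-FIP reduction testbed.

What the generator does *not* emulate: real geography and topography,
fuel-moisture dynamics, post-burn fuel change, seasonal ignition patterns,
and any statistical fit of ignition covariates. Passing tests therefore
demonstrate correctness of the computational chain and its invariants on
landscapes with the right broad structure — not predictive skill on any
real island. In particular the published island-scale headline figures
(e.g. hotspot areas of a few hundred km²) depend on the original
vegetation rasters and external fire/ignition models and are deliberately
out of scope; the procedures that would produce them (threshold areas,
per-unit exceedance curves) are implemented and verified against brute
force on synthetic data instead.

## Problem sizes and determinism

Default grids are 60×60 cells (desk scale; a full run with one fire per
burnable cell takes seconds). Everything downstream of a seed is
deterministic: the spread model is purely deterministic given its inputs,
and all stochastic generation flows through `numpy.random.default_rng`
seeded from the scenario seed. Fixed-seed pipeline runs are bit-identical,
which the test suite asserts on CSV and raster outputs.

## Known limitations

* The spread stand-in has no fire physics: no crown/surface distinction,
  no slope effect, no spotting; wind enters only through a bounded
  alignment factor.
* Vulnerability and diversity treat each unit as internally homogeneous;
  micro-endemism and species-level fire responses are not represented.
* Burn probability ignores land-cover change between fires (columns of
  the burnt-area matrix are independent replays).
* FIP surfaces are relative; absolute fire frequencies or return periods
  cannot be read off any output.
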