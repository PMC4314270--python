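# firebiorisk

Wildfire risk assessment for biodiversity on raster landscapes: per-vegetation-unit
diversity / vulnerability / biodiversity-loss indices, spatially explicit fire
simulation (a built-in stand-in spread model, or ingestion of external
FLAMMAP-style behavior grids), ignition-probability surfaces, and two risk
products — a **one-off event risk** per ignition cell and a **multi-event
(burn-probability) risk** per landscape cell.

The package is aimed at conservation and fire-management analysts who need to
rank where a fire would hurt biodiversity most (to prioritize prevention and
suppression), on landscapes described by a vegetation-unit attribute table and
fractional-composition rasters. It ships a synthetic landscape generator so the
whole pipeline is runnable and testable without any proprietary rasters.

## The model

For each vegetation unit *u* with species counts (TS, ES, SES: total, endemic,
unit-restricted endemic), landscape totals (TS_L, ES_L, SES_L), potential and
actual areas PS, AS (km²) and a time-to-recover coefficient Time ∈ [0, 1]:

    DVU_u = (a·TS_u/TS_L + b·ES_u/ES_L + c·SES_u/SES_L) / AS_u     (diversity, 1/km²)
    Vul_u = (PS_u / AS_u) · Time_u                                  (vulnerability)

On a grid of cells *i* (area S_i, composition ρ_iu):

    D_i   = S_i · Σ_u ρ_iu · DVU_u          DNC_i = D_i / Σ_j D_j   (Σ DNC = 1)
    Vul_i = Σ_u ρ_iu · Vul_u                BL_i  = DNC_i · Vul_i   (loss index)

Each simulated fire ignited at cell *j* yields a burnt area B_j with per-cell
fire-line intensity I (kW/m) and rate of spread RoS (m/min); severity is
Sev = I·(1/RoS). Risk surfaces:

    Oe_j  = Σ_{i∈B_j} BL_i        (optionally severity-weighted)   one-off impact
    OeR_j = FIP_j · Oe_j / max                                      one-off risk
    BAM_ij = 1 iff the fire ignited at j burned i                   burnt-area matrix
    BP_i  = Σ_j FIP_j·BAM_ij / Σ_j FIP_j                            burn probability
    MeR_i = BP_i · BL_i / max                                       multi-event risk

where FIP is the per-cell fire-ignition probability. BP is the classic
burn-probability ratio (times burned over number of simulated fires)
generalized to a nonuniform ignition distribution; it reduces to the classic
ratio exactly when FIP is uniform.

## Worked example

```python
import numpy as np
from firebiorisk import *
from firebiorisk.fire import SpreadModel

table = table1_fixture()                      # packaged unit attribute table
idx = compute_unit_indices(table)
print(f"sclerophyll: DVU={idx.diversity['sclerophyll']:.4g} /km2, "
      f"Vul={idx.vulnerability['sclerophyll']:.3g}, "
      f"BL={idx.biodiversity_loss['sclerophyll']:.3g}")

bundle = generate_scenario("nc_like", seed=42)          # 60x60 cells, 300 m
surf = compute_index_surfaces(bundle.landscape, table)
model = SpreadModel(bundle.landscape, bundle.fuel, bundle.weather)
fires = model.simulate_many(np.flatnonzero(model.burnable))

bam = build_bam(fires, bundle.landscape)
bp = burn_probability(bam, bundle.fip)                  # FIP-weighted
mer = multi_event_risk(bp, surf.biodiversity_loss.ravel())
oe = one_off_impact(fires, surf.biodiversity_loss.ravel())
oer = one_off_risk(oe, bundle.fip)
area, frac = threshold_area(mer, bundle.landscape, 0.02)
print(f"max BP={bp.max():.3f};  MeR>0.02 covers {area:.2f} km2 "
      f"({100*frac:.1f}% of the landscape)")
```

prints

```
sclerophyll: DVU=0.005256 /km2, Vul=15.8, BL=0.0833
max BP=0.200;  MeR>0.02 covers 15.21 km2 (4.7% of the landscape)
```

Sclerophyll forest — a small, species-rich, heavily regressed unit — has by far
the highest loss index (0.083 vs 0 for savanna), so the multi-event risk
hotspots (here 4.7% of a synthetic savanna-dominated landscape) concentrate on
and around its fragments, where burn probability driven by road-clustered
ignitions meets high potential loss.

The same pipeline is available from the shell:

```bash
firebiorisk synth --preset nc_like --seed 42 --out scen/
firebiorisk run --scenario-dir scen/ --seed 42 --out run/
```

which writes the index and risk rasters (`bl.asc`, `bp.asc`, `oer.asc`,
`mer.asc`, …), the per-unit index table, per-unit risk exceedance curves, and
threshold-area summaries with a provenance log of all normalization constants.

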