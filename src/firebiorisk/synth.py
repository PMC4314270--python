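"""Synthetic landscapes, fuels, ignition features and scenario bundles.

Real inputs for this kind of analysis are vegetation rasters, fuel maps
and ignition surfaces that cannot be redistributed. The generators here
produce co-registered stand-ins with the structural features the risk
method relies on:

* a mosaic of vegetation patches with sharp or blended interfaces
  (Voronoi seeds, optional linear boundary blending), including
  species-rich slow-recovery fragments embedded in a species-poor
  fast-recovery matrix;
* an ignition surface clustered along linear road features and around
  village points;
* a published vegetation-unit attribute table, packaged as a fixture in
  two variants (as printed, and with the two maquis SES entries swapped —
  the printed entries are mutually inconsistent and only the swapped
  variant reproduces the printed per-unit diversity values).

Everything is deterministic given ``(parameters, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .fire import FuelModel, WeatherScenario
from .ignition import FIPSurface, synth_fip
from .landscape import LandscapeGrid, UnitTable, read_unit_table

__all__ = [
    "ScenarioBundle",
    "table1_fixture",
    "generate_landscape",
    "make_roads",
    "make_villages",
    "default_fuel_model",
    "generate_scenario",
    "PRESETS",
]

BARE = "bare"  # pseudo-unit: unvegetated residual, dropped from composition

PRESETS = ("nc_like", "two_unit_interface", "uniform")

#: Stand-in fuel behavior per fixture unit: (base rate of spread m/min,
#: intensity coefficient kW/m per m/min). Grassy secondary formations
#: spread fast at moderate intensity; closed humid forest barely carries
#: fire but burns hot where it does.
_DEFAULT_FUEL = {
    "savanna": (25.0, 60.0),
    "maquis_mid_low": (10.0, 150.0),
    "maquis_high": (6.0, 150.0),
    "sclerophyll": (5.0, 250.0),
    "dhf_calcareous": (1.5, 300.0),
    "dhf_ultramafic": (1.5, 300.0),
    "dhf_sed_volcanic": (1.5, 300.0),
}

#: nc-like target cover fractions (savanna-dominant matrix with embedded
#: high-loss fragments; ~32% savanna, small sclerophyll relicts, 2% bare).
_NC_PROFILE = {
    "savanna": 0.32,
    "dhf_sed_volcanic": 0.20,
    "dhf_ultramafic": 0.16,
    "maquis_mid_low": 0.14,
    "dhf_calcareous": 0.08,
    "sclerophyll": 0.06,
    "maquis_high": 0.02,
    BARE: 0.02,
}


@dataclass
class ScenarioBundle:
    """All co-registered inputs for one pipeline run."""

    landscape: LandscapeGrid
    unit_table: UnitTable
    fuel: FuelModel
    weather: WeatherScenario
    fip: FIPSurface
    seed: int
    preset: str = "custom"
    roads: list[np.ndarray] = field(default_factory=list)
    villages: list[tuple[int, int]] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> Path:
        """Write every component in the formats the other modules read."""
        import json

        from .landscape import write_composition_grid, write_unit_table
        from .ignition import write_fip

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_composition_grid(self.landscape, out_dir / "composition")
        write_unit_table(self.unit_table, out_dir / "units.csv")
        write_fip(self.fip, out_dir / "fip.asc", cellsize=self.landscape.cell_size)
        with open(out_dir / "fuel.json", "w") as fh:
            json.dump(
                {
                    "base_ros": self.fuel.base_ros,
                    "intensity_coeff": self.fuel.intensity_coeff,
                    "flammable": self.fuel.flammable,
                },
                fh,
                indent=2,
            )
        with open(out_dir / "scenario.json", "w") as fh:
            json.dump(
                {
                    "preset": self.preset,
                    "seed": self.seed,
                    "cell_size": self.landscape.cell_size,
                    "weather": {
                        "wind_speed": self.weather.wind_speed,
                        "wind_direction": self.weather.wind_direction,
                        "moisture_factor": self.weather.moisture_factor,
                    },
                    "villages": [list(v) for v in self.villages],
                    "roads": [r.tolist() for r in self.roads],
                },
                fh,
            )
        return out_dir


# ---------------------------------------------------------------------------
# packaged fixture


def table1_fixture(variant: str = "ses_swapped") -> UnitTable:
    """The packaged vegetation-unit attribute table (7 leaf units).

    ``variant="as_printed"`` is the table exactly as published, including
    its internally inconsistent maquis SES entries (the high-altitude row
    prints SES=242 > TS=200). ``"ses_swapped"`` exchanges the two maquis
    SES values (21 ↔ 242), the variant under which the published per-unit
    diversity values are reproduced. Totals are the published landscape
    totals (3260, 2412, 1437) in both variants.
    """
    if variant not in ("as_printed", "ses_swapped"):
        raise ValueError(f"unknown variant {variant!r}")
    ref = resources.files("firebiorisk.data") / f"table1_{variant}.csv"
    with resources.as_file(ref) as path:
        import warnings

        with warnings.catch_warnings():
            # the as_printed variant knowingly violates SES <= TS
            warnings.simplefilter("ignore")
            return read_unit_table(path)


# ---------------------------------------------------------------------------
# landscape generator


def generate_landscape(
    nrows: int,
    ncols: int,
    n_patches: int,
    unit_mix_profile: Mapping[str, float],
    interface_width: int = 1,
    seed: int | None = None,
    *,
    cell_size: float = 300.0,
) -> LandscapeGrid:
    """Voronoi-seeded vegetation mosaic with blended interfaces.

    ``unit_mix_profile`` maps unit ids to target cover fractions (summing
    to at most 1; the key ``"bare"`` or any shortfall is unvegetated).
    Patches are Voronoi cells of ``n_patches`` random seed points; each
    patch is assigned one unit so that realized areas track the profile
    (largest patches first, greedy on the remaining deficit). With
    ``interface_width > 0`` each composition layer is smoothed with a
    ``(2w+1)``-cell moving average, producing linearly mixed cells along
    patch boundaries; ``interface_width = 0`` keeps every cell pure.
    """
    if nrows < 4 or ncols < 4:
        raise ValueError("grid dimensions must be at least 4")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    fracs = dict(unit_mix_profile)
    if any(f < 0 for f in fracs.values()):
        raise ValueError("cover fractions must be >= 0")
    total = sum(fracs.values())
    if total > 1 + 1e-9:
        raise ValueError(f"cover fractions sum to {total} > 1")
    if total < 1 - 1e-9:
        fracs[BARE] = fracs.get(BARE, 0.0) + (1 - total)

    rng = np.random.default_rng(seed)
    seeds = rng.uniform([0, 0], [nrows, ncols], size=(n_patches, 2))
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    pts = np.stack([rr.ravel() + 0.5, cc.ravel() + 0.5], axis=1)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    patch_of = d2.argmin(axis=1)  # (n_cells,)

    # greedy unit assignment: biggest patches first, fill the unit with
    # the largest remaining cell deficit
    patch_sizes = np.bincount(patch_of, minlength=n_patches)
    labels = list(fracs)
    n_cells = nrows * ncols
    deficit = {u: fracs[u] * n_cells for u in labels}
    patch_unit: dict[int, str] = {}
    for p in np.argsort(-patch_sizes, kind="stable"):
        u = max(labels, key=lambda k: deficit[k])
        patch_unit[int(p)] = u
        deficit[u] -= patch_sizes[p]

    unit_ids = [u for u in labels if u != BARE]
    layers = np.zeros((len(labels), nrows, ncols))
    cell_unit = np.array([labels.index(patch_unit[int(p)]) for p in patch_of])
    layers[cell_unit, pts[:, 0].astype(int), pts[:, 1].astype(int)] = 1.0

    if interface_width > 0:
        size = 2 * int(interface_width) + 1
        layers = np.stack(
            [uniform_filter(l, size=size, mode="nearest") for l in layers]
        )
        layers = np.clip(layers, 0.0, None)  # moving average can under/overshoot by ~1e-16
    comp = layers[[labels.index(u) for u in unit_ids]]
    return LandscapeGrid(
        unit_ids=tuple(unit_ids), composition=comp, cell_size=cell_size
    )


# ---------------------------------------------------------------------------
# roads and villages


def _line_cells(r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
    """8-connected raster line between two cells, inclusive."""
    n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
    rows = np.rint(np.linspace(r0, r1, n)).astype(int)
    cols = np.rint(np.linspace(c0, c1, n)).astype(int)
    return np.unique(np.stack([rows, cols], axis=1), axis=0)


def make_roads(
    nrows: int, ncols: int, n_roads: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random border-to-border polylines (arrays of (row, col) cells)."""
    roads = []
    for _ in range(n_roads):
        if rng.random() < 0.5:  # roughly west-east
            r0, r1 = rng.integers(0, nrows, size=2)
            roads.append(_line_cells(int(r0), 0, int(r1), ncols - 1))
        else:  # roughly north-south
            c0, c1 = rng.integers(0, ncols, size=2)
            roads.append(_line_cells(0, int(c0), nrows - 1, int(c1)))
    return roads


def make_villages(
    roads: Sequence[np.ndarray],
    n_villages: int,
    rng: np.random.Generator,
    shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Village cells scattered within two cells of a random road cell."""
    if not roads:
        return []
    allcells = np.concatenate([np.asarray(r) for r in roads])
    out = []
    for _ in range(n_villages):
        r, c = allcells[rng.integers(0, len(allcells))]
        r = int(np.clip(r + rng.integers(-2, 3), 0, shape[0] - 1))
        c = int(np.clip(c + rng.integers(-2, 3), 0, shape[1] - 1))
        out.append((r, c))
    return out


def default_fuel_model(
    unit_ids: Sequence[str], non_flammable: Sequence[str] = ()
) -> FuelModel:
    """Stand-in fuel parameters for the fixture units (see module notes)."""
    base_ros, coeff, flam = {}, {}, {}
    for u in unit_ids:
        r, c = _DEFAULT_FUEL.get(u, (8.0, 150.0))
        base_ros[u] = 0.0 if u in non_flammable else r
        coeff[u] = c
        if u in non_flammable:
            flam[u] = False
    return FuelModel(base_ros=base_ros, intensity_coeff=coeff, flammable=flam)


# ---------------------------------------------------------------------------
# scenario presets


def generate_scenario(
    preset: str, seed: int, *, nrows: int = 60, ncols: int = 60
) -> ScenarioBundle:
    """Build a complete, co-registered scenario bundle.

    Presets
    -------
    ``nc_like``
        Savanna-dominant mosaic (~32% cover) with embedded sclerophyll
        fragments and humid-forest blocks (swapped-SES fixture table),
        blended interfaces, road/village-clustered ignition surface,
        moderate trade wind.
    ``two_unit_interface``
        Sharp vertical boundary between a flammable zero-loss unit
        (savanna) and a non-flammable high-loss unit (sclerophyll); near-
        uniform ignition surface. The testbed for interface risk.
    ``uniform``
        Single flammable unit everywhere, constant ignition surface, calm
        weather. The testbed where FIP weighting must reduce to the
        classic burn-probability ratio.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {PRESETS}")
    rng = np.random.default_rng(seed)
    table = table1_fixture("ses_swapped")

    if preset == "uniform":
        comp = np.ones((1, nrows, ncols))
        grid = LandscapeGrid(unit_ids=("savanna",), composition=comp)
        fuel = default_fuel_model(["savanna"])
        weather = WeatherScenario()
        fip = FIPSurface(values=np.ones((nrows, ncols)))
        return ScenarioBundle(grid, table, fuel, weather, fip, seed, preset)

    if preset == "two_unit_interface":
        boundary = ncols // 2 + int(rng.integers(-2, 3))
        comp = np.zeros((2, nrows, ncols))
        comp[0, :, :boundary] = 1.0  # savanna (flammable, zero loss)
        comp[1, :, boundary:] = 1.0  # sclerophyll (non-flammable, high loss)
        grid = LandscapeGrid(unit_ids=("savanna", "sclerophyll"), composition=comp)
        fuel = default_fuel_model(
            ["savanna", "sclerophyll"], non_flammable=["sclerophyll"]
        )
        weather = WeatherScenario()
        noise = rng.lognormal(mean=0.0, sigma=0.1, size=(nrows, ncols))
        fip = FIPSurface(values=noise / noise.max())
        return ScenarioBundle(grid, table, fuel, weather, fip, seed, preset)

    # nc_like
    bad = [u for u in _NC_PROFILE if u != BARE and u not in table]
    if bad:
        raise ValueError(f"profile references unknown units {bad}")
    grid = generate_landscape(
        nrows,
        ncols,
        n_patches=max(8, (nrows * ncols) // 36),
        unit_mix_profile=_NC_PROFILE,
        interface_width=1,
        seed=int(rng.integers(2**31)),
    )
    roads = make_roads(nrows, ncols, n_roads=2, rng=rng)
    villages = make_villages(roads, n_villages=3, rng=rng, shape=(nrows, ncols))
    fip = synth_fip(grid, roads, villages)
    fuel = default_fuel_model(grid.unit_ids)
    weather = WeatherScenario(wind_speed=5.0, wind_direction=110.0, moisture_factor=0.8)
    return ScenarioBundle(
        grid, table, fuel, weather, fip, seed, preset, roads=roads, villages=villages
    )
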