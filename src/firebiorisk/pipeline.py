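"""End-to-end pipeline: scenario -> indices -> fires -> risk surfaces.

A run is a pure function of its configuration and seed. Every run
directory receives the resolved configuration, all index and risk
rasters, the per-unit index table, per-unit exceedance curves, threshold
areas, and a provenance log recording versions, the seed, and every
normalization constant applied (needed to interpret the [0, 1] surfaces
across runs).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .biodiversity import DiversityWeights, compute_index_surfaces, compute_unit_indices
from .fire import FuelModel, SpreadModel, WeatherScenario, DEFAULT_MAX_DURATION_MIN
from .ignition import FIPSurface, read_fip
from .landscape import LandscapeGrid, read_composition_grid, read_unit_table, write_surface
from .risk import (
    BP_METHODS,
    OE_MODES,
    build_bam,
    burn_probability,
    multi_event_risk,
    one_off_impact,
    one_off_risk,
    risk_cdf_by_unit,
    threshold_area,
)
from .synth import PRESETS, ScenarioBundle, generate_scenario

__all__ = ["RunConfig", "run_pipeline", "report_table1", "load_scenario_dir"]

log = logging.getLogger("firebiorisk")


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    # inputs: either a synthetic preset, or a scenario directory on disk
    preset: Literal["nc_like", "two_unit_interface", "uniform"] | None = None
    scenario_dir: str | None = None
    nrows: int = 60
    ncols: int = 60

    # index stage
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    # fire stage
    max_duration: float = DEFAULT_MAX_DURATION_MIN
    max_cells: int | None = None
    leak_into_nonflammable: bool = False
    sample: int | None = Field(
        default=None,
        description="simulate at most this many ignition cells (seeded subsample); "
        "default: one fire per burnable cell",
    )

    # risk stage
    oe_mode: Literal["sum_bl", "severity_weighted"] = "severity_weighted"
    bp_method: Literal["fip_weighted", "uniform"] = "fip_weighted"
    thresholds: list[float] = [1e-3, 1e-2, 2e-2, 1e-1, 0.16]

    out_dir: str = "firebiorisk_run"
    seed: int = 0

    @model_validator(mode="after")
    def _check_inputs(self):
        if (self.preset is None) == (self.scenario_dir is None):
            raise ValueError("exactly one of 'preset' and 'scenario_dir' must be set")
        return self


def load_scenario_dir(path: str | Path) -> ScenarioBundle:
    """Load a scenario bundle written by :meth:`ScenarioBundle.write`."""
    path = Path(path)
    with open(path / "scenario.json") as fh:
        meta = json.load(fh)
    with open(path / "fuel.json") as fh:
        fuel_d = json.load(fh)
    comp_dir = path / "composition"
    layers = {p.stem.removeprefix("comp_"): p for p in sorted(comp_dir.glob("comp_*.asc"))}
    grid = read_composition_grid(layers, cell_size=meta.get("cell_size"))
    table = read_unit_table(path / "units.csv")
    fip = read_fip(path / "fip.asc", grid)
    return ScenarioBundle(
        landscape=grid,
        unit_table=table,
        fuel=FuelModel(
            base_ros=fuel_d["base_ros"],
            intensity_coeff=fuel_d["intensity_coeff"],
            flammable=fuel_d.get("flammable", {}),
        ),
        weather=WeatherScenario(**meta["weather"]),
        fip=fip,
        seed=meta.get("seed", 0),
        preset=meta.get("preset", "custom"),
        roads=[np.asarray(r) for r in meta.get("roads", [])],
        villages=[tuple(v) for v in meta.get("villages", [])],
    )


def report_table1(
    table, weights: DiversityWeights = DiversityWeights(), sig_figs: int = 2
) -> pd.DataFrame:
    """Per-unit index table: full-precision columns plus rounded display columns."""
    idx = compute_unit_indices(table, weights)

    def _round_sig(x: float, n: int) -> float:
        if x == 0:
            return 0.0
        return float(f"{x:.{n}g}")

    rows = []
    for u in table.units:
        d = idx.diversity[u.unit_id]
        v = idx.vulnerability[u.unit_id]
        rows.append(
            {
                "unit_id": u.unit_id,
                "name": u.name,
                "diversity": d,
                "vulnerability": v,
                "biodiversity_loss": d * v,
                "diversity_rounded": _round_sig(d, sig_figs),
                "vulnerability_rounded": _round_sig(v, sig_figs),
                "biodiversity_loss_rounded": _round_sig(d * v, sig_figs),
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    prov: dict = {"version": __version__, "seed": config.seed, "normalization": {}}
    t0 = time.perf_counter()

    # --- inputs ----------------------------------------------------------
    try:
        if config.preset is not None:
            bundle = generate_scenario(
                config.preset, config.seed, nrows=config.nrows, ncols=config.ncols
            )
        else:
            bundle = load_scenario_dir(config.scenario_dir)
    except Exception as e:
        raise RuntimeError(f"stage 'inputs' failed: {e}") from e
    grid, fip = bundle.landscape, bundle.fip
    t0 = _stage("inputs", t0)

    # --- indices ---------------------------------------------------------
    try:
        weights = DiversityWeights(*config.weights)
        surf = compute_index_surfaces(grid, bundle.unit_table, weights)
        report_table1(bundle.unit_table, weights).to_csv(out / "unit_indices.csv", index=False)
        for name, vals in (
            ("d", surf.diversity),
            ("dnc", surf.diversity_normalized),
            ("vul", surf.vulnerability),
            ("bl", surf.biodiversity_loss),
        ):
            write_surface(grid, vals, out / f"{name}.asc")
        prov["normalization"]["diversity_total"] = float(surf.diversity.sum())
    except Exception as e:
        raise RuntimeError(f"stage 'indices' failed: {e}") from e
    t0 = _stage("indices", t0)

    # --- fires -----------------------------------------------------------
    try:
        model = SpreadModel(
            grid,
            bundle.fuel,
            bundle.weather,
            max_duration=config.max_duration,
            max_cells=config.max_cells,
            leak_into_nonflammable=config.leak_into_nonflammable,
        )
        ignitions = np.flatnonzero(model.burnable)
        if config.sample is not None and config.sample < ignitions.size:
            rng = np.random.default_rng(config.seed)
            ignitions = np.sort(rng.choice(ignitions, size=config.sample, replace=False))
        fires = model.simulate_many(ignitions)
        pd.DataFrame(
            {
                "fire_id": np.arange(len(fires)),
                "ignition_row": [f.ignition_cell // grid.ncols for f in fires],
                "ignition_col": [f.ignition_cell % grid.ncols for f in fires],
                "n_burnt": [f.n_burnt for f in fires],
            }
        ).to_csv(out / "fires.csv", index=False)
        prov["n_fires"] = len(fires)
    except Exception as e:
        raise RuntimeError(f"stage 'fires' failed: {e}") from e
    t0 = _stage("fires", t0)

    # --- risk ------------------------------------------------------------
    try:
        bl = surf.biodiversity_loss.ravel()
        oe = one_off_impact(fires, bl, mode=config.oe_mode)
        raw_oer = fip.flat() * oe
        prov["normalization"]["oer_max"] = float(np.nanmax(raw_oer))
        oer = one_off_risk(oe, fip)

        bam = build_bam(fires, grid)
        bp = burn_probability(bam, fip, method=config.bp_method)
        prov["normalization"]["mer_max"] = float((bp * bl).max())
        mer = multi_event_risk(bp, bl)

        for name, vals in (("oe", oe), ("oer", oer), ("bp", bp), ("mer", mer)):
            write_surface(grid, vals, out / f"{name}.asc")

        cdf = pd.concat(
            [
                risk_cdf_by_unit(mer, grid, config.thresholds).assign(risk="multi_event"),
                risk_cdf_by_unit(oer, grid, config.thresholds).assign(risk="one_off"),
            ]
        )
        cdf.to_csv(out / "risk_cdf.csv", index=False)

        summary = {}
        for rname, vals in (("multi_event", mer), ("one_off", oer)):
            summary[rname] = [
                {
                    "threshold": t,
                    "area_km2": a,
                    "landscape_fraction": f,
                }
                for t in config.thresholds
                for a, f in [threshold_area(vals, grid, t)]
            ]
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as e:
        raise RuntimeError(f"stage 'risk' failed: {e}") from e
    t0 = _stage("risk", t0)

    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    return out
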