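"""Stand-in fire spread, fire-behavior grid I/O, and the severity index.

The spread model is a deliberately simple minimum-travel-time scheme on
the 8-neighbour cell graph: the travel time along an edge is the edge
length divided by an effective rate of spread, and every cell reached
within a duration budget burns. The effective rate of spread of a cell is
the composition-weighted mean of the unit base rates (so sparse or mixed
fuel spreads slowly), scaled by a moisture multiplier and a wind-alignment
factor that favours downwind edges. Fire-line intensity in a cell is
proportional to the rate of spread there.

This model exists so the whole risk pipeline runs without external fire
behavior software; it makes no claim to model real fire physics. Grids
produced by an external simulator can be ingested instead through
:func:`read_fire_grids`.

Severity of a burnt cell is fire-line intensity times residence time,
``Sev = I / RoS``, with residence time taken as the reciprocal of the rate
of spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .landscape import LandscapeGrid, read_ascii_grid, write_ascii_grid

__all__ = [
    "FuelModel",
    "WeatherScenario",
    "FireResult",
    "SpreadModel",
    "simulate_fire",
    "severity",
    "write_fire_grids",
    "read_fire_grids",
    "DEFAULT_MAX_DURATION_MIN",
]

#: Default spread duration budget (minutes). Calibrated once so the median
#: fire burns about 50 cells on the default synthetic landscape.
DEFAULT_MAX_DURATION_MIN = 165.0


@dataclass(frozen=True)
class FuelModel:
    """Per-unit fuel behavior at reference (no-wind, dry) conditions.

    ``base_ros`` is the rate of spread in m/min; ``intensity_coeff`` links
    rate of spread to fire-line intensity (kW/m per m/min). Units absent
    from ``flammable`` default to flammable iff their base rate is
    positive. Non-flammable units never ignite or carry fire.
    """

    base_ros: dict[str, float]
    intensity_coeff: dict[str, float]
    flammable: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, r in self.base_ros.items():
            if r < 0:
                raise ValueError(f"unit {u!r}: base_ros must be >= 0, got {r}")
        for u, c in self.intensity_coeff.items():
            if c < 0:
                raise ValueError(f"unit {u!r}: intensity_coeff must be >= 0, got {c}")

    def is_flammable(self, unit_id: str) -> bool:
        if unit_id in self.flammable:
            return self.flammable[unit_id]
        return self.base_ros.get(unit_id, 0.0) > 0


@dataclass(frozen=True)
class WeatherScenario:
    """Wind and moisture driving one simulation run.

    ``wind_direction`` is the meteorological bearing the wind blows *from*
    (degrees clockwise from north); spread is enhanced on the opposite,
    downwind bearing. ``moisture_factor`` in (0, 1] multiplies all rates
    of spread (1 = reference dry conditions).
    """

    wind_speed: float = 0.0  # m/s
    wind_direction: float = 0.0  # degrees from north, wind origin
    moisture_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.wind_speed < 0:
            raise ValueError(f"wind_speed must be >= 0, got {self.wind_speed}")
        if not 0 <= self.wind_direction < 360:
            raise ValueError(f"wind_direction must lie in [0, 360), got {self.wind_direction}")
        if not 0 < self.moisture_factor <= 1:
            raise ValueError(f"moisture_factor must lie in (0, 1], got {self.moisture_factor}")


@dataclass(frozen=True)
class FireResult:
    """One fire: the burnt-cell set and per-cell behavior.

    ``burnt_cells`` are flat row-major cell indices (sorted); ``intensity``
    (kW/m) and ``ros`` (m/min) align with it. A degenerate fire from a
    non-flammable ignition has a single burnt cell with zero intensity and
    rate of spread.
    """

    ignition_cell: int
    burnt_cells: np.ndarray
    intensity: np.ndarray
    ros: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "burnt_cells", np.asarray(self.burnt_cells, dtype=np.int64))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        object.__setattr__(self, "ros", np.asarray(self.ros, dtype=float))
        n = self.burnt_cells.size
        if self.intensity.shape != (n,) or self.ros.shape != (n,):
            raise ValueError("intensity and ros must align with burnt_cells")
        if self.ignition_cell not in self.burnt_cells:
            raise ValueError(
                f"ignition cell {self.ignition_cell} not in burnt set (|B|={n})"
            )
        n_cells = self.shape[0] * self.shape[1]
        if n and (self.burnt_cells.min() < 0 or self.burnt_cells.max() >= n_cells):
            raise ValueError("burnt cells fall outside the landscape")

    @property
    def n_burnt(self) -> int:
        return int(self.burnt_cells.size)

    def to_surface(self, values: np.ndarray | None = None, fill: float = 0.0) -> np.ndarray:
        """Scatter per-burnt-cell values onto a full (nrows, ncols) grid."""
        out = np.full(self.shape[0] * self.shape[1], fill, dtype=float)
        out[self.burnt_cells] = self.ros if values is None else np.asarray(values, dtype=float)
        return out.reshape(self.shape)


# 8-neighbour offsets (drow, dcol)
_NEIGHBOURS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)], dtype=int
)


class SpreadModel:
    """Precomputed travel-time graph for one landscape/fuel/weather triple.

    Building the directed 8-neighbour graph once makes simulating a fire
    from every candidate ignition cell cheap (one multi-source Dijkstra
    sweep in compiled code).

    Parameters
    ----------
    grid, fuel, weather :
        The landscape and the conditions; see the respective classes.
    max_duration :
        Spread duration budget in minutes; cells reached within it burn.
    max_cells :
        Optional hard cap on burnt cells (earliest arrivals kept).
    leak_into_nonflammable :
        When true, non-flammable vegetated cells 8-adjacent to the burnt
        patch are scorched too (they burn at ``leak_ros`` but never carry
        fire onward). This models understorey/edge damage at vegetation
        interfaces.
    """

    def __init__(
        self,
        grid: LandscapeGrid,
        fuel: FuelModel,
        weather: WeatherScenario = WeatherScenario(),
        *,
        max_duration: float = DEFAULT_MAX_DURATION_MIN,
        max_cells: int | None = None,
        leak_into_nonflammable: bool = False,
        leak_ros: float = 0.5,
    ) -> None:
        if max_duration <= 0:
            raise ValueError("max_duration must be positive")
        self.grid = grid
        self.fuel = fuel
        self.weather = weather
        self.max_duration = float(max_duration)
        self.max_cells = max_cells
        self.leak_into_nonflammable = leak_into_nonflammable
        self.leak_ros = float(leak_ros)

        comp = grid.composition_flat()  # (n_units, n_cells)
        ros_w = np.array(
            [fuel.base_ros.get(u, 0.0) if fuel.is_flammable(u) else 0.0 for u in grid.unit_ids]
        )
        coeff_w = np.array([fuel.intensity_coeff.get(u, 0.0) for u in grid.unit_ids])
        flam_w = np.array([1.0 if fuel.is_flammable(u) else 0.0 for u in grid.unit_ids])

        #: per-cell effective rate of spread (m/min), moisture applied
        self.cell_ros = (ros_w @ comp) * weather.moisture_factor
        #: per-cell intensity coefficient (kW/m per m/min), all units count
        self.cell_coeff = coeff_w @ comp
        #: per-cell flammable cover fraction
        self.flammable_fraction = flam_w @ comp
        self.burnable = (self.flammable_fraction > 0) & (self.cell_ros > 0)

        self._graph = self._build_graph()

    # -- graph ------------------------------------------------------------
    def _wind_alignment(self, bearing_deg: np.ndarray) -> np.ndarray:
        """Alignment factor for spread along a compass bearing.

        ``1 + w·cos(bearing − downwind)`` clipped to at least 0.1, with
        ``w = wind_speed / (wind_speed + 10)``: bounded, dimensionless,
        monotone in wind speed, and 1 everywhere under calm conditions.
        """
        w = self.weather.wind_speed / (self.weather.wind_speed + 10.0)
        downwind = (self.weather.wind_direction + 180.0) % 360.0
        align = 1.0 + w * np.cos(np.deg2rad(bearing_deg - downwind))
        return np.maximum(align, 0.1)

    def _build_graph(self) -> sp.csr_matrix:
        nrows, ncols = self.grid.shape
        n = nrows * ncols
        cs = self.grid.cell_size
        rows_idx, cols_idx = np.divmod(np.arange(n), ncols)
        src_list, dst_list, t_list = [], [], []
        for drow, dcol in _NEIGHBOURS:
            r2 = rows_idx + drow
            c2 = cols_idx + dcol
            ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
            src = np.arange(n)[ok]
            dst = r2[ok] * ncols + c2[ok]
            ok2 = self.burnable[src] & self.burnable[dst]
            src, dst = src[ok2], dst[ok2]
            if src.size == 0:
                continue
            dist = cs * float(np.hypot(drow, dcol))
            # bearing of the step, degrees clockwise from north
            bearing = np.rad2deg(np.arctan2(dcol, -drow)) % 360.0
            speed = 0.5 * (self.cell_ros[src] + self.cell_ros[dst])
            speed = speed * self._wind_alignment(np.full(src.size, bearing))
            src_list.append(src)
            dst_list.append(dst)
            t_list.append(dist / speed)
        if not src_list:
            return sp.csr_matrix((n, n))
        return sp.csr_matrix(
            (np.concatenate(t_list), (np.concatenate(src_list), np.concatenate(dst_list))),
            shape=(n, n),
        )

    # -- simulation -------------------------------------------------------
    def _resolve_cell(self, ignition) -> int:
        if isinstance(ignition, tuple):
            return self.grid.flat(*ignition)
        return int(ignition)

    def simulate(self, ignition) -> FireResult:
        """Spread one fire from an ignition cell (flat index or (row, col))."""
        return self.simulate_many([ignition])[0]

    def simulate_many(self, ignitions: Sequence) -> list[FireResult]:
        """Spread one fire per ignition cell; one Dijkstra sweep per chunk."""
        cells = np.array([self._resolve_cell(j) for j in ignitions], dtype=np.int64)
        out: list[FireResult] = []
        chunk = 512
        for lo in range(0, cells.size, chunk):
            sub = cells[lo : lo + chunk]
            live = sub[self.burnable[sub]]
            if live.size:
                dist, pred = dijkstra(
                    self._graph,
                    directed=True,
                    indices=live,
                    limit=self.max_duration,
                    return_predecessors=True,
                )
                live_results = {
                    int(j): self._collect(int(j), dist[k], pred[k]) for k, j in enumerate(live)
                }
            else:
                live_results = {}
            for j in sub:
                j = int(j)
                if j in live_results:
                    out.append(live_results[j])
                else:
                    warnings.warn(
                        f"ignition cell {j} is not flammable; returning a degenerate fire",
                        stacklevel=2,
                    )
                    out.append(
                        FireResult(
                            ignition_cell=j,
                            burnt_cells=np.array([j]),
                            intensity=np.zeros(1),
                            ros=np.zeros(1),
                            shape=self.grid.shape,
                        )
                    )
        return out

    def _collect(self, j: int, dist: np.ndarray, pred: np.ndarray) -> FireResult:
        burnt = np.flatnonzero(np.isfinite(dist))
        if self.max_cells is not None and burnt.size > self.max_cells:
            order = np.argsort(dist[burnt], kind="stable")
            burnt = np.sort(burnt[order[: self.max_cells]])
        # arrival rate of spread: speed along the first-arrival edge
        ros = np.empty(burnt.size)
        p = pred[burnt]
        root = p < 0  # the ignition cell itself
        ros[root] = self.cell_ros[burnt[root]]
        if (~root).any():
            b, pp = burnt[~root], p[~root].astype(np.int64)
            r1, c1 = np.divmod(pp, self.grid.ncols)
            r2, c2 = np.divmod(b, self.grid.ncols)
            step = self.grid.cell_size * np.hypot(r2 - r1, c2 - c1)
            ros[~root] = step / (dist[b] - dist[pp])
        intensity = self.cell_coeff[burnt] * ros
        if self.leak_into_nonflammable:
            burnt, intensity, ros = self._apply_leakage(burnt, intensity, ros)
        return FireResult(
            ignition_cell=j,
            burnt_cells=burnt,
            intensity=intensity,
            ros=ros,
            shape=self.grid.shape,
        )

    def _apply_leakage(self, burnt, intensity, ros):
        """Scorch vegetated non-flammable cells adjacent to the burnt patch."""
        nrows, ncols = self.grid.shape
        veg = self.grid.vegetated_fraction().ravel()
        r, c = np.divmod(burnt, ncols)
        cand: set[int] = set()
        for drow, dcol in _NEIGHBOURS:
            r2, c2 = r + drow, c + dcol
            ok = (r2 >= 0) & (r2 < nrows) & (c2 >= 0) & (c2 < ncols)
            cand.update((r2[ok] * ncols + c2[ok]).tolist())
        cand -= set(burnt.tolist())
        leak = np.array(
            sorted(
                i
                for i in cand
                if not self.burnable[i] and veg[i] > 0 and self.cell_coeff[i] > 0
            ),
            dtype=np.int64,
        )
        if leak.size == 0:
            return burnt, intensity, ros
        leak_ros = np.full(leak.size, self.leak_ros)
        leak_int = self.cell_coeff[leak] * leak_ros
        order = np.argsort(np.concatenate([burnt, leak]), kind="stable")
        allb = np.concatenate([burnt, leak])[order]
        return (
            allb,
            np.concatenate([intensity, leak_int])[order],
            np.concatenate([ros, leak_ros])[order],
        )


def simulate_fire(
    grid: LandscapeGrid,
    fuel: FuelModel,
    weather: WeatherScenario,
    ignition,
    *,
    max_duration: float = DEFAULT_MAX_DURATION_MIN,
    max_cells: int | None = None,
    leak_into_nonflammable: bool = False,
    leak_ros: float = 0.5,
    seed: int | None = None,
) -> FireResult:
    """One-shot convenience wrapper around :class:`SpreadModel`.

    The model is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic generators and ignored.
    """
    model = SpreadModel(
        grid,
        fuel,
        weather,
        max_duration=max_duration,
        max_cells=max_cells,
        leak_into_nonflammable=leak_into_nonflammable,
        leak_ros=leak_ros,
    )
    return model.simulate(ignition)


# ---------------------------------------------------------------------------
# severity


def severity(fire: FireResult) -> np.ndarray:
    """Severity per burnt cell: Sev = I · (1/RoS), aligned with B_j.

    Residence time is the reciprocal rate of spread, so a zero rate on a
    burnt cell makes severity undefined and raises ``ValueError``.
    """
    if fire.n_burnt and (fire.ros <= 0).any():
        bad = fire.burnt_cells[fire.ros <= 0][0]
        raise ValueError(
            f"rate of spread is zero on burnt cell {int(bad)}: residence time undefined"
        )
    return fire.intensity / fire.ros


# ---------------------------------------------------------------------------
# external fire-grid I/O (FLAMMAP-style paired rasters)


def write_fire_grids(
    fire: FireResult,
    grid: LandscapeGrid,
    out_dir: str | Path,
    fire_id: int | str,
) -> tuple[Path, Path]:
    """Write paired ``fire_<id>_intensity.asc`` / ``fire_<id>_ros.asc`` grids.

    Unburnt cells are written as 0 (the convention the reader inverts:
    burnt cells are those with positive rate of spread).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = dict(cellsize=grid.cell_size, xllcorner=grid.xllcorner, yllcorner=grid.yllcorner)
    ipath = out_dir / f"fire_{fire_id}_intensity.asc"
    rpath = out_dir / f"fire_{fire_id}_ros.asc"
    write_ascii_grid(fire.to_surface(fire.intensity), ipath, **meta)
    write_ascii_grid(fire.to_surface(fire.ros), rpath, **meta)
    return ipath, rpath


def read_fire_grids(
    intensity_path: str | Path,
    ros_path: str | Path,
    *,
    ignition: int | tuple[int, int] | None = None,
) -> FireResult:
    """Rebuild a :class:`FireResult` from paired intensity / RoS rasters.

    Burnt cells are those with positive rate of spread. The ignition cell
    is taken as given, or inferred as the maximum-intensity cell when
    omitted. A positive rate with non-positive intensity is a data error.
    """
    inten, _ = read_ascii_grid(intensity_path)
    ros, _ = read_ascii_grid(ros_path)
    if inten.shape != ros.shape:
        raise ValueError(
            f"grid mismatch: intensity {inten.shape} vs ros {ros.shape} "
            f"({intensity_path} / {ros_path})"
        )
    shape = ros.shape
    inten = np.nan_to_num(inten.ravel(), nan=0.0)
    ros = np.nan_to_num(ros.ravel(), nan=0.0)
    burnt = np.flatnonzero(ros > 0)
    bad = burnt[inten[burnt] <= 0]
    if bad.size:
        raise ValueError(
            f"cell {int(bad[0])}: positive rate of spread with non-positive intensity"
        )
    if isinstance(ignition, tuple):
        ignition = ignition[0] * shape[1] + ignition[1]
    if burnt.size == 0:
        warnings.warn("all-zero rate-of-spread grid: empty fire", stacklevel=2)
        j = int(ignition) if ignition is not None else 0
        return FireResult(
            ignition_cell=j,
            burnt_cells=np.array([j]),
            intensity=np.zeros(1),
            ros=np.zeros(1),
            shape=shape,
        )
    if ignition is None:
        ignition = int(burnt[np.argmax(inten[burnt])])
    return FireResult(
        ignition_cell=int(ignition),
        burnt_cells=burnt,
        intensity=inten[burnt],
        ros=ros[burnt],
        shape=shape,
    )
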