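"""Vegetation-unit tables and fractional-composition grids.

The landscape is a regular grid of square cells (default 300 m). Each cell
carries a fractional composition ``rho[u, r, c]`` over a set of vegetation
units; the residual ``1 - sum_u rho`` is the unvegetated class (bare soil,
clouds, buildings). Cells are addressed either by ``(row, col)`` with row 0
the northernmost row, or by a flat row-major index ``i = row * ncols + col``.

Rasters are read and written as ESRI ASCII grids (``.asc``) — a plain-text
format with a six-line header (``ncols/nrows/xllcorner/yllcorner/cellsize/
NODATA_value``) followed by whitespace-separated values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VegetationUnit",
    "UnitTable",
    "LandscapeGrid",
    "UnitTableSchemaError",
    "read_unit_table",
    "write_unit_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_composition_grid",
    "write_composition_grid",
    "write_surface",
    "read_surface",
]

#: Tolerance on per-cell composition sums exceeding 1.
COMPOSITION_EPS = 1e-6

UNIT_TABLE_COLUMNS = (
    "unit_id",
    "name",
    "potential_area_km2",
    "actual_area_km2",
    "time_to_recover",
    "total_species",
    "endemic_species",
    "specific_endemic_species",
)


class UnitTableSchemaError(ValueError):
    """A unit-table file is missing columns or holds invalid values."""


@dataclass(frozen=True)
class VegetationUnit:
    """One mapped vegetation unit and its biodiversity attributes.

    Parameters
    ----------
    unit_id : str
        Short unique key (e.g. ``"sclerophyll"``).
    name : str
        Human-readable label.
    potential_area : float
        Pre-disturbance (potential) extent PS, km².
    actual_area : float
        Present extent AS, km².
    time_to_recover : float
        Post-fire recovery delay coefficient in [0, 1] (1 = slowest).
    total_species, endemic_species, specific_endemic_species : int
        Species richness TS, island-endemic richness ES, and richness of
        species restricted to this unit SES.

    Notes
    -----
    Logically ``SES <= ES <= TS``; published tables occasionally violate
    this (transcription slips), so violations raise a warning, not an
    error, and the row is kept verbatim.
    """

    unit_id: str
    name: str
    potential_area: float
    actual_area: float
    time_to_recover: float
    total_species: int
    endemic_species: int
    specific_endemic_species: int

    def __post_init__(self) -> None:
        if self.potential_area < 0 or self.actual_area < 0:
            raise ValueError(
                f"unit {self.unit_id!r}: areas must be >= 0 "
                f"(PS={self.potential_area}, AS={self.actual_area})"
            )
        if not 0.0 <= self.time_to_recover <= 1.0:
            raise ValueError(
                f"unit {self.unit_id!r}: time_to_recover must lie in [0, 1], "
                f"got {self.time_to_recover}"
            )
        for attr in ("total_species", "endemic_species", "specific_endemic_species"):
            v = getattr(self, attr)
            if v < 0 or int(v) != v:
                raise ValueError(f"unit {self.unit_id!r}: {attr} must be a non-negative integer")
        ts, es, ses = self.total_species, self.endemic_species, self.specific_endemic_species
        if not ses <= es <= ts:
            warnings.warn(
                f"unit {self.unit_id!r}: species counts violate SES <= ES <= TS "
                f"(TS={ts}, ES={es}, SES={ses}); row retained as given",
                stacklevel=2,
            )


@dataclass(frozen=True)
class UnitTable:
    """Ordered collection of :class:`VegetationUnit` plus landscape totals.

    ``totals`` holds the landscape-wide distinct species counts
    ``(TS_L, ES_L, SES_L)`` used as denominators by the diversity index.
    They are *not* the column sums of the rows (species are shared across
    units), which is why they are stored explicitly.
    """

    units: tuple[VegetationUnit, ...]
    totals: tuple[int, int, int]

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate unit_ids: {dupes}")
        if any(t <= 0 for t in self.totals):
            raise ValueError(f"landscape species totals must be strictly positive, got {self.totals}")

    @property
    def unit_ids(self) -> tuple[str, ...]:
        return tuple(u.unit_id for u in self.units)

    def __len__(self) -> int:
        return len(self.units)

    def __getitem__(self, unit_id: str) -> VegetationUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self.unit_ids

    def to_frame(self) -> pd.DataFrame:
        """Per-unit attributes as a DataFrame (totals not included)."""
        return pd.DataFrame(
            {
                "unit_id": [u.unit_id for u in self.units],
                "name": [u.name for u in self.units],
                "potential_area_km2": [u.potential_area for u in self.units],
                "actual_area_km2": [u.actual_area for u in self.units],
                "time_to_recover": [u.time_to_recover for u in self.units],
                "total_species": [u.total_species for u in self.units],
                "endemic_species": [u.endemic_species for u in self.units],
                "specific_endemic_species": [u.specific_endemic_species for u in self.units],
            }
        )


def read_unit_table(path: str | Path, *, totals_from_sums: bool = False) -> UnitTable:
    """Read a vegetation-unit attribute table from CSV.

    The CSV must carry the columns in :data:`UNIT_TABLE_COLUMNS`. A row
    whose ``unit_id`` is ``TOTAL`` (case-insensitive) supplies the
    landscape species totals; if absent, or if ``totals_from_sums`` is
    true, totals are the column sums over the unit rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in UNIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise UnitTableSchemaError(f"{path}: missing column(s) {missing}")

    is_total = df["unit_id"].astype(str).str.upper() == "TOTAL"
    body = df[~is_total]
    units = tuple(
        VegetationUnit(
            unit_id=str(r.unit_id),
            name=str(r.name),
            potential_area=float(r.potential_area_km2),
            actual_area=float(r.actual_area_km2),
            time_to_recover=float(r.time_to_recover),
            total_species=int(r.total_species),
            endemic_species=int(r.endemic_species),
            specific_endemic_species=int(r.specific_endemic_species),
        )
        for r in body.itertuples(index=False)
    )
    if totals_from_sums or not is_total.any():
        totals = (
            int(body["total_species"].sum()),
            int(body["endemic_species"].sum()),
            int(body["specific_endemic_species"].sum()),
        )
    else:
        trow = df[is_total].iloc[0]
        totals = (
            int(trow["total_species"]),
            int(trow["endemic_species"]),
            int(trow["specific_endemic_species"]),
        )
    return UnitTable(units=units, totals=totals)


def write_unit_table(table: UnitTable, path: str | Path) -> Path:
    """Write a :class:`UnitTable` to CSV, totals as a trailing TOTAL row."""
    path = Path(path)
    df = table.to_frame()
    total = {c: "" for c in UNIT_TABLE_COLUMNS}
    total.update(
        unit_id="TOTAL",
        name="TOTAL",
        total_species=table.totals[0],
        endemic_species=table.totals[1],
        specific_endemic_species=table.totals[2],
    )
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# landscape grid


@dataclass
class LandscapeGrid:
    """Regular grid with per-cell fractional vegetation composition.

    ``composition`` has shape ``(n_units, nrows, ncols)``; layer order
    follows ``unit_ids``. Fractions are non-negative and sum to at most
    ``1 + COMPOSITION_EPS`` per cell; the shortfall is the unvegetated
    residual class.
    """

    unit_ids: tuple[str, ...]
    composition: np.ndarray
    cell_size: float = 300.0  # metres
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    crs: str | None = None

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if self.composition.ndim != 3 or self.composition.shape[0] != len(self.unit_ids):
            raise ValueError(
                f"composition must have shape (n_units={len(self.unit_ids)}, nrows, ncols), "
                f"got {self.composition.shape}"
            )
        if (self.composition < 0).any():
            raise ValueError("composition fractions must be >= 0")
        total = self.composition.sum(axis=0)
        bad = np.argwhere(total > 1.0 + COMPOSITION_EPS)
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"composition fractions sum to {total[r, c]:.6f} > 1 at cell "
                f"(row={r}, col={c})"
            )

    # -- geometry ---------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.composition.shape[1]

    @property
    def ncols(self) -> int:
        return self.composition.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.composition.shape[1:]

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area(self) -> float:
        """Cell area S_i in km² (0.09 for the default 300 m cells)."""
        return (self.cell_size / 1000.0) ** 2

    def flat(self, row: int, col: int) -> int:
        return row * self.ncols + col

    def rowcol(self, i: int) -> tuple[int, int]:
        return divmod(i, self.ncols)

    # -- composition views -------------------------------------------------
    def fraction_of(self, unit_id: str) -> np.ndarray:
        """The (nrows, ncols) fraction layer of one unit."""
        try:
            k = self.unit_ids.index(unit_id)
        except ValueError:
            raise KeyError(unit_id) from None
        return self.composition[k]

    def composition_flat(self) -> np.ndarray:
        """Composition reshaped to (n_units, n_cells)."""
        return self.composition.reshape(len(self.unit_ids), -1)

    def vegetated_fraction(self) -> np.ndarray:
        """Per-cell total vegetated fraction, shape (nrows, ncols)."""
        return self.composition.sum(axis=0)

    def mix(self, per_unit: Mapping[str, float]) -> np.ndarray:
        """Composition-weighted per-cell combination of a per-unit quantity.

        Returns ``sum_u rho[u] * per_unit[u]`` as an (nrows, ncols) array.
        Raises ``KeyError`` for grid units missing from ``per_unit``.
        """
        missing = [u for u in self.unit_ids if u not in per_unit]
        if missing:
            raise KeyError(f"no per-unit value for grid unit(s) {missing}")
        w = np.array([per_unit[u] for u in self.unit_ids], dtype=float)
        return np.tensordot(w, self.composition, axes=1)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; NODATA cells become NaN.

    Returns ``(values, header)`` where ``values`` has shape
    ``(nrows, ncols)`` with row 0 the top row, and ``header`` holds
    ``xllcorner``, ``yllcorner``, ``cellsize`` and ``nodata_value``.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    meta = {
        "xllcorner": header.get("xllcorner", 0.0),
        "yllcorner": header.get("yllcorner", 0.0),
        "cellsize": header.get("cellsize", 1.0),
        "nodata_value": nodata if nodata is not None else -9999.0,
    }
    return data, meta


def write_ascii_grid(
    values: np.ndarray,
    path: str | Path,
    *,
    cellsize: float = 300.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata_value: float = -9999.0,
) -> Path:
    """Write a 2-D array as an ESRI ASCII grid; NaN maps to NODATA.

    Values are written with ``repr``-level precision so float64 surfaces
    round-trip bit-identically through :func:`read_ascii_grid`.
    """
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {values.shape}")
    out = np.where(np.isnan(values), nodata_value, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {values.shape[1]}\n")
        fh.write(f"nrows {values.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata_value!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    return path


def read_composition_grid(
    layer_paths: Mapping[str, str | Path],
    *,
    cell_size: float | None = None,
) -> LandscapeGrid:
    """Assemble a :class:`LandscapeGrid` from one fraction raster per unit.

    All layers must share dimensions and georeference. Values outside
    [0, 1] or cells whose fractions sum above ``1 + COMPOSITION_EPS``
    are rejected. NODATA cells are read as fraction 0.
    """
    if not layer_paths:
        raise ValueError("no composition layers given")
    unit_ids: list[str] = []
    layers: list[np.ndarray] = []
    meta0: dict | None = None
    first_unit = None
    for unit_id, p in layer_paths.items():
        arr, meta = read_ascii_grid(p)
        if meta0 is None:
            meta0, first_unit = meta, unit_id
        else:
            same_shape = arr.shape == layers[0].shape
            same_geo = all(
                np.isclose(meta[k], meta0[k]) for k in ("xllcorner", "yllcorner", "cellsize")
            )
            if not (same_shape and same_geo):
                raise ValueError(
                    f"layer {unit_id!r} does not match layer {first_unit!r} "
                    f"(shape {arr.shape} vs {layers[0].shape}, georeference {meta} vs {meta0})"
                )
        arr = np.nan_to_num(arr, nan=0.0)
        if (arr < 0).any() or (arr > 1 + COMPOSITION_EPS).any():
            raise ValueError(f"layer {unit_id!r} has fractions outside [0, 1]")
        unit_ids.append(unit_id)
        layers.append(arr)
    comp = np.stack(layers)
    return LandscapeGrid(
        unit_ids=tuple(unit_ids),
        composition=comp,
        cell_size=cell_size if cell_size is not None else meta0["cellsize"],
        xllcorner=meta0["xllcorner"],
        yllcorner=meta0["yllcorner"],
    )


def write_composition_grid(grid: LandscapeGrid, out_dir: str | Path) -> dict[str, Path]:
    """Write one ``comp_<unit>.asc`` per unit; returns unit -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for u in grid.unit_ids:
        p = out_dir / f"comp_{u}.asc"
        write_ascii_grid(
            grid.fraction_of(u),
            p,
            cellsize=grid.cell_size,
            xllcorner=grid.xllcorner,
            yllcorner=grid.yllcorner,
        )
        paths[u] = p
    return paths


def write_surface(grid: LandscapeGrid, values: np.ndarray, path: str | Path) -> Path:
    """Write a per-cell surface aligned to ``grid`` as an ASCII raster.

    ``values`` may be flat ``(n_cells,)`` or shaped ``(nrows, ncols)``.
    NaN values (off-landscape / not evaluated) become NODATA.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        if values.size != grid.n_cells:
            raise ValueError(f"surface length {values.size} != cell count {grid.n_cells}")
        values = values.reshape(grid.shape)
    elif values.shape != grid.shape:
        raise ValueError(f"surface shape {values.shape} != grid shape {grid.shape}")
    return write_ascii_grid(
        values,
        path,
        cellsize=grid.cell_size,
        xllcorner=grid.xllcorner,
        yllcorner=grid.yllcorner,
    )


def read_surface(path: str | Path, grid: LandscapeGrid | None = None) -> np.ndarray:
    """Read a surface raster; optionally check registration against a grid."""
    arr, meta = read_ascii_grid(path)
    if grid is not None and arr.shape != grid.shape:
        raise ValueError(f"surface shape {arr.shape} != grid shape {grid.shape}")
    return arr
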