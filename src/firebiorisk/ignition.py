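"""Fire-ignition-probability (FIP) surfaces.

A FIP surface holds a non-negative per-cell weight proportional to the
chance a fire starts there. The risk equations only ever use FIP as a
relative weight (their normalizations absorb any positive scale), so the
surface need not sum to 1; :func:`normalize_fip` provides the
probability-mass convention where one is needed (e.g. Monte-Carlo
ignition sampling).

The synthetic generator reproduces the spatial character observed in
anthropogenic fire regimes — ignition mass concentrated along roads and
around villages, decaying exponentially with distance — without modelling
any of the underlying covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .landscape import LandscapeGrid, read_ascii_grid, write_ascii_grid

__all__ = [
    "FIPSurface",
    "read_fip",
    "write_fip",
    "synth_fip",
    "normalize_fip",
]


@dataclass(frozen=True)
class FIPSurface:
    """Per-cell fire ignition weights, shape (nrows, ncols).

    ``mode`` tags the temporal support ("daily" or "ten_year_average");
    the arithmetic is identical for both.
    """

    values: np.ndarray
    mode: str = "ten_year_average"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError(f"FIP surface must be 2-D, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("FIP surface has non-finite values")
        if (v < 0).any():
            bad = np.argwhere(v < 0)[0]
            raise ValueError(f"negative FIP at cell (row={bad[0]}, col={bad[1]})")
        if self.mode not in ("daily", "ten_year_average"):
            raise ValueError(f"unknown FIP mode {self.mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def flat(self) -> np.ndarray:
        return self.values.ravel()


def read_fip(
    path: str | Path, grid: LandscapeGrid | None = None, mode: str = "ten_year_average"
) -> FIPSurface:
    """Read a FIP raster; NODATA becomes 0 (with a warning count)."""
    arr, _ = read_ascii_grid(path)
    if grid is not None and arr.shape != grid.shape:
        raise ValueError(f"FIP shape {arr.shape} does not match landscape {grid.shape}")
    n_nodata = int(np.isnan(arr).sum())
    if n_nodata:
        warnings.warn(f"{path}: {n_nodata} NODATA FIP cell(s) set to 0", stacklevel=2)
        arr = np.nan_to_num(arr, nan=0.0)
    return FIPSurface(values=arr, mode=mode)


def write_fip(fip: FIPSurface, path: str | Path, *, cellsize: float = 300.0) -> Path:
    return write_ascii_grid(fip.values, path, cellsize=cellsize)


def _distance_to(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Euclidean distance (metres) to the nearest True cell; inf if none."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return distance_transform_edt(~mask) * cell_size


def synth_fip(
    grid: LandscapeGrid,
    roads: Sequence[np.ndarray] = (),
    villages: Sequence[tuple[int, int]] = (),
    *,
    background: float = 0.005,
    road_weight: float = 1.0,
    village_weight: float = 0.5,
    decay_length_m: float = 430.0,
    mode: str = "ten_year_average",
    seed: int | None = None,
) -> FIPSurface:
    """Generate an anthropogenic ignition surface.

    Each cell gets ``background + road_weight·exp(−d_road/λ) +
    village_weight·exp(−d_village/λ)`` with λ = ``decay_length_m`` and the
    distances measured to the nearest road cell / village cell; the result
    is rescaled so its maximum is 1. Roads are sequences of ``(row, col)``
    cell arrays (shape (k, 2)); villages are single cells.

    With the default λ = 430 m on a road-bearing landscape, well over half
    of the total ignition mass falls within 500 m of a road and most of it
    within 1 km, matching the anthropogenic clustering the surface is
    meant to emulate. Deterministic; ``seed`` is accepted for interface
    symmetry and ignored.
    """
    if decay_length_m <= 0:
        raise ValueError("decay_length_m must be positive")
    nrows, ncols = grid.shape
    road_mask = np.zeros((nrows, ncols), dtype=bool)
    for line in roads:
        cells = np.asarray(line, dtype=int).reshape(-1, 2)
        road_mask[cells[:, 0], cells[:, 1]] = True
    vill_mask = np.zeros((nrows, ncols), dtype=bool)
    for r, c in villages:
        vill_mask[r, c] = True

    if background <= 0 and not road_mask.any() and not vill_mask.any():
        raise ValueError("no roads, no villages, zero background: FIP would be all zero")

    fip = np.full((nrows, ncols), float(background))
    if road_mask.any() and road_weight > 0:
        fip += road_weight * np.exp(-_distance_to(road_mask, grid.cell_size) / decay_length_m)
    if vill_mask.any() and village_weight > 0:
        fip += village_weight * np.exp(-_distance_to(vill_mask, grid.cell_size) / decay_length_m)
    peak = fip.max()
    if peak <= 0:
        raise ValueError("generated FIP surface is all zero")
    return FIPSurface(values=fip / peak, mode=mode)


def normalize_fip(fip: FIPSurface) -> FIPSurface:
    """Rescale a FIP surface to total mass 1 (probability convention)."""
    total = fip.values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero FIP surface")
    return FIPSurface(values=fip.values / total, mode=fip.mode)
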