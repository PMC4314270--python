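"""One-off and multi-event fire risk on biodiversity.

Risk is probability times impact on a raster landscape:

* One-off event impact ``Oe_j`` sums the per-cell biodiversity-loss index
  over the burnt area of the fire ignited at cell j (optionally weighted
  by per-fire max-normalized severity); one-off risk ``OeR_j`` multiplies
  it by the ignition probability ``FIP_j`` and rescales the surface to a
  maximum of 1.
* The burnt-area matrix ``BAM[i, j]`` records which cells each simulated
  fire burned. Burn probability ``BP_i`` is the FIP-weighted row average
  ``Σ_j FIP_j·BAM_ij / Σ_j FIP_j`` — a nonuniform-ignition generalization
  of the classic burn-probability ratio (row count over number of fires),
  to which it reduces exactly under uniform FIP. Multi-event risk
  ``MeR_i = BP_i·BL_i``, again rescaled to max 1.

Summaries: per-unit exceedance curves (composition-weighted fraction of a
unit's area at risk above a threshold) and landscape threshold areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fire import FireResult, severity
from .ignition import FIPSurface
from .landscape import LandscapeGrid

__all__ = [
    "BurntAreaMatrix",
    "build_bam",
    "one_off_impact",
    "one_off_risk",
    "burn_probability",
    "multi_event_risk",
    "risk_cdf_by_unit",
    "threshold_area",
]

OE_MODES = ("sum_bl", "severity_weighted")
BP_METHODS = ("fip_weighted", "uniform")


@dataclass(frozen=True)
class BurntAreaMatrix:
    """Sparse binary matrix of shape (n_cells, n_fires).

    Column k covers the burnt set of the fire ignited at
    ``ignitions[k]``; ``matrix[i, k] = 1`` iff that fire burned cell i.
    Every column contains its own ignition cell.
    """

    matrix: sp.csc_matrix
    ignitions: np.ndarray  # flat cell index per column
    shape: tuple[int, int]  # landscape (nrows, ncols)

    @property
    def n_fires(self) -> int:
        return int(self.ignitions.size)

    @property
    def n_cells(self) -> int:
        return int(self.matrix.shape[0])

    def burn_counts(self) -> np.ndarray:
        """Row sums: number of simulated fires that burned each cell."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def build_bam(fires: Sequence[FireResult], grid: LandscapeGrid) -> BurntAreaMatrix:
    """Compile simulated fires into a burnt-area matrix.

    Fires must have distinct ignition cells (one fire per candidate
    ignition) and burn only on-landscape cells.
    """
    n_cells = grid.n_cells
    ign = np.array([f.ignition_cell for f in fires], dtype=np.int64)
    uniq, counts = np.unique(ign, return_counts=True)
    if (counts > 1).any():
        raise ValueError(f"duplicate ignition cells: {uniq[counts > 1].tolist()}")
    rows, cols = [], []
    for k, f in enumerate(fires):
        if f.shape != grid.shape:
            raise ValueError(f"fire {k} shape {f.shape} != landscape {grid.shape}")
        if f.n_burnt and f.burnt_cells.max() >= n_cells:
            raise ValueError(f"fire {k} burns off-landscape cells")
        rows.append(f.burnt_cells)
        cols.append(np.full(f.n_burnt, k, dtype=np.int64))
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    m = sp.csc_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_cells, len(fires)), dtype=float
    )
    return BurntAreaMatrix(matrix=m, ignitions=ign, shape=grid.shape)


# ---------------------------------------------------------------------------
# one-off event


def one_off_impact(
    fires: Sequence[FireResult],
    bl: np.ndarray,
    mode: str = "severity_weighted",
) -> np.ndarray:
    """Expected one-off impact Oe_j, reported on the ignition cell.

    ``bl`` is the per-cell biodiversity-loss surface (flat or 2-D).
    ``mode="sum_bl"`` sums BL over the burnt area; ``"severity_weighted"``
    weights each burnt cell by that fire's max-normalized severity (so Oe
    keeps the scale of BL). Returns a flat per-cell array holding Oe at
    each simulated ignition cell and NaN elsewhere.
    """
    if mode not in OE_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {OE_MODES}")
    bl = np.asarray(bl, dtype=float).ravel()
    ign = [f.ignition_cell for f in fires]
    if len(set(ign)) != len(ign):
        raise ValueError("duplicate ignition cells across fires")
    oe = np.full(bl.size, np.nan)
    for f in fires:
        if f.n_burnt and f.burnt_cells.max() >= bl.size:
            raise ValueError("fire burns cells outside the biodiversity-loss surface")
        bl_b = bl[f.burnt_cells]
        if mode == "sum_bl":
            val = bl_b.sum()
        else:
            if f.n_burnt == 0 or not (f.intensity > 0).any():
                val = 0.0  # degenerate fire: nothing actually burned
            else:
                sev = severity(f)
                val = float((sev / sev.max()) @ bl_b)
        oe[f.ignition_cell] = val
    return oe


def one_off_risk(oe: np.ndarray, fip: FIPSurface) -> np.ndarray:
    """OeR_j = FIP_j · Oe_j, rescaled so the landscape maximum is 1.

    NaN entries of ``oe`` (cells with no simulated fire) stay NaN. An
    all-zero product surface stays all zero.
    """
    oe = np.asarray(oe, dtype=float).ravel()
    fipv = fip.flat()
    if oe.size != fipv.size:
        raise ValueError(f"Oe size {oe.size} != FIP size {fipv.size}")
    raw = fipv * oe
    peak = np.nanmax(raw) if np.isfinite(raw).any() else 0.0
    if peak > 0:
        raw = raw / peak
    return raw


# ---------------------------------------------------------------------------
# burn probability and multi-event risk


def burn_probability(
    bam: BurntAreaMatrix,
    fip: FIPSurface | None = None,
    method: str = "fip_weighted",
) -> np.ndarray:
    """Per-cell burn probability from the burnt-area matrix.

    ``"uniform"`` is the classic ratio: times burned over number of
    simulated fires. ``"fip_weighted"`` weights each fire by the ignition
    probability of its start cell: ``BP_i = Σ_j FIP_j·BAM_ij / Σ_j FIP_j``.
    Weights are taken relative to their maximum before the ratio, which
    changes nothing mathematically but makes the uniform-FIP case reduce
    to the classic ratio bit-for-bit. Returns a flat array in [0, 1].
    """
    if method not in BP_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {BP_METHODS}")
    if bam.n_fires == 0:
        raise ValueError("burnt-area matrix has no fires")
    if method == "uniform":
        return bam.burn_counts() / bam.n_fires
    if fip is None:
        raise ValueError("fip_weighted burn probability needs a FIP surface")
    w = fip.flat()[bam.ignitions]
    if w.sum() <= 0:
        raise ValueError("FIP is zero at every simulated ignition cell")
    w = w / w.max()  # scale-free; uniform FIP -> exact Finney reduction
    return (bam.matrix @ w) / w.sum()


def multi_event_risk(bp: np.ndarray, bl: np.ndarray) -> np.ndarray:
    """MeR_i = BP_i · BL_i, rescaled so the landscape maximum is 1."""
    bp = np.asarray(bp, dtype=float).ravel()
    bl = np.asarray(bl, dtype=float).ravel()
    if bp.shape != bl.shape:
        raise ValueError(f"shape mismatch: BP {bp.shape} vs BL {bl.shape}")
    raw = bp * bl
    peak = raw.max()
    if peak > 0:
        raw = raw / peak
    return raw


# ---------------------------------------------------------------------------
# summaries


def risk_cdf_by_unit(
    risk: np.ndarray,
    grid: LandscapeGrid,
    thresholds: Iterable[float] = (0.0, 1e-3, 1e-2, 1e-1, 0.16, 0.5),
) -> pd.DataFrame:
    """Per-unit exceedance curves of a risk surface.

    For each unit u and threshold t, the fraction of u's
    composition-weighted area lying in cells with risk strictly above t.
    NaN risk (cells never evaluated) counts as not exceeding. Returns a
    tidy frame with columns ``unit_id``, ``threshold``, ``exceedance``.
    """
    r = np.nan_to_num(np.asarray(risk, dtype=float).ravel(), nan=0.0)
    comp = grid.composition_flat()
    rows = []
    for k, u in enumerate(grid.unit_ids):
        w = comp[k]
        area = w.sum()
        for t in thresholds:
            if area > 0:
                frac = float(w[r > t].sum() / area)
            else:
                frac = 0.0
            rows.append({"unit_id": u, "threshold": float(t), "exceedance": frac})
    return pd.DataFrame(rows)


def threshold_area(
    risk: np.ndarray, grid: LandscapeGrid, threshold: float
) -> tuple[float, float]:
    """Area (km²) and landscape fraction with risk strictly above a threshold.

    The landscape is the set of vegetated cells (any positive composition);
    NaN risk counts as not exceeding.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    r = np.nan_to_num(np.asarray(risk, dtype=float).ravel(), nan=0.0)
    n_above = int((r > threshold).sum())
    area = n_above * grid.cell_area
    n_landscape = int((grid.vegetated_fraction() > 0).sum())
    frac = area / (n_landscape * grid.cell_area) if n_landscape else 0.0
    return area, frac
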