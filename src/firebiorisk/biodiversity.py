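"""Diversity, vulnerability, and biodiversity-loss indices.

Unit level
----------
For each vegetation unit *u* with species counts (TS, ES, SES), landscape
totals (TS_L, ES_L, SES_L) and actual area AS (km²), the diversity density

    DVU_u = (a·TS_u/TS_L + b·ES_u/ES_L + c·SES_u/SES_L) / AS_u      [1/km²]

mixes three richness ratios (all species, island endemics, unit-restricted
endemics) and normalizes by the unit's present extent, so small species-rich
relicts (sclerophyll forest) score orders of magnitude above extensive
species-poor formations (savanna). The vulnerability index

    Vul_u = (PS_u / AS_u) · Time_u

combines historical regression (potential over actual area) with the
time-to-recover coefficient: it is large for units that have lost most of
their extent and recover slowly, exactly zero for purely anthropogenic
units with no potential extent (savanna, PS = 0). The unit-level loss index
is the product BL_u = DVU_u · Vul_u.

Cell level
----------
On a composition grid, D_i = S_i · Σ_u ρ_iu·DVU_u (cell area S_i in km²),
DNC_i = D_i / Σ_j D_j (so Σ DNC = 1 over the landscape),
Vul_i = Σ_u ρ_iu·Vul_u, and the per-cell loss index BL_i = DNC_i · Vul_i
used by the risk surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import LandscapeGrid, UnitTable

__all__ = [
    "DiversityWeights",
    "UnitIndices",
    "IndexSurfaces",
    "unit_diversity",
    "unit_vulnerability",
    "unit_biodiversity_loss",
    "compute_unit_indices",
    "cell_diversity",
    "normalize_diversity",
    "cell_vulnerability",
    "biodiversity_loss",
    "compute_index_surfaces",
]


@dataclass(frozen=True)
class DiversityWeights:
    """Weights (a, b, c) on the TS/ES/SES richness ratios; default all 1."""

    a: float = 1.0
    b: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError(f"diversity weights must be >= 0, got {(self.a, self.b, self.c)}")
        if self.a + self.b + self.c <= 0:
            raise ValueError("at least one diversity weight must be positive")


@dataclass(frozen=True)
class UnitIndices:
    """Per-unit index columns: diversity density, vulnerability, loss."""

    unit_ids: tuple[str, ...]
    diversity: dict[str, float]
    vulnerability: dict[str, float]
    biodiversity_loss: dict[str, float]


@dataclass(frozen=True)
class IndexSurfaces:
    """Per-cell index maps on a landscape grid (all shaped (nrows, ncols))."""

    diversity: np.ndarray  # D_i
    diversity_normalized: np.ndarray  # DNC_i, sums to 1
    vulnerability: np.ndarray  # Vul_i
    biodiversity_loss: np.ndarray  # BL_i = DNC_i * Vul_i


# ---------------------------------------------------------------------------
# unit level


def unit_diversity(
    table: UnitTable, weights: DiversityWeights = DiversityWeights()
) -> dict[str, float]:
    """Diversity density DVU_u (1/km²) for every unit in the table.

    Raises ``ValueError`` for a unit with zero actual area (the per-area
    density is undefined there).
    """
    ts_l, es_l, ses_l = table.totals
    out: dict[str, float] = {}
    for u in table.units:
        if u.actual_area <= 0:
            raise ValueError(
                f"unit {u.unit_id!r}: actual area is {u.actual_area}; "
                "diversity per km² is undefined"
            )
        out[u.unit_id] = (
            weights.a * u.total_species / ts_l
            + weights.b * u.endemic_species / es_l
            + weights.c * u.specific_endemic_species / ses_l
        ) / u.actual_area
    return out


def unit_vulnerability(table: UnitTable) -> dict[str, float]:
    """Vulnerability Vul_u = (PS_u / AS_u) · Time_u for every unit.

    Zero when the unit has no potential extent or recovers instantly;
    undefined (error) when the actual area is zero.
    """
    out: dict[str, float] = {}
    for u in table.units:
        if u.actual_area <= 0:
            raise ValueError(f"unit {u.unit_id!r}: actual area is {u.actual_area}")
        out[u.unit_id] = (u.potential_area / u.actual_area) * u.time_to_recover
    return out


def unit_biodiversity_loss(
    diversity: dict[str, float], vulnerability: dict[str, float]
) -> dict[str, float]:
    """Unit-level loss BL_u = DVU_u · Vul_u (the published table column)."""
    if set(diversity) != set(vulnerability):
        raise ValueError("diversity and vulnerability must cover the same units")
    return {u: diversity[u] * vulnerability[u] for u in diversity}


def compute_unit_indices(
    table: UnitTable, weights: DiversityWeights = DiversityWeights()
) -> UnitIndices:
    """All three per-unit index columns in one pass."""
    dvu = unit_diversity(table, weights)
    vul = unit_vulnerability(table)
    return UnitIndices(
        unit_ids=table.unit_ids,
        diversity=dvu,
        vulnerability=vul,
        biodiversity_loss=unit_biodiversity_loss(dvu, vul),
    )


# ---------------------------------------------------------------------------
# cell level


def cell_diversity(grid: LandscapeGrid, dvu: dict[str, float]) -> np.ndarray:
    """Per-cell diversity D_i = S_i · Σ_u ρ_iu · DVU_u, shape (nrows, ncols)."""
    return grid.cell_area * grid.mix(dvu)


def normalize_diversity(diversity: np.ndarray) -> np.ndarray:
    """DNC_i = D_i / Σ_j D_j; all-zero input maps to all-zero output."""
    d = np.asarray(diversity, dtype=float)
    if (d < 0).any():
        raise ValueError("diversity surface has negative values")
    total = d.sum()
    if total == 0:
        return np.zeros_like(d)
    return d / total


def cell_vulnerability(grid: LandscapeGrid, vul: dict[str, float]) -> np.ndarray:
    """Per-cell vulnerability Vul_i = Σ_u ρ_iu · Vul_u."""
    return grid.mix(vul)


def biodiversity_loss(dnc: np.ndarray, vul: np.ndarray) -> np.ndarray:
    """Per-cell loss index BL_i = DNC_i · Vul_i."""
    dnc = np.asarray(dnc, dtype=float)
    vul = np.asarray(vul, dtype=float)
    if dnc.shape != vul.shape:
        raise ValueError(f"shape mismatch: DNC {dnc.shape} vs Vul {vul.shape}")
    if (dnc < 0).any() or (vul < 0).any():
        raise ValueError("index surfaces must be non-negative")
    return dnc * vul


def compute_index_surfaces(
    grid: LandscapeGrid,
    table: UnitTable,
    weights: DiversityWeights = DiversityWeights(),
) -> IndexSurfaces:
    """D, DNC, Vul and BL surfaces for a landscape in one call."""
    idx = compute_unit_indices(table, weights)
    d = cell_diversity(grid, idx.diversity)
    dnc = normalize_diversity(d)
    vul = cell_vulnerability(grid, idx.vulnerability)
    return IndexSurfaces(
        diversity=d,
        diversity_normalized=dnc,
        vulnerability=vul,
        biodiversity_loss=biodiversity_loss(dnc, vul),
    )
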