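"""Plot-based products: grazing capacity and plant-diversity valuation.

Grazing capacity is a field statistic — cattle supported per hectare of
natural and artificial grassland times the respective areas — priced at the
local cattle market price.  Plant diversity is measured per 1 m² quadrat by
the Shannon-Weiner index

    H = -Σ (ni/N) · ln(ni/N)

averaged over the (typically three) quadrats of a plot, and valued as the
opportunity cost of annual species loss: each grassland stratum's area is
priced by the tier its mean index falls in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GrazingParams",
    "DiversityTierTable",
    "grazing_capacity",
    "grazing_value",
    "shannon_index",
    "plot_mean_index",
    "biodiversity_value",
]


@dataclass(frozen=True)
class GrazingParams:
    """Per-unit grazing capacities (cattle/hm²), areas (hm²) and cattle price."""

    gc_ng_pua: float
    gc_ag_pua: float
    area_ng: float
    area_ag: float
    cattle_price: float = 2043.51  # USD per head

    def __post_init__(self) -> None:
        for name in ("gc_ng_pua", "gc_ag_pua", "area_ng", "area_ag", "cattle_price"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class DiversityTierTable:
    """Tiered pricing of diversity: (lower bound of Shannon index, USD/hm²/yr).

    Tier lookup uses half-open intervals [lo, hi): an index exactly on a
    bound belongs to the tier that starts there.  Bounds must start at 0 and
    increase strictly.
    """

    def __init__(self, tiers: Iterable[tuple[float, float]]):
        rows = sorted((float(b), float(p)) for b, p in tiers)
        if not rows:
            raise ValueError("tier table must not be empty")
        if rows[0][0] != 0.0:
            raise ValueError("first tier bound must be 0")
        bounds = [b for b, _ in rows]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("tier bounds must increase strictly")
        if any(p < 0 for _, p in rows):
            raise ValueError("tier prices must be non-negative")
        self.rows = rows

    def price(self, index: float) -> float:
        """Price of the tier whose lower bound is the greatest one ≤ index."""
        if index < 0:
            raise ValueError(f"diversity index must be non-negative, got {index}")
        chosen = self.rows[0][1]
        for bound, price in self.rows:
            if index >= bound:
                chosen = price
        return chosen


#: default tier bounds; prices are study-area config and carry no default
DEFAULT_TIER_BOUNDS = (0.0, 0.5, 1.0, 1.5)


def grazing_capacity(params: GrazingParams) -> float:
    """Total grazing capacity GC (cattle) over both grassland types."""
    return params.gc_ng_pua * params.area_ng + params.gc_ag_pua * params.area_ag


def grazing_value(gc: float, cattle_price: float) -> float:
    """Market value of grazing capacity: head count × price per head."""
    if gc < 0:
        raise ValueError("grazing capacity must be non-negative")
    return gc * cattle_price


def shannon_index(counts: Mapping[str, int] | Iterable[int]) -> float:
    """Shannon-Weiner diversity H = -Σ (ni/N)·ln(ni/N), natural log.

    Species with zero count contribute nothing; an all-zero census is an
    error.
    """
    ni = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else list(counts), dtype=float
    )
    if (ni < 0).any():
        raise ValueError("species counts must be non-negative")
    total = ni.sum()
    if total <= 0:
        raise ValueError("shannon_index needs at least one individual")
    p = ni[ni > 0] / total
    return float(-(p * np.log(p)).sum())


def plot_mean_index(quadrat_indices: Iterable[float]) -> float:
    """Plot-level index: arithmetic mean of its quadrat indices."""
    vals = list(quadrat_indices)
    if not vals:
        raise ValueError("plot_mean_index needs at least one quadrat")
    return float(np.mean(vals))


def biodiversity_value(
    area_by_stratum: Mapping[str, tuple[float, float]], tiers: DiversityTierTable
) -> float:
    """Diversity value: Σ over strata of area × tier price of the mean index.

    ``area_by_stratum`` maps a stratum name to (area in hm², mean Shannon
    index of its plots).
    """
    total = 0.0
    for stratum, (area, index) in area_by_stratum.items():
        if area < 0:
            raise ValueError(f"negative area for stratum {stratum!r}")
        if index < 0 or not math.isfinite(index):
            raise ValueError(f"invalid diversity index {index} for stratum {stratum!r}")
        total += area * tiers.price(index)
    return total
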