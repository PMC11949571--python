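"""Karst water yield and water-retention valuation.

Water yield per patch is the precipitation surplus Yx = (1 - AETx/Px)·Px.
In karst terrain only part of that yield is retained on-site; retention is
the yield damped by three capped factors — flow velocity, topographic
wetness, and saturated conductivity:

    WR = min(1, 249/Velocity) · min(1, 0.9·TI/3) · min(1, Ksat/300) · Yx
    TI = log10( DrainageArea / (SoilDepth · Percent_slope) )

Each factor saturates at 1; a negative TI floors the middle factor at 0 so
retention is never negative.  Retained depth (mm) over the grassland mask is
converted to tonnes (1 mm over 1 hm² = 10 m³ = 10 t) and priced at the local
water price.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geodata import RasterGrid, RasterError, _require_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "HydroLayers",
    "WaterPrice",
    "water_yield",
    "topographic_index",
    "water_retention",
    "water_retention_value",
    "TONNES_PER_MM_HM2",
]

#: 1 mm of water over 1 hm² = 10 m³ = 10 tonnes.
TONNES_PER_MM_HM2 = 10.0


@dataclass(frozen=True)
class WaterPrice:
    """Local water price in USD per tonne."""

    price_per_tonne: float = 0.43

    def __post_init__(self) -> None:
        if not self.price_per_tonne > 0:
            raise ValueError(f"water price must be positive, got {self.price_per_tonne}")


@dataclass
class HydroLayers:
    """Aligned raster stack for the water-retention chain.

    Units: precip/aet mm·yr⁻¹, drainage_area hm², soil_depth cm, slope %,
    ksat mm·d⁻¹; velocity is the dimensionless flow coefficient (looked up
    per land-cover class upstream).
    """

    precip: RasterGrid
    aet: RasterGrid
    velocity: RasterGrid
    ksat: RasterGrid
    drainage_area: RasterGrid
    soil_depth: RasterGrid
    slope_pct: RasterGrid
    #: thresholds of the three damping factors, exposed for sensitivity work
    velocity_cap: float = 249.0
    ksat_cap: float = 300.0
    log_base: str = "10"  # "10" or "e"

    def __post_init__(self) -> None:
        layers = [self.aet, self.velocity, self.ksat, self.drainage_area, self.soil_depth, self.slope_pct]
        for lyr in layers:
            _require_aligned(self.precip, lyr, "HydroLayers")
        p = self.precip.filled()
        a = self.aet.filled()
        both = np.isfinite(p) & np.isfinite(a)
        if np.nanmin(np.where(both, p, 0.0)) < 0:
            raise RasterError("precipitation must be non-negative")
        bad = both & (a > p)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise RasterError(
                f"AET exceeds precipitation at cell ({r}, {c}): {a[r, c]:.3f} > {p[r, c]:.3f}"
            )
        if self.log_base not in ("10", "e"):
            raise ValueError(f"log_base must be '10' or 'e', got {self.log_base!r}")


def water_yield(precip: RasterGrid, aet: RasterGrid) -> RasterGrid:
    """Per-cell annual water yield Yx = (1 - AETx/Px)·Px, in mm·yr⁻¹.

    Cells with zero precipitation yield zero.
    """
    _require_aligned(precip, aet, "water_yield")
    p = precip.filled()
    a = aet.filled()
    both = np.isfinite(p) & np.isfinite(a)
    bad = both & (a > p)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise RasterError(f"AET exceeds precipitation at cell ({r}, {c})")
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(p > 0, (1.0 - a / np.where(p > 0, p, 1.0)) * p, 0.0)
    y[~both] = np.nan
    return precip.with_values(y, nodata=np.nan)


def topographic_index(
    drainage_area: RasterGrid,
    soil_depth: RasterGrid,
    slope_pct: RasterGrid,
    log_base: str = "10",
) -> RasterGrid:
    """Topographic index log(DrainageArea / (SoilDepth · Percent_slope)).

    Base-10 logarithm by default (``log_base='e'`` switches to natural log).
    Cells with a non-positive argument become nodata; their count is logged.
    """
    _require_aligned(drainage_area, soil_depth, "topographic_index")
    _require_aligned(drainage_area, slope_pct, "topographic_index")
    da = drainage_area.filled()
    sd = soil_depth.filled()
    sl = slope_pct.filled()
    denom = sd * sl
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = np.where(denom > 0, da / np.where(denom > 0, denom, 1.0), np.nan)
        arg = np.where(arg > 0, arg, np.nan)
        ti = np.log10(arg) if log_base == "10" else np.log(arg)
    valid_in = drainage_area.mask() & soil_depth.mask() & slope_pct.mask()
    n_bad = int((valid_in & np.isnan(ti)).sum())
    if n_bad > 0:
        logger.warning("topographic_index: %d cells with non-positive argument set to nodata", n_bad)
    return drainage_area.with_values(ti, nodata=np.nan)


def water_retention(layers: HydroLayers) -> RasterGrid:
    """Per-cell retained water depth WR (mm·yr⁻¹)."""
    vel = layers.velocity.filled()
    if np.nanmin(vel) <= 0:
        raise RasterError("Velocity coefficient must be positive everywhere")
    yx = water_yield(layers.precip, layers.aet).values
    ti = topographic_index(
        layers.drainage_area, layers.soil_depth, layers.slope_pct, layers.log_base
    ).values
    f_vel = np.minimum(1.0, layers.velocity_cap / vel)
    f_ti = np.clip(0.9 * ti / 3.0, 0.0, 1.0)
    f_ksat = np.minimum(1.0, layers.ksat.filled() / layers.ksat_cap)
    wr = f_vel * f_ti * f_ksat * yx
    return layers.precip.with_values(wr, nodata=np.nan)


def water_retention_value(
    wr: RasterGrid, mask: RasterGrid, price: WaterPrice
) -> tuple[float, float]:
    """Total retained volume (tonnes) and its value (USD) over a mask.

    Returns ``(value_usd, volume_tonnes)``.
    """
    _require_aligned(wr, mask, "water_retention_value")
    sel = (mask.filled(0.0) == 1.0) & wr.mask()
    volume_t = float(np.sum(wr.values[sel]) * wr.cell_area * TONNES_PER_MM_HM2)
    return volume_t * price.price_per_tonne, volume_t
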