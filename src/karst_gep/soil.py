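"""RUSLE soil retention and its two-part valuation.

Retained soil mass comes from the Revised Universal Soil Loss Equation
factor product R·K·LS·(1-C)·P accumulated over the grassland mask.  Its
value has two parts:

* sediment reduction — the retained volume (mass / bulk density) times the
  fraction that would otherwise silt reservoirs, priced at the engineering
  cost of replacing reservoir capacity (shadow-engineering method);
* fertilizer retention — the N, P, K and organic-matter mass held in the
  retained soil, expressed as the equivalent amount of commercial fertilizer
  and priced at fertilizer market prices (replacement-cost method).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geodata import RasterGrid, RasterError, _require_aligned

__all__ = [
    "RusleLayers",
    "SoilValuationParams",
    "rusle_retention",
    "sediment_reduction_value",
    "fertilizer_retention_value",
    "soil_retention_value",
]

NUTRIENTS = ("N", "P", "K", "OM")

#: fertilizer nutrient fractions (N and P as diammonium phosphate, K as
#: potassium chloride, organic matter applied as-is)
DEFAULT_FERTILIZER_FRACTION = {"N": 0.14, "P": 0.15, "K": 0.50, "OM": 1.00}
#: USD per tonne of the corresponding fertilizer product
DEFAULT_FERTILIZER_PRICE = {"N": 434.25, "P": 434.25, "K": 333.49, "OM": 121.33}


@dataclass
class RusleLayers:
    """Aligned RUSLE factor grids.

    ``r_factor`` rainfall erosivity, ``k_factor`` soil erodibility,
    ``ls_factor`` slope length/steepness, ``c_factor`` cover-management and
    ``p_factor`` support practice (both in [0, 1]).
    """

    r_factor: RasterGrid
    k_factor: RasterGrid
    ls_factor: RasterGrid
    c_factor: RasterGrid
    p_factor: RasterGrid

    def __post_init__(self) -> None:
        for lyr in (self.k_factor, self.ls_factor, self.c_factor, self.p_factor):
            _require_aligned(self.r_factor, lyr, "RusleLayers")
        for name, lyr in (("C", self.c_factor), ("P", self.p_factor)):
            v = lyr.filled()
            ok = np.isfinite(v)
            if ok.any() and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
                raise RasterError(f"{name} factor must lie in [0, 1]")
        for name, lyr in (("R", self.r_factor), ("K", self.k_factor), ("LS", self.ls_factor)):
            v = lyr.filled()
            if np.isfinite(v).any() and np.nanmin(v) < 0:
                raise RasterError(f"{name} factor must be non-negative")


@dataclass
class SoilValuationParams:
    """Economic parameters of the soil-retention valuation.

    ``nutrient_content`` holds soil mass fractions (0.002 means 0.2%);
    the config layer converts printed percentages exactly once.
    """

    bulk_density: float  # t/m³
    nutrient_content: dict[str, float]  # soil mass fraction per nutrient
    sediment_fraction: float = 0.24
    reservoir_cost: float = 5.96  # USD per m³ of reservoir capacity
    fertilizer_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FERTILIZER_FRACTION)
    )
    fertilizer_price: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FERTILIZER_PRICE)
    )

    def __post_init__(self) -> None:
        if not self.bulk_density > 0:
            raise ValueError(f"bulk density must be positive, got {self.bulk_density}")
        if not 0 < self.sediment_fraction <= 1:
            raise ValueError("sediment fraction must lie in (0, 1]")
        for name, frac in self.fertilizer_fraction.items():
            if not 0 < frac <= 1:
                raise ValueError(f"fertilizer fraction for {name} must lie in (0, 1]")


def rusle_retention(
    layers: RusleLayers,
    mask: RasterGrid | None = None,
    bracket: str = "printed",
) -> tuple[float, RasterGrid]:
    """Soil retention Qsr (t·yr⁻¹) and the per-cell retention raster.

    Per-cell retention is R·K·LS·(1-C)·P times cell area; ``bracket``
    selects the cover/practice term: ``"printed"`` uses (1-C)·P, and
    ``"standard"`` the common retention form (1-C·P).
    """
    if bracket not in ("printed", "standard"):
        raise ValueError(f"bracket must be 'printed' or 'standard', got {bracket!r}")
    r = layers.r_factor.filled()
    k = layers.k_factor.filled()
    ls = layers.ls_factor.filled()
    c = layers.c_factor.filled()
    p = layers.p_factor.filled()
    cp = (1.0 - c) * p if bracket == "printed" else 1.0 - c * p
    per_cell = r * k * ls * cp * layers.r_factor.cell_area
    grid = layers.r_factor.with_values(per_cell, nodata=np.nan)
    if mask is not None:
        _require_aligned(layers.r_factor, mask, "rusle_retention")
        sel = (mask.filled(0.0) == 1.0) & np.isfinite(per_cell)
    else:
        sel = np.isfinite(per_cell)
    return float(per_cell[sel].sum()), grid


def sediment_reduction_value(qsr: float, params: SoilValuationParams) -> float:
    """Avoided-siltation value V1 = (Qsr/ρ)·r·β1 (USD).

    Retained mass over bulk density gives the soil volume (m³); the sediment
    fraction is the share that would have reached reservoirs; the reservoir
    cost prices each m³ of capacity saved.
    """
    if qsr < 0:
        raise ValueError("retained soil mass must be non-negative")
    return (qsr / params.bulk_density) * params.sediment_fraction * params.reservoir_cost


def fertilizer_retention_value(
    qsr: float, params: SoilValuationParams
) -> tuple[float, dict[str, float]]:
    """Nutrient-replacement value V2 with its per-nutrient breakdown (USD).

    For each nutrient i: retained nutrient mass Qoi = Qsr·Ci, converted to
    fertilizer-product tonnes via the product's nutrient fraction ri and
    priced at β2_i, so the contribution is (Qoi/ri)·β2_i.
    """
    if qsr < 0:
        raise ValueError("retained soil mass must be non-negative")
    breakdown: dict[str, float] = {}
    for nutrient, content in params.nutrient_content.items():
        try:
            ri = params.fertilizer_fraction[nutrient]
            beta2 = params.fertilizer_price[nutrient]
        except KeyError as exc:
            raise KeyError(f"missing fertilizer parameter for nutrient {nutrient!r}") from exc
        qoi = qsr * content
        breakdown[nutrient] = (qoi / ri) * beta2
    return sum(breakdown.values()), breakdown


def soil_retention_value(
    qsr: float, params: SoilValuationParams
) -> tuple[float, dict[str, float]]:
    """Total soil-retention value Vsr = V1 + V2 with a component report."""
    v1 = sediment_reduction_value(qsr, params)
    v2, breakdown = fertilizer_retention_value(qsr, params)
    report = {"sediment_reduction": v1, "fertilizer_retention": v2, **{f"nutrient_{k}": v for k, v in breakdown.items()}}
    return v1 + v2, report
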