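"""Validated study-area configuration.

Every economic constant of the accounting chain lives here: unit prices,
soil parameters, nutrient contents, grassland areas.  Configs are loaded
from YAML, schema-validated before any computation (unknown keys are
rejected), and nutrient contents given as printed percentages are converted
to mass fractions exactly once, at load time.

``STUDY_AREA_PRESETS`` ships the constants of the three South China Karst
demonstration areas (Salaxi, Hongfenghu, Huajiang) so a desk run needs no
hand-typed numbers; tier prices and the tourism time-cost weight α carry no
defaults and must be stated explicitly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .grazing_diversity import DEFAULT_TIER_BOUNDS, DiversityTierTable, GrazingParams
from .soil import (
    DEFAULT_FERTILIZER_FRACTION,
    DEFAULT_FERTILIZER_PRICE,
    NUTRIENTS,
    SoilValuationParams,
)
from .tourism import TourismParams

__all__ = ["StudyAreaConfig", "load_config", "STUDY_AREA_PRESETS"]

CNY_PER_USD = 7.0467


class StudyAreaConfig(BaseModel):
    """All constants for one study area's GEP account."""

    model_config = ConfigDict(extra="forbid")

    name: str
    # areas (hm²)
    area_natural: float = Field(gt=0)
    area_artificial: float = Field(ge=0)
    total_land_area: float = Field(gt=0)  # whole study area, for tourism apportionment

    # grazing
    gc_natural_pua: float = Field(ge=0)  # cattle/hm²
    gc_artificial_pua: float = Field(ge=0)
    # per-unit capacity may be a potential or a realized stocking figure;
    # when realized figures are supplied, grazing_basis selects which one
    # enters the account (and hence the realized value)
    gc_natural_realized_pua: float | None = Field(default=None, ge=0)
    gc_artificial_realized_pua: float | None = Field(default=None, ge=0)
    grazing_basis: str = "potential"
    cattle_price: float = Field(default=2043.51, gt=0)

    # water
    water_price: float = Field(default=0.43, gt=0)
    velocity_cap: float = Field(default=249.0, gt=0)
    ksat_cap: float = Field(default=300.0, gt=0)
    ti_log_base: str = "10"

    # soil
    bulk_density: float = Field(gt=0)  # t/m³
    sediment_fraction: float = Field(default=0.24, gt=0, le=1)
    reservoir_cost: float = Field(default=5.96, gt=0)
    nutrient_content_percent: dict[str, float]  # printed percentages, e.g. N: 0.2
    fertilizer_fraction: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FERTILIZER_FRACTION)
    )
    fertilizer_price: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FERTILIZER_PRICE)
    )
    rusle_bracket: str = "printed"

    # carbon / oxygen
    dm_to_c: float = Field(default=0.45, gt=0, lt=1)
    karst_rate: float = Field(default=0.2198, gt=0)
    carbon_price: float = Field(default=4.77, gt=0)
    oxygen_price: float = Field(default=207.52, gt=0)
    soc_density: float = Field(ge=0)  # g/m²

    # biodiversity: prices per tier (USD/hm²/yr), one per tier bound
    tier_bounds: tuple[float, ...] = DEFAULT_TIER_BOUNDS
    tier_prices: tuple[float, ...]

    # tourism
    alpha: float = Field(ge=0, le=1)  # no default: must be an explicit choice
    tourism_time_unit: str = "days"

    # accounting
    realized_keys: tuple[str, ...] = ("grazing", "tourism")
    exchange_rate: float = Field(default=CNY_PER_USD, gt=0)

    # bare rock normalization
    ndri_p_low: float = Field(default=1.0, ge=0, lt=100)
    ndri_p_high: float = Field(default=99.0, gt=0, le=100)

    @model_validator(mode="after")
    def _check(self) -> "StudyAreaConfig":
        missing = [n for n in NUTRIENTS if n not in self.nutrient_content_percent]
        if missing:
            raise ValueError(f"nutrient_content_percent missing entries: {missing}")
        if len(self.tier_prices) != len(self.tier_bounds):
            raise ValueError(
                f"need one tier price per bound ({len(self.tier_bounds)}), got {len(self.tier_prices)}"
            )
        if self.rusle_bracket not in ("printed", "standard"):
            raise ValueError("rusle_bracket must be 'printed' or 'standard'")
        if self.ti_log_base not in ("10", "e"):
            raise ValueError("ti_log_base must be '10' or 'e'")
        if self.ndri_p_low >= self.ndri_p_high:
            raise ValueError("ndri_p_low must be below ndri_p_high")
        if self.grazing_basis not in ("potential", "realized"):
            raise ValueError("grazing_basis must be 'potential' or 'realized'")
        if self.grazing_basis == "realized" and (
            self.gc_natural_realized_pua is None or self.gc_artificial_realized_pua is None
        ):
            raise ValueError("grazing_basis 'realized' requires realized per-unit capacities")
        return self

    # -- derived parameter objects -------------------------------------------

    @property
    def grassland_area(self) -> float:
        return self.area_natural + self.area_artificial

    def soil_params(self) -> SoilValuationParams:
        """Soil valuation parameters; percentages become fractions here, once."""
        return SoilValuationParams(
            bulk_density=self.bulk_density,
            sediment_fraction=self.sediment_fraction,
            reservoir_cost=self.reservoir_cost,
            nutrient_content={k: v / 100.0 for k, v in self.nutrient_content_percent.items()},
            fertilizer_fraction=dict(self.fertilizer_fraction),
            fertilizer_price=dict(self.fertilizer_price),
        )

    def grazing_params(self, basis: str | None = None) -> GrazingParams:
        basis = basis or self.grazing_basis
        if basis == "realized":
            ng, ag = self.gc_natural_realized_pua, self.gc_artificial_realized_pua
        else:
            ng, ag = self.gc_natural_pua, self.gc_artificial_pua
        return GrazingParams(
            gc_ng_pua=ng,
            gc_ag_pua=ag,
            area_ng=self.area_natural,
            area_ag=self.area_artificial,
            cattle_price=self.cattle_price,
        )

    def tier_table(self) -> DiversityTierTable:
        return DiversityTierTable(zip(self.tier_bounds, self.tier_prices))

    def tourism_params(self) -> TourismParams:
        return TourismParams(
            alpha=self.alpha,
            grassland_area=self.grassland_area,
            total_area=self.total_land_area,
        )


def load_config(path) -> StudyAreaConfig:
    """Load and validate one study-area YAML config; fail fast on errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return StudyAreaConfig(**raw)


def save_config(cfg: StudyAreaConfig, path) -> None:
    data = cfg.model_dump()
    for key in ("tier_bounds", "tier_prices", "realized_keys"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


#: Printed constants of the three demonstration areas.  Nutrient contents
#: are percentages as printed; tier prices and alpha are still required to
#: build a full config from a preset.
STUDY_AREA_PRESETS: dict[str, dict] = {
    "salaxi": dict(
        name="salaxi",
        area_natural=593.11,
        area_artificial=4.89,
        total_land_area=8627.0,  # 86.27 km²
        bulk_density=1.4,
        nutrient_content_percent={"N": 0.2, "P": 0.031, "K": 1.09, "OM": 40.95},
        soc_density=0.0,  # field-measured input, no printed value
        gc_natural_pua=0.0,
        gc_artificial_pua=0.0,
    ),
    "hongfenghu": dict(
        name="hongfenghu",
        area_natural=95.14,
        area_artificial=17.02,
        total_land_area=6044.0,  # 60.44 km²
        bulk_density=1.45,
        nutrient_content_percent={"N": 0.22, "P": 0.0321, "K": 1.17, "OM": 41.82},
        soc_density=0.0,
        gc_natural_pua=0.0,
        gc_artificial_pua=0.0,
    ),
    "huajiang": dict(
        name="huajiang",
        area_natural=209.27,
        area_artificial=22.09,
        total_land_area=5162.0,  # 51.62 km²
        bulk_density=1.21,
        nutrient_content_percent={"N": 0.35, "P": 0.0325, "K": 1.29, "OM": 42.65},
        soc_density=0.0,
        gc_natural_pua=0.0,
        gc_artificial_pua=0.0,
    ),
}

#: Published headline results used only for cross-validation reports.
PRINTED_RESULTS = {
    "salaxi": {"gep_total": 24.02e6, "gep_per_unit_area": 40160.64, "realization_rate": 16.71},
    "hongfenghu": {"gep_total": 2.84e6, "gep_per_unit_area": 25345.20, "realization_rate": 56.69},
    "huajiang": {"gep_total": 2.75e6, "gep_per_unit_area": 12630.03, "realization_rate": 70.9},
}
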