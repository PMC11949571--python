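"""Four-compartment carbon sequestration and stoichiometric oxygen release.

Carbon is accounted in four compartments: above-ground vegetation,
below-ground vegetation, soil organic carbon, and karst (carbonate
weathering) sequestration:

    QTco2 = Qc1 + Qc2 + Qc3 + Qckarst
    Qc1/Qc2 = 0.45 · area · dry matter (t/hm²)
    Qc3     = SOC density (g/m²) · area (hm²) / 100
    Qckarst = 0.2198 (t/hm²/yr) · area

Oxygen release applies the molar-mass ratio 32/44 to the vegetation
compartments only (photosynthesis releases one O₂ per CO₂ fixed); soil and
karst carbon do not release oxygen.  Carbon is priced at the carbon-trading
market price and oxygen at the industrial oxygen price.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CarbonInputs",
    "CarbonAccount",
    "vegetation_carbon",
    "soil_carbon",
    "karst_carbon",
    "carbon_account",
]

#: O₂/CO₂ molar-mass ratio (32 g/mol over 44 g/mol)
O2_CO2_RATIO = 32.0 / 44.0


@dataclass(frozen=True)
class CarbonInputs:
    """Inputs of the carbon/oxygen account for one grassland stratum.

    ``dry_matter_above``/``dry_matter_below`` are annual dry-matter stocks in
    t/hm², ``soc_density`` in g/m², prices in USD/t.  ``dm_to_c`` converts
    dry matter to sequestered carbon mass; ``karst_rate`` is the carbonate
    weathering sink in t/hm²/yr.
    """

    area: float  # hm²
    dry_matter_above: float  # t/hm²
    dry_matter_below: float  # t/hm²
    soc_density: float  # g/m²
    dm_to_c: float = 0.45
    karst_rate: float = 0.2198  # t/hm²/yr
    carbon_price: float = 4.77  # USD/t
    oxygen_price: float = 207.52  # USD/t
    o2_co2_ratio: float = O2_CO2_RATIO

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")
        if not 0 < self.dm_to_c < 1:
            raise ValueError(f"dry-matter-to-carbon conversion must lie in (0, 1), got {self.dm_to_c}")
        for name in ("karst_rate", "carbon_price", "oxygen_price"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("dry_matter_above", "dry_matter_below", "soc_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CarbonAccount:
    """Carbon compartments (t), oxygen release (t O₂) and their USD values."""

    qc1: float
    qc2: float
    qc3: float
    qckarst: float
    total: float
    value: float
    qop: float
    oxygen_value: float


def vegetation_carbon(area: float, dry_matter: float, dm_to_c: float = 0.45) -> float:
    """Carbon in a vegetation compartment: dm_to_c · area · dry matter (t)."""
    if area < 0 or dry_matter < 0:
        raise ValueError("area and dry matter must be non-negative")
    return dm_to_c * area * dry_matter


def soil_carbon(soc_density: float, area: float) -> float:
    """Soil organic carbon stock in tonnes.

    SOC density (g/m²) times area (hm²) gives g·hm²/m² = 10⁴ g = 0.01 t,
    hence the division by 100.
    """
    if soc_density < 0 or area < 0:
        raise ValueError("inputs must be non-negative")
    return soc_density * area / 100.0


def karst_carbon(area: float, rate: float = 0.2198) -> float:
    """Carbonate-weathering carbon sink: rate (t/hm²/yr) · area (t/yr)."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return rate * area


def carbon_account(inputs: CarbonInputs) -> CarbonAccount:
    """Full carbon + oxygen account for one stratum."""
    qc1 = vegetation_carbon(inputs.area, inputs.dry_matter_above, inputs.dm_to_c)
    qc2 = vegetation_carbon(inputs.area, inputs.dry_matter_below, inputs.dm_to_c)
    qc3 = soil_carbon(inputs.soc_density, inputs.area)
    qck = karst_carbon(inputs.area, inputs.karst_rate)
    total = qc1 + qc2 + qc3 + qck
    qop = inputs.o2_co2_ratio * (qc1 + qc2)
    return CarbonAccount(
        qc1=qc1,
        qc2=qc2,
        qc3=qc3,
        qckarst=qck,
        total=total,
        value=total * inputs.carbon_price,
        qop=qop,
        oxygen_value=qop * inputs.oxygen_price,
    )
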