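"""Assembly of the seven product values into GEP and the realization rate.

GEP (gross ecosystem product) is the exact sum of the seven component
values — grazing, water retention, soil retention, carbon, oxygen,
biodiversity, tourism — all in USD at the fixed 2023 exchange rate.  The
value realization rate is the share already converted to market income;
under the market rule used here only grazing and tourism count as realized:

    RGEPV = 100 · (Vgc + Vglt) / GEPVT
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

__all__ = [
    "COMPONENTS",
    "REALIZED_KEYS",
    "CNY_PER_USD",
    "GepAccount",
    "total_gep",
    "realization_rate",
    "per_unit_area",
    "build_account",
    "validate_account",
]

COMPONENTS = ("grazing", "water", "soil", "carbon", "oxygen", "biodiversity", "tourism")
#: components realized through market transactions (the market rule)
REALIZED_KEYS = frozenset({"grazing", "tourism"})
#: 2023 average exchange rate used for CNY report output
CNY_PER_USD = 7.0467


def _check_components(components: Mapping[str, float]) -> None:
    missing = [k for k in COMPONENTS if k not in components]
    if missing:
        raise KeyError(f"missing GEP component(s): {missing}")
    negative = {k: v for k, v in components.items() if v < 0}
    if negative:
        raise ValueError(f"negative component value(s): {negative}")


def total_gep(components: Mapping[str, float]) -> float:
    """GEPVT: exact sum of the seven component values (USD)."""
    _check_components(components)
    return sum(components[k] for k in COMPONENTS)


def realization_rate(
    components: Mapping[str, float], realized_keys: frozenset[str] = REALIZED_KEYS
) -> float:
    """Value realization rate RGEPV = 100·GEPVR/GEPVT, in percent."""
    total = total_gep(components)
    if total <= 0:
        raise ValueError("undefined rate: total GEP is zero")
    realized = sum(components[k] for k in realized_keys)
    return 100.0 * realized / total


def per_unit_area(total: float, area: float) -> float:
    """GEP per unit area (USD/hm²)."""
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    return total / area


@dataclass
class GepAccount:
    """Per-study-area account: components, totals, rate and shares.

    All USD at full precision; rounding happens only in reports.
    """

    components: dict[str, float]
    grassland_area: float
    realized_keys: tuple[str, ...] = tuple(sorted(REALIZED_KEYS))
    gep_total: float = field(init=False)
    realized: float = field(init=False)
    realization_rate: float = field(init=False)
    gep_per_unit_area: float = field(init=False)
    component_shares: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.gep_total = total_gep(self.components)
        self.realized = sum(self.components[k] for k in self.realized_keys)
        self.realization_rate = realization_rate(self.components, frozenset(self.realized_keys))
        self.gep_per_unit_area = per_unit_area(self.gep_total, self.grassland_area)
        self.component_shares = {k: self.components[k] / self.gep_total for k in COMPONENTS}

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, payload: str) -> "GepAccount":
        data = json.loads(payload)
        return cls(
            components=data["components"],
            grassland_area=data["grassland_area"],
            realized_keys=tuple(data["realized_keys"]),
        )

    def in_cny(self) -> dict[str, float]:
        """Report-time currency conversion of the monetary fields."""
        return {
            "gep_total_cny": self.gep_total * CNY_PER_USD,
            "realized_cny": self.realized * CNY_PER_USD,
            "gep_per_unit_area_cny": self.gep_per_unit_area * CNY_PER_USD,
        }


def build_account(
    components: Mapping[str, float],
    grassland_area: float,
    realized_keys: frozenset[str] = REALIZED_KEYS,
) -> GepAccount:
    """Construct a :class:`GepAccount`, validating components."""
    return GepAccount(
        components=dict(components),
        grassland_area=grassland_area,
        realized_keys=tuple(sorted(realized_keys)),
    )


def validate_account(
    account: GepAccount,
    printed_total: float | None = None,
    printed_per_unit_area: float | None = None,
    rel_tol: float = 5e-3,
) -> dict:
    """Cross-check an account against itself and optional printed figures.

    Returns a validation report listing each check with pass/fail; internal
    inconsistencies (e.g. a printed total that disagrees with printed
    per-unit value × area) are flagged, never silently resolved.
    """
    checks: list[dict] = []

    def add(name: str, ok: bool, detail: str) -> None:
        checks.append({"check": name, "pass": bool(ok), "detail": detail})

    comp_sum = sum(account.components[k] for k in COMPONENTS)
    add("total_equals_component_sum", comp_sum == account.gep_total,
        f"sum={comp_sum!r} total={account.gep_total!r}")
    add("rate_in_range", 0.0 <= account.realization_rate <= 100.0,
        f"rate={account.realization_rate:.4f}%")
    share_sum = sum(account.component_shares.values())
    add("shares_sum_to_one", abs(share_sum - 1.0) <= 1e-9, f"share_sum={share_sum!r}")
    pua_product = account.gep_per_unit_area * account.grassland_area
    add("pua_times_area_equals_total",
        abs(pua_product - account.gep_total) <= 1e-6 * max(1.0, abs(account.gep_total)),
        f"pua*area={pua_product!r}")

    if printed_total is not None:
        rel = abs(account.gep_total - printed_total) / printed_total
        add("matches_printed_total", rel <= rel_tol,
            f"computed={account.gep_total:.2f} printed={printed_total:.2f} rel_err={rel:.4g}")
    if printed_per_unit_area is not None:
        rel = abs(account.gep_per_unit_area - printed_per_unit_area) / printed_per_unit_area
        add("matches_printed_per_unit_area", rel <= rel_tol,
            f"computed={account.gep_per_unit_area:.2f} printed={printed_per_unit_area:.2f} rel_err={rel:.4g}")
    if printed_total is not None and printed_per_unit_area is not None:
        implied = printed_per_unit_area * account.grassland_area
        rel = abs(implied - printed_total) / printed_total
        add("printed_figures_internally_consistent", rel <= rel_tol,
            f"printed_pua*area={implied:.2f} printed_total={printed_total:.2f} rel_err={rel:.4g}")

    return {"checks": checks, "all_pass": all(c["pass"] for c in checks)}
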