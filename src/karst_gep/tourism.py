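"""Travel-cost landscape-tourism value and its grassland apportionment.

Visitors are grouped into origin-zone segments.  Each segment's per-person
time cost is the daily wage times trips times total time committed
(foregone work + travel + on-site), and the study area's tourism value is

    Vlt = Σ_i qi · (Ci + α·Wi)

with direct spend Ci and a time-cost weight α ∈ [0, 1] that must be chosen
explicitly (it has no defensible default).  Because the study area mixes
grassland with forest and cropland, the grassland share is apportioned by
land area: Vglt = (Ag/A)·Vlt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "TouristSegment",
    "TourismParams",
    "time_cost",
    "total_tourism_value",
    "grassland_tourism_value",
]

_HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class TouristSegment:
    """One origin zone's visitors and their cost structure.

    Times are in days by default; pass ``time_unit='hours'`` to convert.
    ``wage_rate`` is the daily rate (annual wage / 365, computed upstream).
    """

    visitors: float  # persons (qi)
    direct_spend: float  # USD per person (Ci)
    wage_rate: float  # USD per day (Pi)
    trips: float = 1.0  # r
    foregone_work: float = 0.0  # Tw, days
    travel_time: float = 0.0  # T1, days
    onsite_time: float = 0.0  # T2, days
    time_unit: str = "days"

    def __post_init__(self) -> None:
        for name in (
            "visitors", "direct_spend", "wage_rate", "trips",
            "foregone_work", "travel_time", "onsite_time",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.time_unit not in ("days", "hours"):
            raise ValueError(f"time_unit must be 'days' or 'hours', got {self.time_unit!r}")

    def _days(self, value: float) -> float:
        return value / _HOURS_PER_DAY if self.time_unit == "hours" else value


@dataclass(frozen=True)
class TourismParams:
    """Time-cost weight α and the land areas used for apportionment."""

    alpha: float
    grassland_area: float  # hm² (Ag)
    total_area: float  # hm² (A)

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.total_area > 0:
            raise ValueError("total area must be positive")
        if not 0 <= self.grassland_area <= self.total_area:
            raise ValueError("grassland area must lie in [0, total area]")


def time_cost(segment: TouristSegment) -> float:
    """Per-person time cost Wi = Pi · r · (Tw + T1 + T2), USD."""
    days = (
        segment._days(segment.foregone_work)
        + segment._days(segment.travel_time)
        + segment._days(segment.onsite_time)
    )
    return segment.wage_rate * segment.trips * days


def total_tourism_value(segments: Iterable[TouristSegment], params: TourismParams) -> float:
    """Study-area tourism value Vlt = Σ qi·(Ci + α·Wi), USD."""
    segs = list(segments)
    if not segs:
        raise ValueError("total_tourism_value needs at least one segment")
    return sum(s.visitors * (s.direct_spend + params.alpha * time_cost(s)) for s in segs)


def grassland_tourism_value(vlt: float, params: TourismParams) -> float:
    """Grassland share of tourism value: (Ag/A)·Vlt."""
    if vlt < 0:
        raise ValueError("tourism value must be non-negative")
    return (params.grassland_area / params.total_area) * vlt
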