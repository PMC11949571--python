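"""Synthetic study areas along a karst desertification gradient.

The generator emits, for each of three areas, the complete input bundle the
accounting pipeline consumes — an aligned raster stack, plot survey and
village indicator tables, tourist segments, and a validated config — with
the statistical structure the analysis assumes:

* a desertification gradient across areas: rising bare-rock fraction and
  temperature, thinning soil, falling plot diversity, rising artificial-
  grassland share of value, and monotonically decreasing water and soil
  retention;
* plot species counts drawn from a multinomial whose underlying abundance
  distribution is tuned (geometric-series + bisection) so the mean Shannon
  index hits the area's target;
* village tables in which the realization rate depends on two planted
  drivers plus noise, so driver-recovery is testable.

Defaults are anchored to the three South China Karst demonstration areas:
precipitation/temperature/elevation from their published descriptions,
Shannon targets 1.22/0.88/0.40, and per-area mean water retention near
37/31/25 mm and soil retention near 500/140/35 t/hm² so the gradient
ordering is unambiguous at the default raster size.

Randomness: one global seed fans out to independent substreams through
``numpy.random.SeedSequence`` spawn keys ``(area_index, stream_id)``, so
adding a new output never perturbs existing ones and every file is
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import StudyAreaConfig, save_config
from .geodata import RasterGrid, write_raster

__all__ = [
    "SyntheticSpec", "AreaBundle", "generate_area", "generate_villages",
    "driver_study_spec", "known_truth",
]

# stream ids for the counter-based seeding scheme; append-only
_STREAMS = {
    "precip": 0, "aet": 1, "ksat": 2, "drainage": 3, "soil_depth": 4,
    "slope": 5, "landcover": 6, "bands": 7, "rusle": 8,
    "plots": 9, "villages": 10, "tourists": 11,
}

LANDCOVER_OTHER, LANDCOVER_NATURAL, LANDCOVER_ARTIFICIAL = 0, 1, 2


@dataclass(frozen=True)
class AreaParams:
    """Per-area gradient parameters (one desertification stage)."""

    name: str
    precip_mean: float  # mm/yr
    temp_mean: float  # °C
    elevation_mean: float  # m
    aet_fraction: float  # AET/P ratio
    soil_depth_mean: float  # cm
    bare_rock_target: float  # fraction
    shannon_natural: float
    shannon_artificial: float
    area_natural: float  # hm²
    area_artificial: float  # hm²
    total_land_area: float  # hm²
    gc_natural_pua: float  # cattle/hm²
    gc_artificial_pua: float
    bulk_density: float
    nutrient_content_percent: dict[str, float]
    soc_density: float  # g/m²
    dry_matter_above: dict[str, float]  # t/hm² per stratum {"natural","artificial"}
    dry_matter_below: dict[str, float]
    velocity_by_class: dict[int, float]
    ksat_mean: float  # mm/d
    rusle_r_mean: float
    rusle_k_mean: float
    rusle_ls_mean: float
    rusle_c_mean: float
    rusle_p_mean: float
    n_villages: int
    n_tourist_segments: int
    visitors_scale: float  # persons per segment


def _default_areas() -> tuple[AreaParams, ...]:
    return (
        AreaParams(
            name="area_potential_light",
            precip_mean=984.4, temp_mean=12.8, elevation_mean=1878.0,
            aet_fraction=0.60, soil_depth_mean=40.0, bare_rock_target=0.12,
            shannon_natural=1.22, shannon_artificial=0.95,
            area_natural=593.11, area_artificial=4.89, total_land_area=8627.0,
            gc_natural_pua=6.9, gc_artificial_pua=12.0,
            bulk_density=1.4,
            nutrient_content_percent={"N": 0.2, "P": 0.031, "K": 1.09, "OM": 40.95},
            soc_density=12000.0,
            dry_matter_above={"natural": 2.9, "artificial": 7.2},
            dry_matter_below={"natural": 1.9, "artificial": 4.8},
            velocity_by_class={0: 1400.0, 1: 700.0, 2: 650.0},
            ksat_mean=85.0,
            rusle_r_mean=400.0, rusle_k_mean=0.35, rusle_ls_mean=6.0,
            rusle_c_mean=0.30, rusle_p_mean=0.85,
            n_villages=9, n_tourist_segments=4, visitors_scale=600.0,
        ),
        AreaParams(
            name="area_light_moderate",
            precip_mean=1192.5, temp_mean=15.5, elevation_mean=1300.0,
            aet_fraction=0.65, soil_depth_mean=25.0, bare_rock_target=0.30,
            shannon_natural=0.88, shannon_artificial=0.62,
            area_natural=95.14, area_artificial=17.02, total_land_area=6044.0,
            gc_natural_pua=9.5, gc_artificial_pua=15.0,
            bulk_density=1.45,
            nutrient_content_percent={"N": 0.22, "P": 0.0321, "K": 1.17, "OM": 41.82},
            soc_density=20000.0,
            dry_matter_above={"natural": 3.6, "artificial": 15.0},
            dry_matter_below={"natural": 2.4, "artificial": 10.0},
            velocity_by_class={0: 1800.0, 1: 950.0, 2: 900.0},
            ksat_mean=75.0,
            rusle_r_mean=430.0, rusle_k_mean=0.30, rusle_ls_mean=2.3,
            rusle_c_mean=0.45, rusle_p_mean=0.85,
            n_villages=6, n_tourist_segments=4, visitors_scale=2500.0,
        ),
        AreaParams(
            name="area_medium_severe",
            precip_mean=1100.0, temp_mean=18.4, elevation_mean=947.0,
            aet_fraction=0.70, soil_depth_mean=15.0, bare_rock_target=0.50,
            shannon_natural=0.40, shannon_artificial=0.25,
            area_natural=209.27, area_artificial=22.09, total_land_area=5162.0,
            gc_natural_pua=8.0, gc_artificial_pua=16.3,
            bulk_density=1.21,
            nutrient_content_percent={"N": 0.35, "P": 0.0325, "K": 1.29, "OM": 42.65},
            soc_density=16000.0,
            dry_matter_above={"natural": 3.1, "artificial": 12.0},
            dry_matter_below={"natural": 2.1, "artificial": 8.0},
            velocity_by_class={0: 2600.0, 1: 1300.0, 2: 1250.0},
            ksat_mean=60.0,
            rusle_r_mean=420.0, rusle_k_mean=0.25, rusle_ls_mean=0.93,
            rusle_c_mean=0.55, rusle_p_mean=0.80,
            n_villages=6, n_tourist_segments=4, visitors_scale=4500.0,
        ),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic world; defaults ARE the study conditions."""

    seed: int = 42
    n_rows: int = 100
    n_cols: int = 100
    cell_area: float = 0.01  # 10 m cells
    n_plots_per_stratum: int = 15
    n_quadrats: int = 3
    individuals_per_quadrat: int = 120
    species_pool: int = 12
    plot_biomass_cv: float = 0.15
    village_noise_sd: float = 3.0  # on the VRR scale (percent points)
    planted_drivers: tuple[str, ...] = ("AAP", "AA")
    alpha: float = 0.5
    tier_bounds: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    tier_prices: tuple[float, ...] = (40.0, 120.0, 300.0, 500.0)
    areas: tuple[AreaParams, ...] = field(default_factory=_default_areas)

    def __post_init__(self) -> None:
        for a in self.areas:
            for h in (a.shannon_natural, a.shannon_artificial):
                if h > math.log(self.species_pool):
                    raise ValueError(
                        f"Shannon target {h} infeasible for a {self.species_pool}-species pool "
                        f"(max {math.log(self.species_pool):.4f})"
                    )
                if h < 0:
                    raise ValueError("Shannon target must be non-negative")
            if not 0 <= a.bare_rock_target <= 1:
                raise ValueError("bare-rock target must be a fraction")

    @property
    def n_areas(self) -> int:
        return len(self.areas)


@dataclass
class AreaBundle:
    """In-memory synthetic bundle for one area (what :func:`generate_area` wrote)."""

    params: AreaParams
    config: StudyAreaConfig
    rasters: dict[str, RasterGrid]
    plots: pd.DataFrame
    villages: pd.DataFrame
    tourists: pd.DataFrame
    out_dir: Path | None = None


# -- random-field helpers ----------------------------------------------------


def _rng(spec: SyntheticSpec, area_index: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(spec.seed, spawn_key=(area_index, _STREAMS[stream]))
    return np.random.default_rng(ss)


def _smooth_field(rng, shape, mean, rel_sd, sigma=4.0, clip_lo=None, clip_hi=None):
    """Smooth gaussian random field with given mean and relative SD."""
    white = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    sm /= max(sm.std(), 1e-12)
    out = mean * (1.0 + rel_sd * sm)
    if clip_lo is not None or clip_hi is not None:
        out = np.clip(out, clip_lo, clip_hi)
    return out


def _f32(values: np.ndarray) -> np.ndarray:
    """Round-trip through float32 so in-memory truth equals on-disk rasters."""
    return values.astype(np.float32).astype(float)


# -- Shannon tuning ----------------------------------------------------------


def geometric_abundance(n_species: int, target_h: float) -> np.ndarray:
    """Abundance distribution p_i ∝ exp(-λ·i) with Shannon entropy = target.

    λ is found by bisection; λ=0 gives the uniform maximum ln(S), large λ a
    single-species community (H→0).
    """
    if not 0 <= target_h <= math.log(n_species) + 1e-12:
        raise ValueError(f"target {target_h} outside [0, ln {n_species}]")

    def entropy(lam: float) -> float:
        w = np.exp(-lam * np.arange(n_species))
        p = w / w.sum()
        return float(-(p * np.log(p)).sum())

    lo, hi = 0.0, 1.0
    while entropy(hi) > target_h:
        hi *= 2.0
        if hi > 1e4:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if entropy(mid) > target_h:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    w = np.exp(-lam * np.arange(n_species))
    return w / w.sum()


# -- per-area generation -----------------------------------------------------


def _generate_rasters(spec: SyntheticSpec, i: int, p: AreaParams) -> dict[str, RasterGrid]:
    shape = (spec.n_rows, spec.n_cols)

    def grid(values, nodata=None):
        return RasterGrid(_f32(values), cell_area=spec.cell_area, nodata=nodata,
                          crs_tag=f"synthetic-utm48n-{p.name}")

    rng = _rng(spec, i, "precip")
    precip = _smooth_field(rng, shape, p.precip_mean, 0.03, clip_lo=1.0)
    rng = _rng(spec, i, "aet")
    aet_ratio = np.clip(_smooth_field(rng, shape, p.aet_fraction, 0.05), 0.05, 0.98)
    aet = precip * aet_ratio

    rng = _rng(spec, i, "ksat")
    ksat = _smooth_field(rng, shape, p.ksat_mean, 0.20, clip_lo=1.0)
    rng = _rng(spec, i, "drainage")
    # catchment areas: lognormal around 10⁴ hm², keeping the topographic
    # index in its informative (unsaturated) range for 15-40 cm soils
    drainage = np.exp(_smooth_field(rng, shape, math.log(1.0e4), 0.04))
    rng = _rng(spec, i, "soil_depth")
    soil_depth = _smooth_field(rng, shape, p.soil_depth_mean, 0.15, clip_lo=2.0)
    rng = _rng(spec, i, "slope")
    slope = _smooth_field(rng, shape, 20.0, 0.25, clip_lo=2.0, clip_hi=60.0)

    # land cover: grassland where a smooth latent field is high; artificial
    # grassland the top slice of that, with share growing along the gradient
    rng = _rng(spec, i, "landcover")
    latent = _smooth_field(rng, shape, 0.0, 1.0, sigma=8.0)
    ag_share = p.area_artificial / (p.area_natural + p.area_artificial)
    grass_frac = 0.45
    thr_grass = np.quantile(latent, 1.0 - grass_frac)
    thr_ag = np.quantile(latent, 1.0 - grass_frac * ag_share)
    landcover = np.where(latent >= thr_ag, LANDCOVER_ARTIFICIAL,
                         np.where(latent >= thr_grass, LANDCOVER_NATURAL, LANDCOVER_OTHER))

    # spectral bands: build an NDRI field whose level tracks the bare-rock
    # target, then back out band8 from a constant-ish green band
    rng = _rng(spec, i, "bands")
    # rock-cover field as a Beta-marginal smooth field: a Gaussian field is
    # pushed through the Beta(5t, 5(1-t)) quantile map so the distribution's
    # mean AND shape track the bare-rock target — after per-raster percentile
    # stretching the recovered fraction still rises along the gradient
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0, mode="reflect")
    z /= max(z.std(), 1e-12)
    t = min(max(p.bare_rock_target, 0.02), 0.98)
    from scipy import stats as _stats
    rock = _stats.beta.ppf(_stats.norm.cdf(z), 5.0 * t, 5.0 * (1.0 - t))
    ndri = -0.25 + 0.85 * rock  # in (-0.25, 0.60)
    band3 = np.clip(_smooth_field(rng, shape, 0.10, 0.10), 0.01, None)
    band8 = band3 * (1.0 + ndri) / (1.0 - ndri)

    rng = _rng(spec, i, "rusle")
    r_f = _smooth_field(rng, shape, p.rusle_r_mean, 0.10, clip_lo=0.0)
    k_f = _smooth_field(rng, shape, p.rusle_k_mean, 0.10, clip_lo=0.0)
    ls_f = _smooth_field(rng, shape, p.rusle_ls_mean, 0.20, clip_lo=0.0)
    c_f = np.clip(_smooth_field(rng, shape, p.rusle_c_mean, 0.15), 0.0, 1.0)
    p_f = np.clip(_smooth_field(rng, shape, p.rusle_p_mean, 0.08), 0.0, 1.0)

    return {
        "precip": grid(precip),
        "aet": grid(aet),
        "ksat": grid(ksat),
        "drainage_area": grid(drainage),
        "soil_depth": grid(soil_depth),
        "slope_pct": grid(slope),
        "landcover": grid(landcover.astype(float)),
        "band3": grid(band3),
        "band8": grid(band8),
        "r_factor": grid(r_f),
        "k_factor": grid(k_f),
        "ls_factor": grid(ls_f),
        "c_factor": grid(c_f),
        "p_factor": grid(p_f),
    }


def _generate_plots(spec: SyntheticSpec, i: int, p: AreaParams) -> pd.DataFrame:
    rng = _rng(spec, i, "plots")
    rows = []
    species_names = [f"sp{j:02d}" for j in range(spec.species_pool)]
    for stratum, target in (("natural", p.shannon_natural), ("artificial", p.shannon_artificial)):
        probs = geometric_abundance(spec.species_pool, target)
        dm_above = p.dry_matter_above[stratum]
        dm_below = p.dry_matter_below[stratum]
        for plot in range(spec.n_plots_per_stratum):
            plot_id = f"{p.name}-{stratum[:3]}-{plot:02d}"
            for quadrat in range(spec.n_quadrats):
                counts = rng.multinomial(spec.individuals_per_quadrat, probs)
                # quadrat biomass, g per 1 m²; dry matter t/hm² = g/m² × 0.01
                fresh_above = max(rng.normal(dm_above / 0.01 / 0.35, spec.plot_biomass_cv * dm_above / 0.01 / 0.35), 1.0)
                dry_above = fresh_above * 0.35
                fresh_below = max(rng.normal(dm_below / 0.01 / 0.30, spec.plot_biomass_cv * dm_below / 0.01 / 0.30), 1.0)
                dry_below = fresh_below * 0.30
                for sp, n in zip(species_names, counts):
                    if n == 0:
                        continue
                    rows.append({
                        "study_area": p.name, "plot_id": plot_id, "quadrat": quadrat,
                        "grassland_type": stratum, "species": sp, "count": int(n),
                        "fresh_above_g": fresh_above, "dry_above_g": dry_above,
                        "fresh_below_g": fresh_below, "dry_below_g": dry_below,
                    })
    return pd.DataFrame(rows)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _generate_villages(spec: SyntheticSpec, i: int, p: AreaParams) -> pd.DataFrame:
    rng = _rng(spec, i, "villages")
    n = p.n_villages
    df = pd.DataFrame({
        "village": [f"{p.name}-v{j:02d}" for j in range(n)],
        "study_area": p.name,
        "GAR": np.clip(rng.normal(0.20, 0.06, n), 0.02, 0.6),
        "AGR": np.clip(rng.normal(p.area_artificial / (p.area_natural + p.area_artificial), 0.03, n), 0.0, 1.0),
        # village means vary widely within an area: karst relief spans
        # hundreds of metres of elevation, with orographic precipitation
        "AA": rng.normal(p.elevation_mean, 350.0, n),
        "AAP": rng.normal(p.precip_mean, 130.0, n),
        "AAT": rng.normal(p.temp_mean, 0.6, n),
        "GPD": np.clip(rng.normal(1.8, 0.5, n), 0.2, None),
        "BRRG": np.clip(rng.normal(p.bare_rock_target, 0.05, n), 0.0, 1.0),
        "PD": np.clip(rng.normal(260.0, 70.0, n), 20.0, None),
        "PCDIF": np.clip(rng.normal(1800.0, 350.0, n), 300.0, None),
        "DC": np.clip(rng.normal(18.0, 6.0, n), 1.0, None),
        "DTA": np.clip(rng.normal(12.0, 5.0, n), 0.5, None),
        "PMW": np.clip(rng.normal(0.35, 0.08, n), 0.02, 0.9),
        "PPLF": np.clip(rng.normal(0.22, 0.07, n), 0.01, 0.8),
    })
    return df


def plant_dependent_variables(
    spec: SyntheticSpec, villages: pd.DataFrame, seed: int | None = None
) -> pd.DataFrame:
    """Attach GEP_PUA and VRR columns driven by the planted drivers + noise.

    The dependence is linear in the standardized planted columns with
    coefficients (12, 8) on the VRR percent scale, strong against the
    ``village_noise_sd`` default so recovery is a property of the method,
    not luck.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed if seed is None else seed, spawn_key=(999, 0))
    )
    out = villages.copy()
    d1, d2 = spec.planted_drivers
    z1 = _standardize(out[d1].to_numpy(float))
    z2 = _standardize(out[d2].to_numpy(float))
    n = len(out)
    out["VRR"] = np.clip(45.0 + 12.0 * z1 + 8.0 * z2 + rng.normal(0, spec.village_noise_sd, n), 0.0, 100.0)
    out["GEP_PUA"] = np.clip(
        25000.0 + 6000.0 * z1 + 4000.0 * z2 + rng.normal(0, 400.0 * spec.village_noise_sd, n),
        1000.0, None,
    )
    return out


def generate_villages(spec: SyntheticSpec, seed: int | None = None) -> pd.DataFrame:
    """Pooled village table across all areas, with planted dependents."""
    frames = [_generate_villages(spec, i, p) for i, p in enumerate(spec.areas)]
    pooled = pd.concat(frames, ignore_index=True)
    return plant_dependent_variables(spec, pooled, seed=seed)


def driver_study_spec(seed: int, villages_per_area: int = 30) -> SyntheticSpec:
    """Spec variant sized for driver-recovery simulation.

    The surveyed design of the real areas (9/6/6 villages) is too small for
    impurity-based importance to attribute even a noiseless signal reliably;
    recovery simulations therefore run at 30 villages per area, where
    attribution is limited by the method rather than by sampling noise.
    """
    base = SyntheticSpec(seed=seed)
    areas = tuple(replace(a, n_villages=villages_per_area) for a in base.areas)
    return replace(base, areas=areas)


def _generate_tourists(spec: SyntheticSpec, i: int, p: AreaParams) -> pd.DataFrame:
    rng = _rng(spec, i, "tourists")
    rows = []
    for s in range(p.n_tourist_segments):
        rows.append({
            "origin_zone": f"zone{s}",
            "visitors": float(np.round(rng.normal(p.visitors_scale, 0.2 * p.visitors_scale))),
            "direct_spend": float(np.round(rng.uniform(15.0, 60.0), 2)),
            "wage_rate": float(np.round(rng.uniform(10.0, 40.0), 2)),
            "trips": 1.0,
            "foregone_work": float(np.round(rng.uniform(0.0, 1.0), 2)),
            "travel_time": float(np.round(rng.uniform(0.1, 1.0), 2)),
            "onsite_time": float(np.round(rng.uniform(0.2, 2.0), 2)),
        })
    df = pd.DataFrame(rows)
    df["visitors"] = df["visitors"].clip(lower=10.0)
    return df


def _area_config(spec: SyntheticSpec, p: AreaParams) -> StudyAreaConfig:
    return StudyAreaConfig(
        name=p.name,
        area_natural=p.area_natural,
        area_artificial=p.area_artificial,
        total_land_area=p.total_land_area,
        gc_natural_pua=p.gc_natural_pua,
        gc_artificial_pua=p.gc_artificial_pua,
        bulk_density=p.bulk_density,
        nutrient_content_percent=dict(p.nutrient_content_percent),
        soc_density=p.soc_density,
        tier_bounds=spec.tier_bounds,
        tier_prices=spec.tier_prices,
        alpha=spec.alpha,
    )


def generate_area(spec: SyntheticSpec, area_index: int, out_dir=None) -> AreaBundle:
    """Generate one area's full input bundle; optionally write it to disk.

    On disk the bundle is the exact layout the pipeline consumes: one TIFF
    per raster, ``plots.csv``, ``villages.csv``, ``tourists.csv``,
    ``velocity_by_class.csv`` and ``config.yaml``.
    """
    if not 0 <= area_index < spec.n_areas:
        raise IndexError(f"area_index {area_index} out of range 0..{spec.n_areas - 1}")
    p = spec.areas[area_index]
    rasters = _generate_rasters(spec, area_index, p)
    plots = _generate_plots(spec, area_index, p)
    villages = plant_dependent_variables(spec, _generate_villages(spec, area_index, p))
    tourists = _generate_tourists(spec, area_index, p)
    cfg = _area_config(spec, p)
    bundle = AreaBundle(params=p, config=cfg, rasters=rasters, plots=plots,
                        villages=villages, tourists=tourists)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, grid in rasters.items():
            write_raster(out / f"{name}.tif", grid)
        plots.to_csv(out / "plots.csv", index=False)
        villages.to_csv(out / "villages.csv", index=False)
        tourists.to_csv(out / "tourists.csv", index=False)
        pd.DataFrame(
            [{"class_code": k, "velocity": v} for k, v in sorted(p.velocity_by_class.items())]
        ).to_csv(out / "velocity_by_class.csv", index=False)
        save_config(cfg, out / "config.yaml")
        bundle.out_dir = out
    return bundle


# -- generator-side truth ----------------------------------------------------


def known_truth(spec: SyntheticSpec, area_index: int):
    """The generator's own closed-form GEP account for one area.

    Computed directly from the fields the generator drew (rasters already
    quantized to float32, realized plot and tourist tables), so a correct
    pipeline run over the written bundle must agree to float precision.
    Imports locally to stay independent of pipeline wiring.
    """
    from . import accounting
    from .carbon_oxygen import CarbonInputs, carbon_account
    from .grazing_diversity import (
        grazing_capacity, grazing_value, plot_mean_index, shannon_index,
    )
    from .hydrology import HydroLayers, WaterPrice, water_retention, water_retention_value
    from .soil import RusleLayers, rusle_retention, soil_retention_value
    from .tourism import TouristSegment, grassland_tourism_value, total_tourism_value

    p = spec.areas[area_index]
    cfg = _area_config(spec, p)
    rasters = _generate_rasters(spec, area_index, p)
    plots = _generate_plots(spec, area_index, p)
    tourists = _generate_tourists(spec, area_index, p)

    lc = rasters["landcover"]
    mask = lc.with_values((np.isin(lc.values, [LANDCOVER_NATURAL, LANDCOVER_ARTIFICIAL])).astype(float))
    vel_values = np.zeros_like(lc.values)
    for code, v in p.velocity_by_class.items():
        vel_values[lc.values == code] = v
    velocity = lc.with_values(_f32(vel_values))

    # water
    layers = HydroLayers(
        precip=rasters["precip"], aet=rasters["aet"], velocity=velocity,
        ksat=rasters["ksat"], drainage_area=rasters["drainage_area"],
        soil_depth=rasters["soil_depth"], slope_pct=rasters["slope_pct"],
        velocity_cap=cfg.velocity_cap, ksat_cap=cfg.ksat_cap, log_base=cfg.ti_log_base,
    )
    wr = water_retention(layers)
    v_water, _ = water_retention_value(wr, mask, WaterPrice(cfg.water_price))

    # soil
    rusle = RusleLayers(
        r_factor=rasters["r_factor"], k_factor=rasters["k_factor"],
        ls_factor=rasters["ls_factor"], c_factor=rasters["c_factor"],
        p_factor=rasters["p_factor"],
    )
    qsr, _ = rusle_retention(rusle, mask, bracket=cfg.rusle_bracket)
    v_soil, _ = soil_retention_value(qsr, cfg.soil_params())

    # carbon + oxygen from realized plot biomass
    v_carbon = v_oxygen = 0.0
    strata = {"natural": cfg.area_natural, "artificial": cfg.area_artificial}
    quadrats = plots.drop_duplicates(["plot_id", "quadrat"])
    for stratum, area in strata.items():
        sub = quadrats[quadrats["grassland_type"] == stratum]
        dm_above = sub["dry_above_g"].mean() * 0.01  # g/m² -> t/hm²
        dm_below = sub["dry_below_g"].mean() * 0.01
        acct = carbon_account(CarbonInputs(
            area=area, dry_matter_above=dm_above, dry_matter_below=dm_below,
            soc_density=cfg.soc_density, dm_to_c=cfg.dm_to_c, karst_rate=cfg.karst_rate,
            carbon_price=cfg.carbon_price, oxygen_price=cfg.oxygen_price,
        ))
        v_carbon += acct.value
        v_oxygen += acct.oxygen_value

    # grazing
    gc = grazing_capacity(cfg.grazing_params())
    v_grazing = grazing_value(gc, cfg.cattle_price)

    # biodiversity from realized counts
    tiers = cfg.tier_table()
    area_by_stratum = {}
    for stratum, area in strata.items():
        sub = plots[plots["grassland_type"] == stratum]
        plot_indices = []
        for _, plot_df in sub.groupby("plot_id"):
            qs = [shannon_index(q["count"].to_numpy()) for _, q in plot_df.groupby("quadrat")]
            plot_indices.append(plot_mean_index(qs))
        area_by_stratum[stratum] = (area, float(np.mean(plot_indices)))
    from .grazing_diversity import biodiversity_value
    v_bio = biodiversity_value(area_by_stratum, tiers)

    # tourism
    tp = cfg.tourism_params()
    segments = [
        TouristSegment(
            visitors=r.visitors, direct_spend=r.direct_spend, wage_rate=r.wage_rate,
            trips=r.trips, foregone_work=r.foregone_work, travel_time=r.travel_time,
            onsite_time=r.onsite_time, time_unit=cfg.tourism_time_unit,
        )
        for r in tourists.itertuples()
    ]
    v_tourism = grassland_tourism_value(total_tourism_value(segments, tp), tp)

    components = {
        "grazing": v_grazing, "water": v_water, "soil": v_soil,
        "carbon": v_carbon, "oxygen": v_oxygen,
        "biodiversity": v_bio, "tourism": v_tourism,
    }
    return accounting.build_account(components, cfg.grassland_area,
                                    frozenset(cfg.realized_keys))
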