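"""End-to-end orchestration: input bundle on disk → GEP account.

A bundle directory holds one TIFF per raster layer, the plot, village and
tourist CSV tables, a velocity lookup (land-cover class → flow coefficient)
and a validated ``config.yaml``.  :func:`run_area` reads everything, runs
the seven valuation chains, and assembles the account;
:func:`run_pipeline` maps it over the per-area subdirectories and writes
JSON reports plus a validation report of structural cross-checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import accounting
from .carbon_oxygen import CarbonInputs, carbon_account
from .config import StudyAreaConfig, load_config
from .geodata import NdriNormalization, RasterGrid, bare_rock_fraction, compute_ndri, read_raster, zonal_mean
from .grazing_diversity import (
    biodiversity_value, grazing_capacity, grazing_value, plot_mean_index, shannon_index,
)
from .hydrology import HydroLayers, WaterPrice, water_retention, water_retention_value
from .soil import RusleLayers, rusle_retention, soil_retention_value
from .tourism import TouristSegment, grassland_tourism_value, total_tourism_value

logger = logging.getLogger(__name__)

__all__ = ["run_area", "run_pipeline", "AreaResult"]

RASTER_LAYERS = (
    "precip", "aet", "ksat", "drainage_area", "soil_depth", "slope_pct",
    "landcover", "band3", "band8",
    "r_factor", "k_factor", "ls_factor", "c_factor", "p_factor",
)

GRASSLAND_CODES = (1, 2)  # natural, artificial


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def plot_stratum_summary(plots: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum mean dry matter (t/hm²) and mean plot Shannon index.

    One biomass observation per quadrat (species rows repeat it); the
    Shannon index is computed per quadrat, averaged to the plot, then
    averaged over plots.
    """
    out = []
    for stratum, sub in plots.groupby("grassland_type", sort=True):
        quadrats = sub.drop_duplicates(["plot_id", "quadrat"])
        plot_indices = []
        for _, plot_df in sub.groupby("plot_id"):
            qs = [shannon_index(q["count"].to_numpy()) for _, q in plot_df.groupby("quadrat")]
            plot_indices.append(plot_mean_index(qs))
        out.append({
            "grassland_type": stratum,
            "dry_above_t_hm2": quadrats["dry_above_g"].mean() * 0.01,
            "dry_below_t_hm2": quadrats["dry_below_g"].mean() * 0.01,
            "mean_shannon": float(np.mean(plot_indices)),
            "n_plots": sub["plot_id"].nunique(),
        })
    return pd.DataFrame(out).set_index("grassland_type")


class AreaResult:
    """Account plus intermediates for one study area."""

    def __init__(self, name: str, account: accounting.GepAccount,
                 intermediates: dict, validation: dict):
        self.name = name
        self.account = account
        self.intermediates = intermediates
        self.validation = validation

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "account": json.loads(self.account.to_json()),
            "intermediates": self.intermediates,
            "validation": self.validation,
        }


def run_area(bundle_dir, config: StudyAreaConfig | None = None) -> AreaResult:
    """Compute the full GEP account for one bundle directory."""
    bundle = Path(bundle_dir)
    if config is None:
        config = load_config(bundle / "config.yaml")

    rasters: dict[str, RasterGrid] = {}
    for name in RASTER_LAYERS:
        path = bundle / f"{name}.tif"
        if not path.exists():
            raise FileNotFoundError(f"bundle {bundle} lacks raster layer {name}.tif")
        rasters[name] = read_raster(path)
        logger.info("loaded %s.tif sha256=%s", name, _digest(path))

    plots = pd.read_csv(bundle / "plots.csv")
    tourists = pd.read_csv(bundle / "tourists.csv")
    vel_lookup = pd.read_csv(bundle / "velocity_by_class.csv")
    velocity_by_class = dict(zip(vel_lookup["class_code"].astype(int), vel_lookup["velocity"].astype(float)))

    lc = rasters["landcover"]
    mask = lc.with_values(np.isin(lc.values, GRASSLAND_CODES).astype(float))
    missing_classes = set(np.unique(lc.values[np.isfinite(lc.values)]).astype(int)) - set(velocity_by_class)
    if missing_classes:
        raise KeyError(f"velocity lookup lacks land-cover class(es) {sorted(missing_classes)}")
    vel_values = np.zeros_like(lc.values)
    for code, v in velocity_by_class.items():
        vel_values[lc.values == code] = v
    velocity = lc.with_values(vel_values.astype(np.float32).astype(float))

    # -- water ---------------------------------------------------------------
    layers = HydroLayers(
        precip=rasters["precip"], aet=rasters["aet"], velocity=velocity,
        ksat=rasters["ksat"], drainage_area=rasters["drainage_area"],
        soil_depth=rasters["soil_depth"], slope_pct=rasters["slope_pct"],
        velocity_cap=config.velocity_cap, ksat_cap=config.ksat_cap,
        log_base=config.ti_log_base,
    )
    wr = water_retention(layers)
    v_water, water_tonnes = water_retention_value(wr, mask, WaterPrice(config.water_price))
    wr_mean_mm = zonal_mean(wr, mask)

    # -- soil ----------------------------------------------------------------
    rusle = RusleLayers(
        r_factor=rasters["r_factor"], k_factor=rasters["k_factor"],
        ls_factor=rasters["ls_factor"], c_factor=rasters["c_factor"],
        p_factor=rasters["p_factor"],
    )
    qsr, qsr_grid = rusle_retention(rusle, mask, bracket=config.rusle_bracket)
    v_soil, soil_breakdown = soil_retention_value(qsr, config.soil_params())
    grass_area_cells = mask.values.sum() * mask.cell_area
    # t over hm² -> kg/m²: 1 t/hm² = 0.1 kg/m²
    qsr_kg_m2 = qsr / grass_area_cells * 0.1 if grass_area_cells > 0 else float("nan")

    # -- bare rock (feeds the BRRG driver indicator) -------------------------
    ndri = compute_ndri(rasters["band3"], rasters["band8"])
    fr = bare_rock_fraction(ndri, NdriNormalization(config.ndri_p_low, config.ndri_p_high))
    brrg = zonal_mean(fr, mask)

    # -- plots: carbon, oxygen, biodiversity ---------------------------------
    summary = plot_stratum_summary(plots)
    strata_areas = {"natural": config.area_natural, "artificial": config.area_artificial}
    v_carbon = v_oxygen = 0.0
    carbon_detail = {}
    for stratum, area in strata_areas.items():
        row = summary.loc[stratum]
        acct = carbon_account(CarbonInputs(
            area=area,
            dry_matter_above=float(row["dry_above_t_hm2"]),
            dry_matter_below=float(row["dry_below_t_hm2"]),
            soc_density=config.soc_density,
            dm_to_c=config.dm_to_c, karst_rate=config.karst_rate,
            carbon_price=config.carbon_price, oxygen_price=config.oxygen_price,
        ))
        v_carbon += acct.value
        v_oxygen += acct.oxygen_value
        carbon_detail[stratum] = {"qtco2_t": acct.total, "qop_t": acct.qop}

    area_by_stratum = {
        s: (a, float(summary.loc[s, "mean_shannon"])) for s, a in strata_areas.items()
    }
    v_bio = biodiversity_value(area_by_stratum, config.tier_table())

    # -- grazing -------------------------------------------------------------
    gc = grazing_capacity(config.grazing_params())
    v_grazing = grazing_value(gc, config.cattle_price)
    grazing_both = {"basis": config.grazing_basis, config.grazing_basis: v_grazing}
    other = "realized" if config.grazing_basis == "potential" else "potential"
    if config.gc_natural_realized_pua is not None or other == "potential":
        try:
            gc_other = grazing_capacity(config.grazing_params(basis=other))
            grazing_both[other] = grazing_value(gc_other, config.cattle_price)
        except (TypeError, ValueError):
            pass  # realized figures not supplied

    # -- tourism -------------------------------------------------------------
    tp = config.tourism_params()
    segments = [
        TouristSegment(
            visitors=float(r.visitors), direct_spend=float(r.direct_spend),
            wage_rate=float(r.wage_rate), trips=float(r.trips),
            foregone_work=float(r.foregone_work), travel_time=float(r.travel_time),
            onsite_time=float(r.onsite_time), time_unit=config.tourism_time_unit,
        )
        for r in tourists.itertuples()
    ]
    vlt = total_tourism_value(segments, tp)
    v_tourism = grassland_tourism_value(vlt, tp)

    components = {
        "grazing": v_grazing, "water": v_water, "soil": v_soil,
        "carbon": v_carbon, "oxygen": v_oxygen,
        "biodiversity": v_bio, "tourism": v_tourism,
    }
    account = accounting.build_account(
        components, config.grassland_area, frozenset(config.realized_keys)
    )
    validation = accounting.validate_account(account)

    intermediates = {
        "water_retention_mean_mm": wr_mean_mm,
        "water_retention_tonnes": water_tonnes,
        "soil_retention_t": qsr,
        "soil_retention_kg_m2": qsr_kg_m2,
        "soil_value_breakdown": soil_breakdown,
        "bare_rock_fraction_grassland": brrg,
        "grazing_capacity_cattle": gc,
        "grazing_value_by_basis": grazing_both,
        "tourism_total_value": vlt,
        "carbon_detail": carbon_detail,
        "mean_shannon": {s: area_by_stratum[s][1] for s in strata_areas},
    }
    return AreaResult(config.name, account, intermediates, validation)


def run_pipeline(bundle_root, out_dir=None) -> list[AreaResult]:
    """Run every ``area_*`` subdirectory of a bundle root; write reports.

    Aborts on the first failing area, naming it.  With ``out_dir`` set,
    writes one ``<area>.json`` per area plus ``combined.csv`` and
    ``validation.json``.
    """
    root = Path(bundle_root)
    area_dirs = sorted(d for d in root.iterdir() if d.is_dir() and d.name.startswith("area_"))
    if not area_dirs:
        raise FileNotFoundError(f"no area_* bundle directories under {root}")
    results = []
    for d in area_dirs:
        try:
            results.append(run_area(d))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in area bundle {d.name}: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for res in results:
            (out / f"{res.name}.json").write_text(
                json.dumps(res.to_dict(), indent=2, sort_keys=True)
            )
            rows.append({
                "area": res.name,
                **{f"v_{k}": v for k, v in res.account.components.items()},
                "gep_total": res.account.gep_total,
                "gep_per_unit_area": res.account.gep_per_unit_area,
                "realization_rate": res.account.realization_rate,
            })
        pd.DataFrame(rows).to_csv(out / "combined.csv", index=False)
        (out / "validation.json").write_text(json.dumps(
            {res.name: res.validation for res in results}, indent=2, sort_keys=True
        ))
    return results
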