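"""Raster grids, TIFF I/O, and the bare-rock spectral index.

The accounting pipeline works on co-registered single-band rasters
(precipitation, evapotranspiration, RUSLE factors, Sentinel-2-style
reflectance bands, ...).  :class:`RasterGrid` is the in-memory container:
a 2-D float array with an explicit missing-data sentinel, the area of one
cell in hectares (hm²), and an opaque CRS tag used only to check that two
grids were produced on the same georeferencing.

Bare rock is estimated from green (band 3) and near-infrared (band 8)
reflectance through the normalized difference rock index

    NDRI = (band8 - band3) / (band8 + band3)

which is then stretched between its low and high cumulative-frequency
anchors (1% and 99% by default) to a bare-rock fraction in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile


__all__ = [
    "RasterGrid",
    "NdriNormalization",
    "read_raster",
    "write_raster",
    "compute_ndri",
    "bare_rock_fraction",
    "zonal_mean",
]

#: TIFF tag codes used for geo-metadata (GDAL conventions).
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_GDAL_NODATA = 42113


class RasterError(ValueError):
    """Raised on invalid raster inputs (misalignment, degenerate data, ...)."""


@dataclass
class RasterGrid:
    """Single-band georeferenced grid; row 0 is the top of the scene.

    Parameters
    ----------
    values
        2-D float array.  Cells equal to ``nodata`` are missing.
    cell_area
        Area of one cell in hm² (1 hm² = 10⁴ m²).
    nodata
        Sentinel marking missing cells, or ``None`` when every cell is valid.
    crs_tag
        Opaque coordinate-reference identifier; only compared for equality.
    """

    values: np.ndarray
    cell_area: float = 0.01  # 10 m cells
    nodata: float | None = None
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError(f"raster must be 2-D, got shape {self.values.shape}")
        if not self.cell_area > 0:
            raise RasterError(f"cell_area must be positive, got {self.cell_area}")
        if self.nodata is None and not np.all(np.isfinite(self.values)):
            raise RasterError("non-finite cells present but no nodata sentinel declared")

    # -- missing-data handling -------------------------------------------------

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        ok = np.isfinite(self.values)
        if self.nodata is not None:
            if np.isnan(self.nodata):
                return ok
            ok &= self.values != self.nodata
        return ok

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Values with missing cells replaced by ``fill``."""
        out = self.values.copy()
        out[~self.mask()] = fill
        return out

    def with_values(self, values: np.ndarray, nodata: float | None = np.nan) -> "RasterGrid":
        """New grid on this grid's georeferencing."""
        return RasterGrid(values=values, cell_area=self.cell_area, nodata=nodata, crs_tag=self.crs_tag)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_area, other.cell_area)
            and self.crs_tag == other.crs_tag
        )


@dataclass(frozen=True)
class NdriNormalization:
    """Cumulative-frequency anchors for the bare-rock stretch.

    ``p_low`` is the percentile taken as the fully soil/vegetation-covered
    pixel value (NDRI0) and ``p_high`` the fully rock-exposed value (NDRIr).
    """

    p_low: float = 1.0
    p_high: float = 99.0

    def __post_init__(self) -> None:
        if not (0 <= self.p_low < self.p_high <= 100):
            raise ValueError(f"require 0 <= p_low < p_high <= 100, got {self.p_low}, {self.p_high}")


def _require_aligned(a: RasterGrid, b: RasterGrid, what: str) -> None:
    if not a.aligned_with(b):
        raise RasterError(
            f"{what}: grids are not aligned "
            f"(shapes {a.shape} vs {b.shape}, cell areas {a.cell_area} vs {b.cell_area}, "
            f"crs {a.crs_tag!r} vs {b.crs_tag!r})"
        )


# -- I/O ---------------------------------------------------------------------


def read_raster(path) -> RasterGrid:
    """Read a single-band TIFF raster written by :func:`write_raster`.

    Nodata is taken from the GDAL_NODATA tag; cell area and CRS tag from the
    JSON ImageDescription (falling back to the ModelPixelScale tag for the
    cell size, assuming metre units).
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except (OSError, tifffile.TiffFileError) as exc:
        raise RasterError(f"cannot read raster {path}: {exc}") from exc
    values = np.asarray(values)
    if values.ndim == 3 and values.shape[-1] == 1:
        values = values[..., 0]
    if values.ndim != 2:
        raise RasterError(f"{path} is not a single-band raster (shape {values.shape})")

    cell_area = None
    nodata = None
    crs_tag = ""
    desc = tags.get(270)  # ImageDescription
    if desc:
        try:
            meta = json.loads(desc)
            cell_area = meta.get("cell_area_hm2")
            crs_tag = meta.get("crs_tag", "")
            if meta.get("nodata") is not None:
                nodata = float(meta["nodata"])
        except (json.JSONDecodeError, TypeError):
            pass
    if _TAG_GDAL_NODATA in tags and nodata is None:
        raw = str(tags[_TAG_GDAL_NODATA]).strip("\x00 ")
        if raw:
            nodata = float(raw)
    if cell_area is None and _TAG_MODEL_PIXEL_SCALE in tags:
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
        cell_area = abs(sx * sy) / 1e4  # m² -> hm²
    if cell_area is None:
        cell_area = 0.01
    return RasterGrid(values=values.astype(float), cell_area=float(cell_area), nodata=nodata, crs_tag=crs_tag)


def write_raster(path, grid: RasterGrid) -> None:
    """Write ``grid`` as a single-band float32 TIFF with geo tags."""
    cell_m = float(np.sqrt(grid.cell_area * 1e4))
    meta = {"cell_area_hm2": grid.cell_area, "crs_tag": grid.crs_tag, "nodata": grid.nodata}
    extratags = [(_TAG_MODEL_PIXEL_SCALE, "d", 3, (cell_m, cell_m, 0.0), True)]
    if grid.nodata is not None:
        nd = repr(float(grid.nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd, True))
    tifffile.imwrite(
        str(path),
        grid.values.astype(np.float32),
        description=json.dumps(meta),
        metadata=None,  # keep the JSON description as-is
        extratags=extratags,
    )


# -- index computations ------------------------------------------------------


def compute_ndri(band3: RasterGrid, band8: RasterGrid) -> RasterGrid:
    """Normalized difference rock index (band8 - band3)/(band8 + band3).

    Cells where both reflectances are zero are set to nodata (NaN).
    """
    _require_aligned(band3, band8, "compute_ndri")
    b3 = band3.filled()
    b8 = band8.filled()
    if np.nanmin(b3) < 0 or np.nanmin(b8) < 0:
        raise RasterError("reflectance bands must be non-negative")
    denom = b8 + b3
    with np.errstate(invalid="ignore", divide="ignore"):
        ndri = np.where(denom > 0, (b8 - b3) / np.where(denom > 0, denom, 1.0), np.nan)
    ndri[~(band3.mask() & band8.mask())] = np.nan
    return band3.with_values(ndri, nodata=np.nan)


def bare_rock_fraction(
    ndri: RasterGrid,
    norm: NdriNormalization = NdriNormalization(),
    *,
    as_printed: bool = False,
) -> RasterGrid:
    """Bare-rock fraction from NDRI via percentile min-max stretch.

    The low/high percentile anchors (NDRI0, NDRIr) are treated as saturation
    points: values below NDRI0 map to 0, above NDRIr to 1.  Percentiles use
    linear interpolation between order statistics.

    With ``as_printed=True`` the alternative numerator (NDRI - NDRIr) is used,
    which yields non-positive output for all cells below the high anchor; it
    exists only for comparison and is not clamped.
    """
    vals = ndri.filled()
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise RasterError("bare_rock_fraction needs at least 2 non-missing cells")
    lo, hi = np.percentile(vals[ok], [norm.p_low, norm.p_high])
    if hi == lo:
        raise RasterError("degenerate normalization: NDRIr equals NDRI0 (constant raster)")
    if as_printed:
        fr = (vals - hi) / (hi - lo)
    else:
        fr = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    fr[~ok] = np.nan
    return ndri.with_values(fr, nodata=np.nan)


def zonal_mean(layer: RasterGrid, mask: RasterGrid) -> float:
    """Mean of ``layer`` over cells where ``mask`` is 1, ignoring nodata."""
    _require_aligned(layer, mask, "zonal_mean")
    m = mask.filled(0.0)
    uniq = np.unique(m[np.isfinite(m)])
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise RasterError(f"mask must be binary, found values {uniq[:5]}")
    sel = (m == 1.0) & layer.mask()
    if not sel.any():
        raise RasterError("zonal_mean over an empty zone")
    return float(layer.values[sel].mean())
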