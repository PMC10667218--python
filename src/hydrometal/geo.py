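"""Inverse-distance-weighted surfaces and banded quality maps.

Station-level quantities (a metal concentration, the pollution index,
a hazard index, a model prediction) are interpolated onto a regular
lon/lat grid with power-p inverse distance weighting.  Over a study
extent of a fraction of a degree the geometry is treated as planar: an
equirectangular local projection (longitude scaled by cos of the mean
latitude) is applied before computing distances.

Exports are plain-text GIS formats: ESRI ASCII grid for rasters,
GeoJSON for banded polygons, PNG for quick-looks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np

NODATA = -9999.0
#: Station-coincidence tolerance, degrees.
EPS_DEG = 1e-9


@dataclass
class SurfaceGrid:
    """Regular lon/lat raster; row 0 is the northern edge, values at
    cell centers."""

    west: float
    south: float
    east: float
    north: float
    cell_size: float  # degrees
    values: np.ndarray
    nodata: float = NODATA
    name: str = ""
    season: str = ""
    source: str = "observed"  # or a model name
    band_labels: tuple[str, ...] | None = None  # set for categorical grids

    def __post_init__(self) -> None:
        nrow = max(1, int(round((self.north - self.south) / self.cell_size)))
        ncol = max(1, int(round((self.east - self.west) / self.cell_size)))
        self.values = np.asarray(self.values)
        if self.values.shape != (nrow, ncol):
            raise ValueError(
                f"value array shape {self.values.shape} does not match the "
                f"{nrow}x{ncol} grid implied by the box and cell size"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.shape[1]) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        # row 0 = north
        return self.north - (np.arange(self.shape[0]) + 0.5) * self.cell_size

    def same_grid(self, other: "SurfaceGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.west, other.west)
            and math.isclose(self.south, other.south)
            and math.isclose(self.cell_size, other.cell_size)
        )


def empty_grid(west, south, east, north, cell_size, **kw) -> SurfaceGrid:
    nrow = max(1, int(round((north - south) / cell_size)))
    ncol = max(1, int(round((east - west) / cell_size)))
    return SurfaceGrid(west, south, east, north, cell_size,
                       np.full((nrow, ncol), NODATA), **kw)


def idw_interpolate(
    stations: list[tuple[float, float, float]],
    grid: SurfaceGrid,
    power: float = 2.0,
    max_neighbors: int | None = None,
) -> SurfaceGrid:
    """Fill ``grid`` with the IDW estimate of the station values.

    Each cell takes sum(w_i v_i)/sum(w_i) with w_i = d_i^-power; a cell
    coincident with a station (d < 1e-9 deg) takes that station's value
    exactly.  Output is therefore bounded by the station value range.
    Duplicate station coordinates with conflicting values are rejected.
    """
    if not stations:
        raise ValueError("need at least one station")
    if power <= 0:
        raise ValueError("power must be > 0")
    pts: dict[tuple[float, float], float] = {}
    for lon, lat, v in stations:
        key = (round(lon / EPS_DEG), round(lat / EPS_DEG))
        if key in pts and not math.isclose(pts[key], v, rel_tol=1e-12, abs_tol=0):
            raise ValueError(
                f"duplicate station location ({lon}, {lat}) with conflicting "
                "values"
            )
        pts[key] = v
    lons = np.array([lon for lon, _, _ in stations])
    lats = np.array([lat for _, lat, _ in stations])
    vals = np.array([v for _, _, v in stations])

    lat0 = math.radians(lats.mean())
    kx = math.cos(lat0)  # equirectangular: shrink longitude
    sx, sy = lons * kx, lats

    glon = grid.lon_centers() * kx
    glat = grid.lat_centers()
    gx, gy = np.meshgrid(glon, glat)  # (nrow, ncol)

    d = np.sqrt(
        (gx[..., None] - sx) ** 2 + (gy[..., None] - sy) ** 2
    )  # (nrow, ncol, nsta)
    out = np.empty(grid.shape)
    coincident = d < EPS_DEG
    if max_neighbors is not None and max_neighbors < len(stations):
        order = np.argsort(d, axis=-1)
        keep = np.zeros_like(d, dtype=bool)
        np.put_along_axis(keep, order[..., :max_neighbors], True, axis=-1)
    else:
        keep = np.ones_like(d, dtype=bool)
    with np.errstate(divide="ignore"):
        w = np.where(keep & ~coincident, d**-power, 0.0)
    hit = coincident.any(axis=-1)
    # weighted mean where no station coincides
    wsum = np.where(hit, 1.0, w.sum(axis=-1))
    out = np.where(hit, vals[np.argmax(coincident, axis=-1)],
                   (w * vals).sum(axis=-1) / wsum)
    return replace(grid, values=out)


def surface_difference(observed: SurfaceGrid, predicted: SurfaceGrid) -> SurfaceGrid:
    """Cellwise predicted - observed, with the mean absolute cell
    difference attached as ``summary``."""
    if not observed.same_grid(predicted):
        raise ValueError("grids have different extents or resolutions")
    diff = replace(
        observed,
        values=predicted.values - observed.values,
        name=f"{predicted.name}_minus_{observed.name}",
        source=f"{predicted.source}-{observed.source}",
    )
    diff.summary = float(np.mean(np.abs(diff.values)))
    return diff


def band_surface(
    surface: SurfaceGrid, bands: list[tuple[float, float, str]]
) -> SurfaceGrid:
    """Map each cell onto an ordered, exhaustive set of value bands.

    ``bands`` are (lower, upper, label) with edges belonging to the
    lower band; they must tile the value range without overlap.  The
    result stores integer band codes and the label list, with per-band
    cell counts in ``band_counts``.
    """
    if not bands:
        raise ValueError("need at least one band")
    for (lo1, up1, _), (lo2, up2, _) in zip(bands, bands[1:]):
        if up1 > lo2:
            raise ValueError("bands overlap")
        if up1 < lo2:
            raise ValueError("bands leave a gap")
    codes = np.full(surface.shape, -1, dtype=int)
    v = surface.values
    for i, (lo, up, _) in enumerate(bands):
        mask = (v > lo) & (v <= up) if i else (v >= lo) & (v <= up)
        codes[mask] = i
    if (codes < 0).any():
        raise ValueError("bands are not exhaustive for the surface values")
    labels = tuple(label for _, _, label in bands)
    out = replace(surface, values=codes, band_labels=labels,
                  name=f"{surface.name}_bands")
    out.band_counts = {
        label: int((codes == i).sum()) for i, label in enumerate(labels)
    }
    return out


def hpi_bands() -> list[tuple[float, float, str]]:
    """The five pollution-index bands as (lower, upper, label) tuples."""
    from .hpi import BANDS

    out = []
    lo = 0.0
    for up, label in BANDS:
        out.append((lo, up, label))
        lo = up
    return out


# --- plain-text exports ------------------------------------------------------


def write_ascii_grid(surface: SurfaceGrid, path) -> None:
    """ESRI ASCII grid (.asc): plain-text raster readable by GIS tools."""
    nrow, ncol = surface.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {surface.west}\n")
        fh.write(f"yllcorner {surface.south}\n")
        fh.write(f"cellsize {surface.cell_size}\n")
        fh.write(f"NODATA_value {surface.nodata}\n")
        for row in surface.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path, **kw) -> SurfaceGrid:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            k, v = fh.readline().split()
            header[k.lower()] = float(v)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.atleast_2d(values).reshape(nrows, ncols)
    cs = header["cellsize"]
    return SurfaceGrid(
        west=header["xllcorner"],
        south=header["yllcorner"],
        east=header["xllcorner"] + ncols * cs,
        north=header["yllcorner"] + nrows * cs,
        cell_size=cs,
        values=values,
        nodata=header.get("nodata_value", NODATA),
        **kw,
    )


def write_geojson_bands(banded: SurfaceGrid, path) -> None:
    """Dissolve a categorical grid into per-band polygons (GeoJSON)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    if banded.band_labels is None:
        raise ValueError("write_geojson_bands expects a banded surface")
    lons = banded.lon_centers()
    lats = banded.lat_centers()
    half = banded.cell_size / 2.0
    features = []
    for code, label in enumerate(banded.band_labels):
        cells = [
            box(lons[j] - half, lats[i] - half, lons[j] + half, lats[i] + half)
            for i, j in zip(*np.where(banded.values == code))
        ]
        if not cells:
            continue
        geom = unary_union(cells)
        features.append(
            {
                "type": "Feature",
                "properties": {"band": label, "code": code},
                "geometry": mapping(geom),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def quicklook_png(surface: SurfaceGrid, path, cmap: str = "viridis") -> None:
    """Render the surface (continuous or banded) to a PNG with a legend."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    extent = (surface.west, surface.east, surface.south, surface.north)
    im = ax.imshow(surface.values, extent=extent, origin="upper", cmap=cmap,
                   aspect="auto")
    title = " ".join(x for x in (surface.name, surface.season, surface.source)
                     if x)
    ax.set_title(title)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    if surface.band_labels is not None:
        cbar = fig.colorbar(im, ax=ax, ticks=range(len(surface.band_labels)))
        cbar.ax.set_yticklabels(surface.band_labels)
    else:
        fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=100)
    plt.close(fig)
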