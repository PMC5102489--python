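"""Habitat-structure proxies: canopy roughness, waveform extent, site summaries.

Canopy roughness is the 3×3 focal sample standard deviation of an SRTM-style
DEM. Waveform extent is the elevation distance between the beginning and end
of a full-waveform LiDAR return, detected against a noise threshold
estimated from the waveform tails; it proxies canopy height plus the
topographic-slope spread. Site summaries aggregate structure rasters and
waveform footprints over site polygons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter

from .errors import InvalidArgumentError, NoDataError, NoSignalError
from .landscape import LayerStack


def focal_roughness(dem: np.ndarray, window: int = 3) -> np.ndarray:
    """Focal sample standard deviation of a DEM (roughness proxy).

    Each interior cell gets the (n−1)-denominator SD of its window×window
    neighbourhood; border cells (no complete window) are NaN. Invariant to
    adding a constant to the DEM.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidArgumentError("window must be an odd integer >= 3")
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or min(dem.shape) < window:
        raise InvalidArgumentError(f"DEM must be 2-D with at least "
                                   f"{window}x{window} cells")
    # centre first: the moments subtraction is then numerically safe under
    # large offsets (translation invariance to ~1e-10 instead of ~1e-3)
    c = dem - dem.mean()
    n = window * window
    mean = uniform_filter(c, window, mode="constant")
    mean_sq = uniform_filter(c * c, window, mode="constant")
    var = np.clip((mean_sq - mean ** 2) * (n / (n - 1)), 0.0, None)
    out = np.sqrt(var)
    half = window // 2
    out[:half, :] = np.nan
    out[-half:, :] = np.nan
    out[:, :half] = np.nan
    out[:, -half:] = np.nan
    return out


def waveform_extent(elevation: np.ndarray, intensity: np.ndarray,
                    noise_k: float = 3.0, tail_frac: float = 0.1) -> float:
    """Elevation distance between a waveform's signal beginning and end (m).

    The noise floor (mean, sd) is estimated from the first and last
    ``tail_frac`` of samples; signal begin/end are the first/last runs of
    two consecutive samples exceeding mean + ``noise_k``·sd (the two-sample
    run rejects isolated noise spikes). Invariant to uniform intensity
    scaling up to the additive-noise floor.
    """
    elevation = np.asarray(elevation, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if elevation.size != intensity.size or elevation.size < 10:
        raise InvalidArgumentError("need >= 10 aligned samples")
    order = np.argsort(elevation)
    elevation, intensity = elevation[order], intensity[order]
    n_tail = max(int(round(tail_frac * elevation.size)), 3)
    tails = np.concatenate([intensity[:n_tail], intensity[-n_tail:]])
    thresh = tails.mean() + noise_k * tails.std(ddof=1)
    above = intensity > thresh
    runs = np.flatnonzero(above[:-1] & above[1:])   # two-consecutive runs
    if runs.size == 0:
        raise NoSignalError("waveform never exceeds the noise threshold")
    return float(elevation[runs[-1] + 1] - elevation[runs[0]])


@dataclass
class SiteStructure:
    """Per-site habitat-structure summary; missing layers give NaN fields."""

    site: str
    max_canopy_height_m: float
    mean_extent_m: float
    mean_roughness: float
    mean_agb: float
    modal_geology: int | float
    mean_hfi: float
    suitability: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _cells_in_polygon(stack: LayerStack, polygon_xy) -> tuple[np.ndarray, np.ndarray]:
    poly = shapely.polygons(np.asarray(polygon_xy, dtype=float))
    jj, ii = np.meshgrid(np.arange(stack.cols), np.arange(stack.rows))
    x, y = stack.cell_xy(ii.ravel(), jj.ravel())
    inside = shapely.contains_xy(poly, x, y) & stack.validity.ravel()
    idx = np.flatnonzero(inside)
    return np.unravel_index(idx, stack.shape)


def summarize_site(site: str, polygon_xy, stack: LayerStack,
                   rasters: dict[str, np.ndarray] | None = None,
                   waveforms: pd.DataFrame | None = None,
                   noise_k: float = 3.0) -> SiteStructure:
    """Aggregate structure variables over the cells inside a site polygon.

    ``rasters`` may supply ``canopy_height``, ``roughness`` and
    ``suitability`` grids aligned with the stack; ``waveforms`` is a long
    frame (footprint, elevation_m, intensity) of LiDAR returns inside the
    site. Missing layers yield NaN fields rather than failure.
    """
    rows, cols = _cells_in_polygon(stack, polygon_xy)
    if rows.size == 0:
        raise NoDataError(f"site {site!r} does not intersect the raster extent")
    rasters = rasters or {}

    def _agg(grid, fn):
        if grid is None:
            return float("nan")
        vals = np.asarray(grid, dtype=float)[rows, cols]
        vals = vals[~np.isnan(vals)]
        return float(fn(vals)) if vals.size else float("nan")

    extent = float("nan")
    if waveforms is not None and len(waveforms):
        extents = []
        for _, grp in waveforms.groupby("footprint"):
            try:
                extents.append(waveform_extent(grp["elevation_m"].to_numpy(),
                                               grp["intensity"].to_numpy(),
                                               noise_k=noise_k))
            except NoSignalError:
                continue
        if extents:
            extent = float(np.mean(extents))

    geo = stack.categorical.get("geology")
    if geo is not None:
        vals, counts = np.unique(geo[rows, cols], return_counts=True)
        modal = int(vals[np.argmax(counts)])
    else:
        modal = float("nan")

    return SiteStructure(
        site=site,
        max_canopy_height_m=_agg(rasters.get("canopy_height"), np.max),
        mean_extent_m=extent,
        mean_roughness=_agg(rasters.get("roughness"), np.mean),
        mean_agb=_agg(stack.continuous.get("agb"), np.mean),
        modal_geology=modal,
        mean_hfi=_agg(stack.continuous.get("footprint"), np.mean),
        suitability=_agg(rasters.get("suitability"), np.mean),
    )


def site_structure_table(sites: dict[str, np.ndarray], stack: LayerStack,
                         rasters: dict[str, np.ndarray] | None = None,
                         waveforms_by_site: dict[str, pd.DataFrame] | None = None,
                         ) -> pd.DataFrame:
    """Vectorized :func:`summarize_site` over a {site: polygon} mapping."""
    waveforms_by_site = waveforms_by_site or {}
    recs = [summarize_site(s, poly, stack, rasters,
                           waveforms_by_site.get(s)).as_dict()
            for s, poly in sites.items()]
    return pd.DataFrame(recs)


def square_site_polygon(center_x_km: float, center_y_km: float,
                        half_side_km: float) -> np.ndarray:
    """Axis-aligned square site polygon (closed ring) around a centre."""
    x0, x1 = center_x_km - half_side_km, center_x_km + half_side_km
    y0, y1 = center_y_km - half_side_km, center_y_km + half_side_km
    return np.array([(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)])
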