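"""Geometry of the identified disturbance range.

Disturbance distance: the shortest Euclidean distance from a pixel on the
SRMD boundary to the mining-area boundary, in km (centre-to-centre between
pixels; polygon inputs are rasterized to the study grid first). The module
also reports how much of the SRMD falls inside a buffer around the mine
(the method's headline check uses 3 km) and per-sector distance ranges in
eight 45-degree azimuth sectors around the mine centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .drivers import rasterize_region
from .grid import Grid, RegionMask

__all__ = [
    "SRMDResult",
    "mask_boundary",
    "distance_map_km",
    "disturbance_distances",
    "buffer_fraction",
    "directional_ranges",
    "summarize_srmd",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SRMDResult:
    """Summary geometry of one identified disturbance range."""

    mask: RegionMask
    boundary_distances_km: np.ndarray
    stats: dict[str, float]
    buffer_km: float
    buffer_fraction: float
    direction_ranges: pd.DataFrame


def _as_mask(region: RegionMask | BaseGeometry, like: RegionMask) -> RegionMask:
    if isinstance(region, RegionMask):
        if not region.same_geometry(like):
            raise ValueError("region mask not aligned to the SRMD grid")
        return region
    return rasterize_region(like.to_grid(), region)


def mask_boundary(mask: RegionMask) -> RegionMask:
    """Pixels of the mask with at least one 8-neighbour outside it.

    Grid-edge pixels of the mask count as boundary (the outside of the grid
    is treated as outside the mask).
    """
    if mask.count() == 0:
        raise ValueError("empty mask has no boundary")
    interior = ndimage.binary_erosion(mask.values, structure=_EIGHT, border_value=0)
    return RegionMask(
        values=mask.values & ~interior,
        cell_size_m=mask.cell_size_m,
        origin_xy=mask.origin_xy,
        crs_label=mask.crs_label,
    )


def distance_map_km(target: RegionMask) -> np.ndarray:
    """Per-cell Euclidean distance (km) to the nearest cell of ``target``."""
    if target.count() == 0:
        raise ValueError("empty target region")
    d_m = ndimage.distance_transform_edt(~target.values, sampling=target.cell_size_m)
    return d_m / 1000.0


def disturbance_distances(
    srmd: RegionMask, mine_boundary: RegionMask | BaseGeometry
) -> tuple[np.ndarray, dict[str, float]]:
    """Disturbance distance per SRMD-boundary pixel, with summary statistics.

    For every pixel on the SRMD boundary, the minimum centre-to-centre
    distance to the mining area's boundary pixels, km. Stats: mean, median,
    lower/upper quartile, min, max.
    """
    mine = _as_mask(mine_boundary, srmd)
    if srmd.count() == 0 or mine.count() == 0:
        raise ValueError("SRMD and mining region must both be non-empty")
    srmd_b = mask_boundary(srmd)
    mine_b = mask_boundary(mine)
    dist = distance_map_km(mine_b)
    d = dist[srmd_b.values]
    stats = {
        "n": int(d.size),
        "mean": float(d.mean()),
        "median": float(np.median(d)),
        "q25": float(np.quantile(d, 0.25)),
        "q75": float(np.quantile(d, 0.75)),
        "min": float(d.min()),
        "max": float(d.max()),
    }
    return d, stats


def buffer_fraction(
    srmd: RegionMask, mine_boundary: RegionMask | BaseGeometry, radius_km: float
) -> float:
    """Fraction of SRMD pixels within ``radius_km`` of the mining area.

    A pixel inside (or touching) the mining region has distance 0, so it is
    always inside the buffer. Non-decreasing in the radius.
    """
    if radius_km < 0:
        raise ValueError(f"radius_km must be >= 0, got {radius_km}")
    if srmd.count() == 0:
        raise ValueError("empty SRMD")
    mine = _as_mask(mine_boundary, srmd)
    dist = distance_map_km(mine)        # 0 inside the mining region
    d = dist[srmd.values]
    return float(np.mean(d <= radius_km))


def directional_ranges(
    srmd: RegionMask,
    mine_boundary: RegionMask | BaseGeometry,
    n_sectors: int = 8,
    centroid_xy: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-sector (min, max) disturbance distance around the mine centroid.

    SRMD boundary pixels are assigned to equal azimuth sectors by bearing
    from the mine centroid; sector 1 starts at north (0 deg) and sectors
    proceed clockwise. The sector labels are a package convention of
    azimuth ranges, not compass-verified direction numbers. Empty sectors
    are reported with NaN distances.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be >= 1")
    mine = _as_mask(mine_boundary, srmd)
    if centroid_xy is None:
        rr, cc = np.nonzero(mine.values)
        if rr.size == 0:
            raise ValueError("mine region is empty; centroid undefined")
        x0, y0 = mine.origin_xy
        cx = x0 + (cc.mean() + 0.5) * mine.cell_size_m
        cy = y0 - (rr.mean() + 0.5) * mine.cell_size_m
    else:
        cx, cy = map(float, centroid_xy)

    srmd_b = mask_boundary(srmd)
    d_all, _ = disturbance_distances(srmd, mine_boundary)
    rr, cc = np.nonzero(srmd_b.values)
    x0, y0 = srmd.origin_xy
    px = x0 + (cc + 0.5) * srmd.cell_size_m
    py = y0 - (rr + 0.5) * srmd.cell_size_m
    azimuth = np.degrees(np.arctan2(px - cx, py - cy)) % 360.0
    width = 360.0 / n_sectors
    sector = np.minimum((azimuth // width).astype(int), n_sectors - 1)

    rows = []
    for k in range(n_sectors):
        sel = sector == k
        rows.append(
            {
                "sector": k + 1,
                "azimuth_start_deg": k * width,
                "azimuth_end_deg": (k + 1) * width,
                "n": int(sel.sum()),
                "min_km": float(d_all[sel].min()) if sel.any() else np.nan,
                "max_km": float(d_all[sel].max()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def summarize_srmd(
    srmd: RegionMask,
    mine_boundary: RegionMask | BaseGeometry,
    buffer_km: float = 3.0,
    n_sectors: int = 8,
) -> SRMDResult:
    """Full geometric summary: distances, buffer containment, directions."""
    d, stats = disturbance_distances(srmd, mine_boundary)
    frac = buffer_fraction(srmd, mine_boundary, buffer_km)
    directions = directional_ranges(srmd, mine_boundary, n_sectors=n_sectors)
    return SRMDResult(
        mask=srmd,
        boundary_distances_km=d,
        stats=stats,
        buffer_km=buffer_km,
        buffer_fraction=frac,
        direction_ranges=directions,
    )
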