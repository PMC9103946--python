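"""Spatialization and normalization of the five FVC driving factors.

Natural factors: growing-season accumulated precipitation, growing-season
mean temperature (both single-station scalars per year) and topography
(DEM). Artificial factors: urban activity and mining activity, quantified
by an intensity/distance law

    x_urban = P_pop / (D_U + 1),        x_mine = MI_m / (D_M + 1),

with D the shortest Euclidean distance (km) from a pixel centre to the
urban/mining boundary region (0 inside). For a period with no mining, a
*virtual* mining factor vx_mine = MI_u / (D_VM + 1) is built from an
assumed production and boundary taken from the mining period; its
downstream contribution is the attribution noise sample.

All factors are min-max normalized to [0, 1]. Spatially varying factors
(dem, urban, mine) are normalized over the pixels of each year; spatially
constant station scalars (precipitation, temperature) are normalized across
the study years, since their within-year pixel range is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import shapely
from shapely.geometry.base import BaseGeometry

from .grid import Grid, RegionMask, require_aligned

__all__ = [
    "ActivityRecord",
    "DriverField",
    "DriverStack",
    "FACTOR_IDS",
    "rasterize_region",
    "distance_to_region",
    "quantify_activity",
    "quantify_virtual_mining",
    "normalize_factor",
    "pearson_window_selection",
    "build_driver_stack",
]

FACTOR_IDS = ("pre", "temp", "dem", "urban", "mine")


@dataclass
class ActivityRecord:
    """Per-year human-activity data: population, coal production, boundaries."""

    year: int
    population: float
    coal_production: float
    urban_boundary: BaseGeometry | None = None
    mine_boundary: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"population must be >= 0, got {self.population}")
        if self.coal_production < 0:
            raise ValueError(
                f"coal_production must be >= 0, got {self.coal_production}"
            )


@dataclass
class DriverField:
    """One quantified (pre-normalization) driving factor.

    ``distance`` holds the km distance field for the distance-based factors
    (urban, mine, virtual mine); it is None for the others.
    """

    factor_id: str
    raw: Grid
    distance: Grid | None = None

    def __post_init__(self) -> None:
        if self.factor_id not in FACTOR_IDS:
            raise ValueError(f"unknown factor_id {self.factor_id!r}")
        if self.distance is not None:
            d = self.distance.valid_values()
            if d.size and d.min() < 0:
                raise ValueError("distance field contains negative values")


@dataclass
class DriverStack:
    """The five normalized driving factors of one year, mutually aligned."""

    year: int
    factors: dict[str, Grid]
    normalization_bounds: dict[str, tuple[float, float]]
    mining_is_virtual: bool = False

    def __post_init__(self) -> None:
        missing = [f for f in FACTOR_IDS if f not in self.factors]
        if missing:
            raise ValueError(f"driver stack for {self.year} missing factors {missing}")
        require_aligned(*[self.factors[f] for f in FACTOR_IDS])
        # small headroom above 1 so a finite-difference-perturbed stack
        # (X + 0.001 X) remains a valid stack
        for fid in FACTOR_IDS:
            vals = self.factors[fid].valid_values()
            if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-2):
                raise ValueError(
                    f"factor {fid!r} of year {self.year} not normalized to [0, 1]"
                )

    @property
    def grid(self) -> Grid:
        return self.factors[FACTOR_IDS[0]]

    def valid_mask(self) -> np.ndarray:
        m = self.factors[FACTOR_IDS[0]].mask
        for fid in FACTOR_IDS[1:]:
            m = m & self.factors[fid].mask
        return m

    def matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_pixels, 5) matrix of the factors over the valid (or given) cells,
        ordered (pre, temp, dem, urban, mine)."""
        if mask is None:
            mask = self.valid_mask()
        return np.column_stack([self.factors[f].values[mask] for f in FACTOR_IDS])

    def replace_factor(self, factor_id: str, grid: Grid) -> "DriverStack":
        if factor_id not in FACTOR_IDS:
            raise ValueError(f"unknown factor_id {factor_id!r}")
        factors = dict(self.factors)
        factors[factor_id] = grid
        return DriverStack(
            year=self.year,
            factors=factors,
            normalization_bounds=dict(self.normalization_bounds),
            mining_is_virtual=self.mining_is_virtual,
        )


# ---------------------------------------------------------------------------
# Distance and activity quantification
# ---------------------------------------------------------------------------

def rasterize_region(grid: Grid, region: RegionMask | BaseGeometry) -> RegionMask:
    """Region as a boolean mask on the study grid.

    Polygons are rasterized by membership of the cell centre (boundary
    inclusive). A polygon too small to cover any centre claims the single
    cell containing its representative point.
    """
    if isinstance(region, RegionMask):
        if not region.same_geometry(grid):
            raise ValueError("region mask is not aligned to the grid")
        return region
    if region is None or region.is_empty:
        raise ValueError("empty region")
    xs, ys = grid.cell_centers()
    inside = shapely.intersects_xy(region, xs.ravel(), ys.ravel()).reshape(grid.shape)
    if not inside.any():
        p = region.representative_point()
        c = int((p.x - grid.origin_xy[0]) // grid.cell_size_m)
        r = int((grid.origin_xy[1] - p.y) // grid.cell_size_m)
        if not (0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]):
            raise ValueError("region does not overlap the grid")
        inside[r, c] = True
    return RegionMask.like(grid, inside)


def distance_to_region(
    grid: Grid, region: RegionMask | BaseGeometry, units: str = "km"
) -> Grid:
    """Shortest Euclidean distance from each cell centre to the region.

    Distances are centre-to-centre against the region's cells; cells inside
    the region get 0. Euclidean distance transform in projected metres,
    reported in km by default.
    """
    mask = rasterize_region(grid, region)
    if mask.count() == 0:
        raise ValueError("empty region")
    dist_m = ndimage.distance_transform_edt(
        ~mask.values, sampling=grid.cell_size_m
    )
    scale = 1000.0 if units == "km" else 1.0
    return grid.with_values(dist_m / scale)


def quantify_activity(magnitude: float, distance: Grid) -> Grid:
    """Activity intensity field: magnitude / (distance + 1), distance in km.

    The intensity equals the full magnitude inside/at the source region and
    decays hyperbolically with distance.
    """
    if magnitude < 0:
        raise ValueError(f"activity magnitude must be >= 0, got {magnitude}")
    vals = magnitude / (distance.values + 1.0)
    out = np.where(distance.mask, vals, distance.nodata)
    return distance.with_values(out)


def quantify_virtual_mining(
    assumed_production: float,
    assumed_boundary: RegionMask | BaseGeometry,
    grid: Grid,
) -> DriverField:
    """Virtual mining factor for a no-mining year.

    Applies the mining period's production and boundary to a year with no
    mining activity: vx_mine = MI_u / (D_VM + 1). Its attributed
    contribution downstream is noise by construction.
    """
    dist = distance_to_region(grid, assumed_boundary)
    raw = quantify_activity(assumed_production, dist)
    return DriverField(factor_id="mine", raw=raw, distance=dist)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_factor(
    raw: np.ndarray,
    scope: str = "per_year_pixels",
    factor_id: str = "",
    bounds: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max normalize a factor's quantified values to [0, 1].

    ``bounds`` may be supplied to reuse a previously computed (min, max),
    e.g. to place several years on a common scale. The minimum maps to
    exactly 0 and the maximum to exactly 1.
    """
    arr = np.asarray(raw, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError(f"factor {factor_id!r}: no finite values in scope {scope!r}")
    if bounds is None:
        lo, hi = float(finite.min()), float(finite.max())
    else:
        lo, hi = map(float, bounds)
    if not hi > lo:
        raise ValueError(
            f"factor {factor_id!r} is constant within scope {scope!r} "
            f"(min = max = {lo}); normalization undefined"
        )
    return (arr - lo) / (hi - lo), (lo, hi)


# ---------------------------------------------------------------------------
# Meteorological window selection
# ---------------------------------------------------------------------------

def pearson_window_selection(
    fvc_series: pd.Series,
    meteo_monthly: pd.DataFrame,
    candidate_windows: list[tuple[int, int]],
    aggregate: str = "sum",
) -> pd.DataFrame:
    """Rank candidate month windows by |Pearson r| against a per-year FVC summary.

    ``meteo_monthly`` is indexed by year with columns 1..12 (months);
    precipitation windows aggregate by accumulation (``sum``), temperature
    windows by ``mean``. Windows whose aggregate (or the FVC series) has
    zero variance get an undefined r reported as NaN.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    fvc = pd.Series(fvc_series).astype(float)
    if len(fvc) < 3:
        raise ValueError("need at least 3 years for correlation analysis")
    meteo = meteo_monthly.loc[fvc.index]
    rows = []
    for start, end in candidate_windows:
        if not (1 <= start <= end <= 12):
            raise ValueError(f"window ({start}, {end}) outside Jan-Dec")
        months = list(range(start, end + 1))
        agg = meteo[months].sum(axis=1) if aggregate == "sum" else meteo[months].mean(axis=1)
        if np.ptp(agg.to_numpy()) == 0 or np.ptp(fvc.to_numpy()) == 0:
            r = np.nan
        else:
            r = stats.pearsonr(fvc.to_numpy(), agg.to_numpy()).statistic
        rows.append({"start_month": start, "end_month": end, "r": r})
    table = pd.DataFrame(rows)
    table["abs_r"] = table["r"].abs()
    table = table.sort_values("abs_r", ascending=False, na_position="last")
    return table.drop(columns="abs_r").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stack assembly
# ---------------------------------------------------------------------------

def build_driver_stack(
    year: int,
    grid: Grid,
    dem: Grid,
    precip_by_year: dict[int, float],
    temp_by_year: dict[int, float],
    activities: dict[int, ActivityRecord],
    virtual_mining: tuple[float, RegionMask | BaseGeometry] | None = None,
) -> DriverStack:
    """Assemble the five normalized factors of one year.

    The mining factor is the real one where the year has mining activity
    (production > 0 and a mining boundary); otherwise the virtual factor
    built from ``virtual_mining = (assumed_production, assumed_boundary)``
    is used and the stack is flagged ``mining_is_virtual``.
    """
    if year not in activities:
        raise ValueError(f"no activity record for year {year}")
    if year not in precip_by_year or year not in temp_by_year:
        raise ValueError(f"missing meteorological scalars for year {year}")
    require_aligned(grid, dem)
    rec = activities[year]

    bounds: dict[str, tuple[float, float]] = {}
    factors: dict[str, Grid] = {}

    # station scalars: normalized across the study years (constant per year)
    for fid, series in (("pre", precip_by_year), ("temp", temp_by_year)):
        vals = np.array(list(series.values()), dtype=float)
        norm, b = normalize_factor(vals, scope="across_years", factor_id=fid)
        this = float(norm[list(series.keys()).index(year)])
        bounds[fid] = b
        factors[fid] = grid.with_values(
            np.where(grid.mask, this, grid.nodata)
        )

    # topography: per-year pixel normalization (same DEM every year)
    dem_norm, b = normalize_factor(
        np.where(dem.mask, dem.values, np.nan), scope="per_year_pixels",
        factor_id="dem",
    )
    bounds["dem"] = b
    factors["dem"] = dem.with_values(np.where(dem.mask, dem_norm, dem.nodata))

    # urban activity
    if rec.urban_boundary is None:
        raise ValueError(f"year {year}: missing urban boundary")
    d_u = distance_to_region(grid, rec.urban_boundary)
    x_urban = quantify_activity(rec.population, d_u)
    urb_norm, b = normalize_factor(
        np.where(x_urban.mask, x_urban.values, np.nan),
        scope="per_year_pixels", factor_id="urban",
    )
    bounds["urban"] = b
    factors["urban"] = grid.with_values(np.where(x_urban.mask, urb_norm, grid.nodata))

    # mining activity: real or virtual
    mining_is_virtual = rec.mine_boundary is None or rec.coal_production == 0
    if mining_is_virtual:
        if virtual_mining is None:
            raise ValueError(
                f"year {year} has no mining activity and no virtual mining "
                "(assumed_production, assumed_boundary) was supplied"
            )
        mi, boundary = virtual_mining
        mine_field = quantify_virtual_mining(mi, boundary, grid)
    else:
        d_m = distance_to_region(grid, rec.mine_boundary)
        mine_field = DriverField(
            factor_id="mine",
            raw=quantify_activity(rec.coal_production, d_m),
            distance=d_m,
        )
    mine_norm, b = normalize_factor(
        np.where(mine_field.raw.mask, mine_field.raw.values, np.nan),
        scope="per_year_pixels", factor_id="mine",
    )
    bounds["mine"] = b
    factors["mine"] = grid.with_values(
        np.where(mine_field.raw.mask, mine_norm, grid.nodata)
    )

    return DriverStack(
        year=year,
        factors=factors,
        normalization_bounds=bounds,
        mining_is_virtual=mining_is_virtual,
    )
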