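"""Georeferenced raster grids: the carrier for every per-pixel quantity.

A :class:`Grid` is a north-up, row-major 2D field on a square-cell raster.
Row 0 is the northernmost row; the centre of pixel ``(r, c)`` sits at
``origin + (c + 0.5, -(r + 0.5)) * cell_size`` in projected map coordinates.
All inter-pixel distances are Euclidean in projected metres and reported in
kilometres. Nodata cells are propagated, never imputed.

Rasters are read and written as single-band GeoTIFFs through :mod:`tifffile`,
carrying the standard ``ModelPixelScale``/``ModelTiepoint`` georeferencing
tags and the GDAL nodata tag, so files interoperate with ordinary GIS stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Grid", "RegionMask", "read_grid", "write_grid", "align_grids"]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A rectangular, north-up raster of real values.

    Parameters
    ----------
    values
        2D float array, row-major, row 0 = northernmost row.
    cell_size_m
        Square cell edge length in metres (> 0).
    origin_xy
        Projected map coordinates ``(x, y)`` of the *top-left corner* of
        pixel (0, 0).
    nodata
        Sentinel marking missing cells. Nodata cells are excluded from all
        statistics and never imputed.
    crs_label
        Free-text tag for the projected CRS (e.g. ``"EPSG:32650"``). The
        package performs no reprojection; it only checks labels agree.
    """

    values: np.ndarray
    cell_size_m: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    nodata: float = _DEFAULT_NODATA
    crs_label: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"Grid values must be 2D, got shape {self.values.shape}")
        if not self.cell_size_m > 0:
            raise ValueError(f"cell_size_m must be > 0, got {self.cell_size_m}")
        self.origin_xy = (float(self.origin_xy[0]), float(self.origin_xy[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        valid = np.isfinite(self.values)
        if np.isfinite(self.nodata):
            valid &= self.values != self.nodata
        return valid

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell centre, each shaped like values."""
        nr, nc = self.shape
        x0, y0 = self.origin_xy
        cols = x0 + (np.arange(nc) + 0.5) * self.cell_size_m
        rows = y0 - (np.arange(nr) + 0.5) * self.cell_size_m
        return np.meshgrid(cols, rows)

    def same_geometry(self, other: "Grid | RegionMask") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin_xy, other.origin_xy)
        )

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New Grid sharing this grid's georeferencing."""
        g = replace(self, values=np.asarray(values, dtype=float))
        if nodata is not None:
            g.nodata = nodata
        return g

    # -- statistics over valid cells ------------------------------------
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def min(self) -> float:
        return float(self.valid_values().min())

    def max(self) -> float:
        return float(self.valid_values().max())


@dataclass
class RegionMask:
    """Boolean field aligned to a reference :class:`Grid` (e.g. mine area, SRMD)."""

    values: np.ndarray
    cell_size_m: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    crs_label: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("RegionMask values must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "Grid | RegionMask") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin_xy, other.origin_xy)
        )

    def count(self) -> int:
        return int(self.values.sum())

    @classmethod
    def like(cls, grid: Grid, values: np.ndarray) -> "RegionMask":
        return cls(
            values=values,
            cell_size_m=grid.cell_size_m,
            origin_xy=grid.origin_xy,
            crs_label=grid.crs_label,
        )

    def to_grid(self, nodata: float = _DEFAULT_NODATA) -> Grid:
        return Grid(
            values=self.values.astype(float),
            cell_size_m=self.cell_size_m,
            origin_xy=self.origin_xy,
            nodata=nodata,
            crs_label=self.crs_label,
        )


def require_aligned(*grids: Grid | RegionMask) -> None:
    """Raise if any two grids differ in shape, cell size or origin.

    Downstream modules call this rather than silently broadcasting.
    """
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError(
                "grids are not aligned: "
                f"{ref.shape}@{ref.origin_xy} vs {g.shape}@{g.origin_xy}"
            )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_grid(grid: Grid, path: str | Path) -> Path:
    """Write a Grid as a single-band float GeoTIFF with georeferencing tags."""
    path = Path(path)
    x0, y0 = grid.origin_xy
    s = float(grid.cell_size_m)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    description = json.dumps({"crs_label": grid.crs_label})
    values = np.where(grid.mask, grid.values, grid.nodata)
    tifffile.imwrite(
        path,
        values.astype(np.float64),
        extratags=extratags,
        description=description,
    )
    return path


def read_grid(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF written with pixel-scale/tiepoint tags.

    Raises a :class:`ValueError` naming the file if it is not a raster or
    lacks georeferencing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
            if scale is None or tiepoint is None:
                raise ValueError(
                    f"raster {path} has no GeoTIFF georeferencing "
                    "(ModelPixelScale/ModelTiepoint tags missing)"
                )
            sx, sy = float(scale.value[0]), float(scale.value[1])
            tp = tiepoint.value
            # tiepoint maps raster (i, j) -> map (x, y); we require i = j = 0
            x0 = float(tp[3]) - float(tp[0]) * sx
            y0 = float(tp[4]) + float(tp[1]) * sy
            nodata = _DEFAULT_NODATA
            nd_tag = tags.get(_TAG_GDAL_NODATA)
            if nd_tag is not None:
                nodata = float(str(nd_tag.value))
            crs_label = "local"
            desc = tags.get("ImageDescription")
            if desc is not None:
                try:
                    crs_label = json.loads(desc.value).get("crs_label", "local")
                except (json.JSONDecodeError, AttributeError):
                    pass
    except tifffile.TiffFileError as exc:
        raise ValueError(f"not a readable raster: {path} ({exc})") from exc
    if values.ndim != 2:
        raise ValueError(f"raster {path} is not single-band 2D (shape {values.shape})")
    if not np.isclose(sx, sy):
        raise ValueError(f"raster {path} has non-square cells ({sx} x {sy} m)")
    return Grid(
        values=np.asarray(values, dtype=float),
        cell_size_m=sx,
        origin_xy=(x0, y0),
        nodata=nodata,
        crs_label=crs_label,
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_grids(grids: list[Grid]) -> list[Grid]:
    """Crop/resample a set of overlapping grids onto their common intersection.

    The first grid's cell size defines the target resolution; every output
    shares one shape, cell size and origin. Resampling is nearest-neighbour.
    Cells falling outside an input's extent become nodata. Grids that are
    already aligned are returned unchanged (same objects).

    Raises if the extents are spatially disjoint.
    """
    if not grids:
        raise ValueError("align_grids requires at least one grid")
    if all(grids[0].same_geometry(g) for g in grids[1:]):
        return list(grids)

    s = float(grids[0].cell_size_m)
    # intersection of extents  (x_min, x_max, y_min, y_max)
    x_min = max(g.origin_xy[0] for g in grids)
    y_max = min(g.origin_xy[1] for g in grids)
    x_max = min(g.origin_xy[0] + g.shape[1] * g.cell_size_m for g in grids)
    y_min = max(g.origin_xy[1] - g.shape[0] * g.cell_size_m for g in grids)
    if x_max - x_min < s or y_max - y_min < s:
        raise ValueError("grids have disjoint (or sub-cell) spatial extents")

    nc = int(round((x_max - x_min) / s))
    nr = int(round((y_max - y_min) / s))
    xs = x_min + (np.arange(nc) + 0.5) * s
    ys = y_max - (np.arange(nr) + 0.5) * s

    out: list[Grid] = []
    for g in grids:
        # nearest-neighbour sample at the target cell centres
        cols = np.floor((xs - g.origin_xy[0]) / g.cell_size_m).astype(int)
        rows = np.floor((g.origin_xy[1] - ys) / g.cell_size_m).astype(int)
        ok_c = (cols >= 0) & (cols < g.shape[1])
        ok_r = (rows >= 0) & (rows < g.shape[0])
        vals = np.full((nr, nc), g.nodata, dtype=float)
        rr, cc = np.meshgrid(rows.clip(0, g.shape[0] - 1), cols.clip(0, g.shape[1] - 1),
                             indexing="ij")
        sampled = g.values[rr, cc]
        inside = np.outer(ok_r, ok_c)
        vals[inside] = sampled[inside]
        out.append(
            Grid(values=vals, cell_size_m=s, origin_xy=(x_min, y_max),
                 nodata=g.nodata, crs_label=g.crs_label)
        )
    return out
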