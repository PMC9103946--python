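"""Fractional vegetation cover (FVC) from red/NIR reflectance.

NDVI = (rho_NIR - rho_Red) / (rho_NIR + rho_Red) is composited to the
per-year growing-season maximum, optionally harmonized across sensors by an
ordinary least-squares mapping fitted on overlapping scenes, and inverted to
FVC with the pixel dichotomy model

    FVC = (NDVI - NDVI_min) / (NDVI_max - NDVI_min),

where NDVI_min is the pure-soil endpoint and NDVI_max the pure-vegetation
endpoint, each read off the cumulative distribution of NDVI over hand-picked
pure pixels (defaults: the 5% and 95% cumulative-percentage points). FVC is
a physical fraction and is clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import Grid, require_aligned

__all__ = [
    "ReflectancePair",
    "FVCEndpoints",
    "SensorHarmonization",
    "compute_ndvi",
    "max_composite",
    "fit_sensor_harmonization",
    "chain_harmonizations",
    "apply_harmonization",
    "select_endpoints",
    "compute_fvc",
]


@dataclass
class ReflectancePair:
    """Aligned near-infrared and red surface-reflectance grids (unitless)."""

    nir: Grid
    red: Grid

    def __post_init__(self) -> None:
        require_aligned(self.nir, self.red)
        for name, g in (("nir", self.nir), ("red", self.red)):
            vals = g.valid_values()
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(
                    f"{name} reflectance outside [0, 1]: "
                    f"range [{vals.min():.4f}, {vals.max():.4f}]"
                )


@dataclass
class FVCEndpoints:
    """Pure-soil and pure-vegetation NDVI endpoints of the dichotomy model."""

    ndvi_min: float
    ndvi_max: float
    soil_percentile: float = 5.0
    veg_percentile: float = 95.0

    def __post_init__(self) -> None:
        if not -1 <= self.ndvi_min < self.ndvi_max <= 1:
            raise ValueError(
                f"need -1 <= ndvi_min < ndvi_max <= 1, got "
                f"({self.ndvi_min}, {self.ndvi_max})"
            )


@dataclass
class SensorHarmonization:
    """OLS slope/intercept mapping one sensor's NDVI onto a reference sensor."""

    slope: float
    intercept: float
    source_sensor: str = "source"
    reference_sensor: str = "reference"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("harmonization slope must be non-zero")

    def __call__(self, ndvi: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(ndvi, dtype=float) + self.intercept


def compute_ndvi(pair: ReflectancePair) -> Grid:
    """Normalized difference vegetation index per cell.

    Cells where NIR + Red = 0 (no signal) become nodata, as do cells that
    are nodata in either band.
    """
    nir, red = pair.nir, pair.red
    valid = nir.mask & red.mask
    total = nir.values + red.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir.values - red.values) / total
    valid &= total != 0
    out = np.where(valid, ndvi, nir.nodata)
    return nir.with_values(out)


def max_composite(ndvi_stack: list[Grid]) -> Grid:
    """Per-cell maximum over a stack of aligned NDVI grids, ignoring nodata.

    Emulates growing-season maximum-value compositing: the per-pixel max
    suppresses clouds and off-peak phenology. Cells that are nodata in
    every grid stay nodata.
    """
    if not ndvi_stack:
        raise ValueError("max_composite requires at least one grid")
    require_aligned(*ndvi_stack)
    ref = ndvi_stack[0]
    stack = np.stack([np.where(g.mask, g.values, -np.inf) for g in ndvi_stack])
    best = stack.max(axis=0)
    out = np.where(np.isfinite(best), best, ref.nodata)
    return ref.with_values(out)


def fit_sensor_harmonization(
    source_vals: np.ndarray,
    reference_vals: np.ndarray,
    source_sensor: str = "source",
    reference_sensor: str = "reference",
) -> SensorHarmonization:
    """Least-squares NDVI mapping from one sensor onto a reference sensor.

    Fitted on paired samples from overlapping scenes. Mappings compose, so a
    sensor without overlap with the reference can be harmonized through an
    intermediate sensor (see :func:`chain_harmonizations`).
    """
    x = np.asarray(source_vals, dtype=float).ravel()
    y = np.asarray(reference_vals, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired samples")
    if np.ptp(x) == 0:
        raise ValueError("source samples have zero variance; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return SensorHarmonization(
        slope=float(slope),
        intercept=float(intercept),
        source_sensor=source_sensor,
        reference_sensor=reference_sensor,
    )


def chain_harmonizations(
    first: SensorHarmonization, second: SensorHarmonization
) -> SensorHarmonization:
    """Compose source->intermediate with intermediate->reference.

    ``second(first(x)) = (a1*a2) x + (a2*b1 + b2)``.
    """
    return SensorHarmonization(
        slope=first.slope * second.slope,
        intercept=second.slope * first.intercept + second.intercept,
        source_sensor=first.source_sensor,
        reference_sensor=second.reference_sensor,
    )


def apply_harmonization(ndvi: Grid, h: SensorHarmonization) -> Grid:
    out = np.where(ndvi.mask, h(ndvi.values), ndvi.nodata)
    return ndvi.with_values(out)


def _cumulative_percentage_value(samples: np.ndarray, percent: float) -> float:
    """Value at the given cumulative percentage of the ascending-sorted samples.

    Nearest-rank convention: the ceil(p/100 * n)-th ascending value. This
    mirrors reading a cumulative-count curve rather than interpolating.
    """
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    if s.size == 0:
        raise ValueError("empty sample set")
    rank = max(1, math.ceil(percent / 100.0 * s.size))
    return float(s[min(rank, s.size) - 1])


def select_endpoints(
    pure_soil_ndvi: np.ndarray,
    pure_veg_ndvi: np.ndarray,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> FVCEndpoints:
    """Endpoints from NDVI samples over pure-soil and pure-vegetation pixels.

    NDVI_min is the value at the soil samples' lower cumulative-percentage
    point (default 5%), trimming low-end noise; NDVI_max the vegetation
    samples' upper point (default 95%), trimming high-end noise.
    """
    soil_p, veg_p = percentiles
    ndvi_min = _cumulative_percentage_value(pure_soil_ndvi, soil_p)
    ndvi_max = _cumulative_percentage_value(pure_veg_ndvi, veg_p)
    if ndvi_min >= ndvi_max:
        raise ValueError(
            f"degenerate endpoints: soil {ndvi_min:.4f} >= vegetation {ndvi_max:.4f}"
        )
    return FVCEndpoints(
        ndvi_min=ndvi_min, ndvi_max=ndvi_max,
        soil_percentile=soil_p, veg_percentile=veg_p,
    )


def compute_fvc(ndvi: Grid, endpoints: FVCEndpoints) -> Grid:
    """Pixel-dichotomy FVC, clipped to the physical range [0, 1].

    NDVI below the soil endpoint maps to 0, above the vegetation endpoint
    to 1; nodata is propagated.
    """
    span = endpoints.ndvi_max - endpoints.ndvi_min
    if span <= 0:
        raise ValueError("ndvi_min must be strictly below ndvi_max")
    fvc = (ndvi.values - endpoints.ndvi_min) / span
    fvc = np.clip(fvc, 0.0, 1.0)
    out = np.where(ndvi.mask, fvc, ndvi.nodata)
    return ndvi.with_values(out)
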