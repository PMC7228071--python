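"""Remote-sensing covariate engine.

Derives the modelling covariates from the raster stack:

* ``LocBrnOpn`` — percent of the 3x3-pixel (0.81 ha at 30 m) neighbourhood that
  is moderately-to-severely burned (dNBR > 270) or open (< 10% pre-fire canopy),
* ``LandBrnOpn`` — the same percentage over a 1-km-radius disc neighbourhood,
* ``LandPIPO`` — percent ponderosa-pine-dominated forest over the 1-km disc,
* ``Slope`` — topographic slope (% rise over run), taken directly,
* ``Casp`` — cosine-transformed aspect (+1 north-facing, -1 south-facing),
  forced to 0 on near-flat ground (slope <= 2%).

Neighbourhood percentages at raster edges are computed over the intersection
of the neighbourhood with the raster, so they remain valid percentages.

The disc neighbourhood uses a whole-pixel radius: a pixel belongs to the disc
when its centre lies within ``floor(radius / pixel_size)`` pixels of the focal
centre (inclusive).  At 30 m and a 1-km radius this is a 33-cell disc of
exactly 3,409 pixels for interior cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from burnhab.rasters import RasterStack

logger = logging.getLogger(__name__)

DNBR_THRESHOLD = 270.0
CANOPY_THRESHOLD = 10.0
FLAT_SLOPE_THRESHOLD = 2.0
LANDSCAPE_RADIUS_M = 1000.0


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A focal neighbourhood: the 3x3 square or a disc of given radius (m)."""

    kind: str  # "square3x3" | "radius"
    radius_m: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("square3x3", "radius"):
            raise ValueError(f"unknown neighbourhood kind {self.kind!r}")
        if self.kind == "radius" and (self.radius_m is None or self.radius_m <= 0):
            raise ValueError("radius neighbourhood requires radius_m > 0")

    def kernel(self, pixel_size: float) -> np.ndarray:
        if self.kind == "square3x3":
            return np.ones((3, 3))
        r_cells = int(np.floor(self.radius_m / pixel_size))
        if r_cells < 1:
            raise ValueError(
                f"radius {self.radius_m} m is smaller than one {pixel_size} m pixel"
            )
        ii, jj = np.meshgrid(np.arange(-r_cells, r_cells + 1), np.arange(-r_cells, r_cells + 1))
        return (ii**2 + jj**2 <= r_cells**2).astype(float)


def burned_or_open_mask(
    landscape: RasterStack,
    dnbr_threshold: float = DNBR_THRESHOLD,
    canopy_threshold: float = CANOPY_THRESHOLD,
) -> np.ndarray:
    """Binary raster: burned moderately-to-severely OR open pre-fire canopy.

    Both thresholds are strict (dNBR > 270, canopy < 10%); ties fall outside
    the mask.  Non-forest pixels are expected to carry canopy cover 0 (hence
    open) in the input layer.
    """
    for name in ("dnbr", "canopy"):
        if name not in landscape:
            raise ValueError(f"burned_or_open_mask requires layer {name!r}")
    return (landscape["dnbr"] > dnbr_threshold) | (landscape["canopy"] < canopy_threshold)


def neighborhood_percent(
    mask: np.ndarray, spec: NeighborhoodSpec, pixel_size: float = 30.0
) -> np.ndarray:
    """Per-pixel percentage of neighbourhood pixels that are True.

    Edge pixels use the intersected neighbourhood as denominator.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary")
    kernel = spec.kernel(pixel_size)
    num = signal.fftconvolve(mask.astype(float), kernel, mode="same")
    den = signal.fftconvolve(np.ones(mask.shape), kernel, mode="same")
    return np.clip(100.0 * num / den, 0.0, 100.0)


def cosine_aspect(
    slope_pct: np.ndarray,
    aspect_deg: np.ndarray,
    flat_threshold: float = FLAT_SLOPE_THRESHOLD,
) -> np.ndarray:
    """cos(aspect) where slope exceeds the flat threshold, else 0.

    Aspect is degrees clockwise from north, so the transform is +1 on
    north-facing and -1 on south-facing slopes.
    """
    return np.where(
        np.asarray(slope_pct) > flat_threshold,
        np.cos(np.deg2rad(np.asarray(aspect_deg))),
        0.0,
    )


def remote_covariate_stack(
    landscape: RasterStack,
    dnbr_threshold: float = DNBR_THRESHOLD,
    canopy_threshold: float = CANOPY_THRESHOLD,
    landscape_radius_m: float = LANDSCAPE_RADIUS_M,
) -> RasterStack:
    """Compute the remote covariates as rasters on the landscape grid."""
    mask = burned_or_open_mask(landscape, dnbr_threshold, canopy_threshold)
    local = NeighborhoodSpec("square3x3")
    disc = NeighborhoodSpec("radius", landscape_radius_m)
    layers = {
        "Slope": landscape["slope"],
        "Casp": cosine_aspect(landscape["slope"], landscape["aspect"]),
        "LocBrnOpn": neighborhood_percent(mask, local, landscape.pixel_size),
        "LandBrnOpn": neighborhood_percent(mask, disc, landscape.pixel_size),
        "LandPIPO": neighborhood_percent(landscape["pine"].astype(bool), disc, landscape.pixel_size),
    }
    return RasterStack(
        layers=layers,
        pixel_size=landscape.pixel_size,
        origin=landscape.origin,
        meta=dict(landscape.meta),
    )


def extract_covariates(
    sites,
    stacks_by_year: dict[int, RasterStack] | RasterStack,
    columns: list[str],
    available_year: int | None = None,
):
    """Attach raster covariates to sites with year-aware rules.

    Nests take values from the raster stack of the year they were found
    (``year`` column); non-nests take the mean across all surveyed years;
    available sites take values from ``available_year`` (default: earliest).
    Sites outside the raster extent are dropped with a log entry.
    """
    if isinstance(stacks_by_year, RasterStack):
        stacks_by_year = {1: stacks_by_year}
    years = sorted(stacks_by_year)
    if available_year is None:
        available_year = years[0]
    ref = stacks_by_year[years[0]]

    sites = sites.copy()
    inside = ref.in_extent(sites["x"].to_numpy(), sites["y"].to_numpy())
    if not inside.all():
        dropped = sites.loc[~inside, "id"].tolist()
        logger.warning("excluding %d sites outside raster extent: %s", len(dropped), dropped)
        sites = sites.loc[inside].reset_index(drop=True)

    x = sites["x"].to_numpy()
    y = sites["y"].to_numpy()
    role = sites["role"].to_numpy()
    for col in columns:
        per_year = np.stack([stacks_by_year[yr].value_at(col, x, y) for yr in years])
        year_index = {yr: i for i, yr in enumerate(years)}
        out = np.empty(len(sites))
        for i in range(len(sites)):
            if role[i] == "nest":
                yr = int(sites["year"].iloc[i])
                out[i] = per_year[year_index.get(yr, 0), i]
            elif role[i] == "non-nest":
                out[i] = per_year[:, i].mean()
            else:
                out[i] = per_year[year_index[available_year], i]
        sites[col] = out
    return sites


def rescale_plot_counts(count, plot_area_ha: float):
    """Convert a plot count to a per-hectare density."""
    if plot_area_ha <= 0:
        raise ValueError("plot_area_ha must be > 0")
    if np.any(np.asarray(count) < 0):
        raise ValueError("counts must be >= 0")
    return np.asarray(count, dtype=float) / plot_area_ha
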