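"""Raster and site-table I/O.

Rasters live in memory as a :class:`RasterStack` (named 2-D float arrays on one
grid) and on disk as multi-band TIFF with a JSON header in the ImageDescription
tag carrying grid origin, pixel size, band names and provenance (seed, params).
Site tables are plain CSV with a documented schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

#: Columns every site table must carry. Covariate columns are optional and
#: validated where they are consumed.
SITE_REQUIRED_COLUMNS = ["id", "x", "y", "role", "location", "year", "cell_id"]

ROLES = ("nest", "non-nest", "available")


@dataclass
class RasterStack:
    """Co-registered named raster layers on a common square grid.

    Rows are indexed south-to-north: row 0 is the southernmost row, so the
    y-coordinate of the centre of pixel (row, col) is
    ``origin_y + (row + 0.5) * pixel_size``.  Point-in-pixel containment uses
    the pixel-centre convention (a point belongs to the pixel whose centre is
    nearest in the floor sense).
    """

    layers: dict[str, np.ndarray]
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers are not co-registered: shapes {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise KeyError(f"raster stack has no layer {name!r}; has {sorted(self.layers)}")
        return self.layers[name]

    def pixel_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of pixels containing points (x, y) in map units."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.pixel_size).astype(int)
        return row, col

    def in_extent(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.pixel_index(x, y)
        ny, nx = self.shape
        return (row >= 0) & (row < ny) & (col >= 0) & (col < nx)

    def value_at(self, name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.pixel_index(x, y)
        return self[name][row, col]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened x, y centre coordinates of every pixel (row-major)."""
        ny, nx = self.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.pixel_size
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()


def write_raster(stack: RasterStack, path) -> None:
    """Write a stack as multi-band TIFF with a JSON metadata header."""
    names = sorted(stack.layers)
    data = np.stack([stack.layers[n].astype(np.float64) for n in names])
    header = {
        "bands": names,
        "pixel_size": stack.pixel_size,
        "origin": list(stack.origin),
        "meta": stack.meta,
    }
    tifffile.imwrite(path, data, description=json.dumps(header))


def read_raster(path) -> RasterStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        header = json.loads(tif.pages[0].tags["ImageDescription"].value)
    if data.ndim == 2:
        data = data[None]
    layers = {name: data[i] for i, name in enumerate(header["bands"])}
    return RasterStack(
        layers=layers,
        pixel_size=float(header["pixel_size"]),
        origin=tuple(header["origin"]),
        meta=header.get("meta", {}),
    )


def write_sites(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, index=False)


def read_sites(path) -> pd.DataFrame:
    """Read a site CSV, validating schema and row contents.

    Raises ``ValueError`` naming every missing required column, and rejecting
    malformed rows (unknown role) with their 1-based CSV line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in SITE_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} is missing required columns: {missing}")
    bad = ~df["role"].isin(ROLES)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise ValueError(f"site table {path}: invalid 'role' values at CSV lines {lines}")
    return df
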