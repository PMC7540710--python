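"""Raster grid conventions and file I/O.

All rasters in this package are plain numpy arrays on a shared north-up
grid: axis 0 is row (top to bottom), axis 1 is column (left to right),
0-based indices, and the centre of pixel ``(r, c)`` sits at map
coordinates ``x = c * pixel_size``, ``y = r * pixel_size``. Pixel area is
``pixel_size**2`` everywhere (no geodesic correction); scenes are
desk-scale, so the flat-grid approximation is documented as a limitation
rather than corrected for.

Rasters are written as TIFF with a small JSON sidecar carrying the grid
metadata (pixel size, nodata value, band names); vectors are GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

M2_PER_HA = 10_000.0
HA_PER_KM2 = 100.0


@dataclass(frozen=True)
class Grid:
    """Shape and scale of a scene raster stack."""

    rows: int
    cols: int
    pixel_size: float = 30.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size**2 / M2_PER_HA

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every pixel centre, each (rows, cols)."""
        c, r = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        return c * self.pixel_size, r * self.pixel_size

    def validate_like(self, arr: np.ndarray, name: str = "raster") -> None:
        if arr.shape[-2:] != self.shape:
            raise ValueError(
                f"{name} shape {arr.shape} does not match grid {self.shape}"
            )


def write_raster(path: str | Path, arr: np.ndarray, grid: Grid,
                 nodata: float | int | None = None,
                 band_names: list[str] | None = None) -> None:
    """Write a 2-D or (bands, rows, cols) raster as TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(arr))
    meta = {
        "pixel_size": grid.pixel_size,
        "rows": grid.rows,
        "cols": grid.cols,
        "nodata": nodata,
        "band_names": band_names,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid, dict]:
    path = Path(path)
    arr = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = Grid(meta["rows"], meta["cols"], meta["pixel_size"])
    return arr, grid, meta


def write_geojson(path: str | Path, geoms, properties: list[dict] | None = None) -> None:
    """Write shapely geometries (+ per-feature properties) as GeoJSON."""
    geoms = list(geoms)
    if properties is None:
        properties = [{} for _ in geoms]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, properties, strict=True)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_geojson(path: str | Path) -> tuple[list, list[dict]]:
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties", {}) for f in doc["features"]]
    return geoms, props
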