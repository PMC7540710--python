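"""Scene directory persistence.

A scene directory holds one multi-band TIFF per acquisition date
(NaN marks cloud-masked observations), the baseline mangrove mask,
ancillary masks, ground-truth rasters, region polygons as GeoJSON, the
truth area table as CSV, and the scene config as YAML — all plain text
or uncompressed TIFF, reloadable into an identical
:class:`~mangrove_drivers.synthetic.SceneBundle`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import read_geojson, read_raster, write_geojson, write_raster
from .indices import BAND_NAMES
from .synthetic import (AncillaryLayers, EventSpec, GroundTruthMap,
                        SceneBundle, SceneConfig)

_MASKS = ("mangrove_mask", "ocean_mask", "roads", "settlement_mask",
          "agriculture_mask")


def config_to_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    d["endmember_table"] = {k: list(v) for k, v in d["endmember_table"].items()}
    return d


def config_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    d["event_specs"] = [EventSpec(**e) for e in d.get("event_specs", [])]
    d["endmember_table"] = {
        k: tuple(v) for k, v in d["endmember_table"].items()
    }
    return SceneConfig(**d)


def save_scene(bundle: SceneBundle, scene_dir: str | Path) -> Path:
    scene_dir = Path(scene_dir)
    (scene_dir / "reflectance").mkdir(parents=True, exist_ok=True)
    grid = bundle.grid
    for t, date in enumerate(bundle.dates):
        write_raster(scene_dir / "reflectance" / f"{date}.tif",
                     bundle.reflectance[t], grid, nodata=float("nan"),
                     band_names=list(BAND_NAMES))
    for name in _MASKS:
        src = bundle if name == "mangrove_mask" else bundle.ancillary
        write_raster(scene_dir / f"{name}.tif",
                     getattr(src, name).astype(np.uint8), grid, nodata=None)
    write_raster(scene_dir / "truth_driver.tif", bundle.truth.driver_label,
                 grid, nodata=0)
    write_raster(scene_dir / "truth_epoch.tif", bundle.truth.loss_epoch,
                 grid, nodata=0)
    bundle.truth.true_areas.to_csv(scene_dir / "truth_areas.csv", index=False)
    geoms = [g for g, _ in bundle.ancillary.region_polygons]
    props = [p for _, p in bundle.ancillary.region_polygons]
    write_geojson(scene_dir / "regions.geojson", geoms, props)
    (scene_dir / "scene.yaml").write_text(
        yaml.safe_dump(config_to_dict(bundle.config)))
    return scene_dir


def load_scene(scene_dir: str | Path) -> SceneBundle:
    scene_dir = Path(scene_dir)
    if not scene_dir.is_dir():
        raise FileNotFoundError(f"scene directory not found: {scene_dir}")
    config = config_from_dict(
        yaml.safe_load((scene_dir / "scene.yaml").read_text()))
    grid = config.grid
    dates = config.dates
    reflectance = np.empty((len(dates), len(BAND_NAMES), *grid.shape),
                           np.float32)
    for t, date in enumerate(dates):
        arr, _, _ = read_raster(scene_dir / "reflectance" / f"{date}.tif")
        reflectance[t] = arr
    valid = ~np.isnan(reflectance).any(axis=1)
    masks = {}
    for name in _MASKS:
        arr, _, _ = read_raster(scene_dir / f"{name}.tif")
        masks[name] = arr.astype(bool)
    driver, _, _ = read_raster(scene_dir / "truth_driver.tif")
    epoch, _, _ = read_raster(scene_dir / "truth_epoch.tif")
    areas = pd.read_csv(scene_dir / "truth_areas.csv")
    geoms, props = read_geojson(scene_dir / "regions.geojson")
    ancillary = AncillaryLayers(
        ocean_mask=masks["ocean_mask"], roads=masks["roads"],
        settlement_mask=masks["settlement_mask"],
        agriculture_mask=masks["agriculture_mask"],
        region_polygons=list(zip(geoms, props)),
    )
    truth = GroundTruthMap(driver.astype(np.uint8), epoch.astype(np.uint8), areas)
    return SceneBundle(config, grid, dates, reflectance, valid,
                       masks["mangrove_mask"], ancillary, truth)
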