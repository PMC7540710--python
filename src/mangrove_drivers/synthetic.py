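"""Seeded synthetic coastal scenes for end-to-end pipeline testing.

A scene is a desk-scale stand-in for a Landsat surface-reflectance
archive over a mangrove coastline: a monthly six-band reflectance time
series on a 30 m grid spanning 1998-01..2016-12, a baseline mangrove
extent mask, ancillary infrastructure layers, and a ground-truth map of
driver-specific conversion events. Every stochastic element (reflectance
noise, per-pixel-date cloud gaps) is driven by one integer seed, so two
calls with the same config produce bit-identical bundles.

The scene layout is deterministic: an open-ocean strip along the left
(west) edge, a mangrove band beside it, and an inland zone carrying
roads, a settlement block and an agriculture block. Conversion events
are rectangles carved inside the mangrove band in driver-specific
zones chosen so each driver's diagnostic evidence holds by construction:
erosion fronts grow inward from the ocean edge (post-conversion water is
8-connected to ocean), commodity ponds are enclosed basins, settlement
patches abut the settlement block, non-productive-conversion dieback
abuts a road, and extreme-weather dieback is isolated from all
infrastructure and more than a shoreline band away from the ocean.

Class spectra come from one editable endmember table (mean reflectance
per band); noise is i.i.d. Gaussian per pixel-date-band, truncated to
[0, 1], and clouds are i.i.d. Bernoulli per pixel-date with no spatial
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grid import Grid
from .indices import BAND_NAMES

DRIVERS = ("ER", "CM", "ST", "NPC", "EWE")
DRIVER_CODES = {"none": 0, "ER": 1, "CM": 2, "ST": 3, "NPC": 4, "EWE": 5}
DRIVER_FROM_CODE = {v: k for k, v in DRIVER_CODES.items()}

EPOCH_NAMES = ("loss2005", "loss2010", "loss2016")
EPOCH_CODES = {"none": 0, "loss2005": 1, "loss2010": 2, "loss2016": 3}
# half-open [start, end) windows tiling 2000..2016
EPOCH_WINDOWS = {
    "loss2005": (np.datetime64("2000-01-01"), np.datetime64("2005-01-01")),
    "loss2010": (np.datetime64("2005-01-01"), np.datetime64("2010-01-01")),
    "loss2016": (np.datetime64("2010-01-01"), np.datetime64("2017-01-01")),
}
EPOCH_YEARS = {"loss2005": 5, "loss2010": 5, "loss2016": 6}

# post-conversion land cover for each driver
POST_CLASS = {
    "ER": "water",
    "CM": "water",
    "ST": "dry_soil",
    "NPC": "wet_soil",
    "EWE": "wet_soil",
}

# Mean reflectance (blue, green, red, nir, swir1, swir2) per class.
# Chosen for class separability, not radiometric realism: mangrove
# NDVI = 0.75, wet soil 0.15, dry soil 0.10, water -0.30.
DEFAULT_ENDMEMBERS: dict[str, tuple[float, ...]] = {
    "mangrove": (0.04, 0.06, 0.05, 0.35, 0.16, 0.08),
    "water":    (0.06, 0.05, 0.065, 0.035, 0.02, 0.01),
    "wet_soil": (0.08, 0.12, 0.17, 0.23, 0.18, 0.12),
    "dry_soil": (0.18, 0.22, 0.27, 0.33, 0.40, 0.35),
}


def monthly_dates(start: str = "1998-01", end: str = "2016-12") -> np.ndarray:
    """Mid-month acquisition dates, one per calendar month, as datetime64[D]."""
    months = np.arange(np.datetime64(start, "M"), np.datetime64(end, "M") + 1)
    return months.astype("datetime64[D]") + 14


@dataclass(frozen=True)
class EventSpec:
    """One driver-specific conversion event."""

    driver: str                 # ER | CM | ST | NPC | EWE
    area_ha: float              # target area; quantized to whole pixels
    converted: str              # conversion date, e.g. "2003-07-15"

    def __post_init__(self):
        if self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.area_ha <= 0:
            raise ValueError("event area must be positive")


def default_events() -> list[EventSpec]:
    """One 90 ha event per driver, spread over the three epochs."""
    return [
        EventSpec("ER", 90.0, "2003-07-15"),
        EventSpec("CM", 90.0, "2003-01-15"),
        EventSpec("ST", 90.0, "2007-06-15"),
        EventSpec("NPC", 90.0, "2007-01-15"),
        EventSpec("EWE", 90.0, "2010-07-15"),
    ]


@dataclass(frozen=True)
class SceneConfig:
    grid_rows: int = 200
    grid_cols: int = 200
    pixel_size: float = 30.0
    cloud_fraction: float = 0.3
    noise_sigma: float = 0.02
    endmember_table: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ENDMEMBERS)
    )
    event_specs: list[EventSpec] = field(default_factory=default_events)
    date_start: str = "1998-01"
    date_end: str = "2016-12"
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 32 or self.grid_cols < 32:
            raise ValueError("grid dims must be >= 32")
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for cls, row in self.endmember_table.items():
            if len(row) != len(BAND_NAMES):
                raise ValueError(f"endmember row for {cls!r} must have 6 bands")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_rows, self.grid_cols, self.pixel_size)

    @property
    def dates(self) -> np.ndarray:
        d = monthly_dates(self.date_start, self.date_end)
        if not np.all(np.diff(d) > np.timedelta64(0, "D")):
            raise ValueError("date axis must be strictly increasing")
        return d


@dataclass
class AncillaryLayers:
    ocean_mask: np.ndarray       # bool; open-ocean seed region, touches an edge
    roads: np.ndarray            # bool
    settlement_mask: np.ndarray  # bool
    agriculture_mask: np.ndarray # bool
    region_polygons: list[tuple]  # (shapely polygon, {"region": name})


@dataclass
class GroundTruthMap:
    driver_label: np.ndarray     # uint8, DRIVER_CODES
    loss_epoch: np.ndarray       # uint8, EPOCH_CODES
    true_areas: pd.DataFrame     # columns: driver, epoch, n_pixels, area_ha


@dataclass
class SceneBundle:
    config: SceneConfig
    grid: Grid
    dates: np.ndarray                 # (n_dates,) datetime64[D]
    reflectance: np.ndarray           # (n_dates, 6, rows, cols) float32, NaN=masked
    valid: np.ndarray                 # (n_dates, rows, cols) bool
    mangrove_mask: np.ndarray         # bool baseline extent
    ancillary: AncillaryLayers
    truth: GroundTruthMap


# ---------------------------------------------------------------------------
# scene layout


def _layout(config: SceneConfig) -> dict:
    """Deterministic zone geometry derived from the grid dimensions."""
    rows, cols = config.grid_rows, config.grid_cols
    ps = config.pixel_size
    ocean_w = max(4, cols // 10)
    mang_c0 = ocean_w
    mang_c1 = ocean_w + cols // 2          # exclusive
    shoreline_px = math.ceil(300.0 / ps)   # matches default shoreline band
    return {
        "ocean_cols": (0, ocean_w),
        "mangrove_cols": (mang_c0, mang_c1),
        "road_col": mang_c1,
        "road_rows": (0, rows // 3),
        "settlement": (rows // 2, rows // 2 + (2 * rows) // 5,
                       mang_c1, min(cols, mang_c1 + max(2, cols // 10))),
        "agriculture": (0, rows // 4,
                        min(cols - 1, mang_c1 + (3 * cols) // 20),
                        min(cols, mang_c1 + (3 * cols) // 20 + max(2, cols // 10))),
        # event zones: (r0, r1, c_start, fill_direction)
        "zones": {
            "ER":  (0, rows // 4, mang_c0, +1),
            "NPC": (0, rows // 4, mang_c1 - 1, -1),
            "CM":  ((3 * rows) // 10, (11 * rows) // 20, mang_c0 + 2, +1),
            "ST":  (rows // 2, rows // 2 + (2 * rows) // 5, mang_c1 - 1, -1),
            "EWE": ((3 * rows) // 4, rows,
                    mang_c0 + shoreline_px + 1, +1),
        },
    }


def _base_masks(config: SceneConfig, lay: dict):
    rows, cols = config.grid_rows, config.grid_cols
    ocean = np.zeros((rows, cols), bool)
    ocean[:, lay["ocean_cols"][0]:lay["ocean_cols"][1]] = True
    mangrove = np.zeros((rows, cols), bool)
    mangrove[:, lay["mangrove_cols"][0]:lay["mangrove_cols"][1]] = True
    roads = np.zeros((rows, cols), bool)
    r0, r1 = lay["road_rows"]
    roads[r0:r1, lay["road_col"]] = True
    settlement = np.zeros((rows, cols), bool)
    sr0, sr1, sc0, sc1 = lay["settlement"]
    settlement[sr0:sr1, sc0:sc1] = True
    agriculture = np.zeros((rows, cols), bool)
    ar0, ar1, ac0, ac1 = lay["agriculture"]
    agriculture[ar0:ar1, ac0:ac1] = True
    return ocean, mangrove, roads, settlement, agriculture


def _default_regions(config: SceneConfig) -> list[tuple]:
    """Two labelled half-scene regions (north/south split by row)."""
    rows, cols, ps = config.grid_rows, config.grid_cols, config.pixel_size
    x0, x1 = -ps / 2, (cols - 0.5) * ps
    y_mid = (rows / 2 - 0.5) * ps
    y1 = (rows - 0.5) * ps
    return [
        (box(x0, -ps / 2, x1, y_mid), {"region": "north"}),
        (box(x0, y_mid, x1, y1), {"region": "south"}),
    ]


def _carve_event(truth: np.ndarray, zone: tuple, n_px: int, code: int,
                 mangrove: np.ndarray, driver: str) -> None:
    """Fill n_px pixels column-by-column inside the zone rectangle."""
    r0, r1, c_start, step = zone
    height = r1 - r0
    placed = 0
    c = c_start
    while placed < n_px:
        if c < 0 or c >= truth.shape[1]:
            raise ValueError(
                f"event {driver}: area exceeds available mangrove zone")
        take = min(height, n_px - placed)
        rows_sel = slice(r0, r0 + take)
        col_block = truth[rows_sel, c]
        if not mangrove[rows_sel, c].all():
            raise ValueError(
                f"event {driver}: area exceeds available mangrove zone")
        if (col_block != 0).any():
            raise ValueError(f"event {driver}: overlapping events")
        truth[rows_sel, c] = code
        placed += take
        c += step


def _epoch_of_date(date: np.datetime64) -> str:
    for name, (start, end) in EPOCH_WINDOWS.items():
        if start <= date < end:
            return name
    raise ValueError(f"conversion date {date} outside the 2000-2016 epochs")


# ---------------------------------------------------------------------------
# reflectance


def simulate_reflectance(class_label: str, date, config: SceneConfig,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Six-band reflectance draw for one class at one date.

    Endmember mean plus Gaussian noise (sigma = ``config.noise_sigma``),
    truncated to [0, 1]. The date does not alter the mean (no seasonality
    model); it is accepted for interface symmetry with the time series.
    """
    if class_label not in config.endmember_table:
        raise ValueError(f"unknown class {class_label!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mean = np.asarray(config.endmember_table[class_label], dtype=float)
    vec = mean + rng.normal(0.0, config.noise_sigma, size=mean.shape)
    return np.clip(vec, 0.0, 1.0)


def generate_scene(config: SceneConfig) -> SceneBundle:
    """Generate a fully specified scene bundle from a config.

    Deterministic given ``config.seed``. Before an event's conversion
    date its pixels carry mangrove spectra; from the conversion date on
    they carry the driver's post-conversion class spectra.
    """
    grid = config.grid
    dates = config.dates
    lay = _layout(config)
    ocean, mangrove, roads, settlement, agriculture = _base_masks(config, lay)

    # ground truth
    truth_driver = np.zeros(grid.shape, np.uint8)
    converted_dates: list[np.datetime64] = []
    for ev in config.event_specs:
        n_px = round(ev.area_ha / grid.pixel_area_ha)
        if n_px == 0:
            raise ValueError(f"event {ev.driver}: area below one pixel")
        _carve_event(truth_driver, lay["zones"][ev.driver], n_px,
                     DRIVER_CODES[ev.driver], mangrove, ev.driver)
        converted_dates.append(np.datetime64(ev.converted))

    loss_epoch = np.zeros(grid.shape, np.uint8)
    rows_areas = []
    for ev, conv in zip(config.event_specs, converted_dates):
        sel = truth_driver == DRIVER_CODES[ev.driver]
        epoch = _epoch_of_date(conv)
        loss_epoch[sel] = EPOCH_CODES[epoch]
        n_px = int(sel.sum())
        rows_areas.append({
            "driver": ev.driver, "epoch": epoch, "n_pixels": n_px,
            "area_ha": n_px * grid.pixel_area_ha,
        })
    true_areas = pd.DataFrame(
        rows_areas, columns=["driver", "epoch", "n_pixels", "area_ha"])

    # base class index map; inland background is dry soil
    class_names = list(config.endmember_table)
    class_idx = {c: i for i, c in enumerate(class_names)}
    base = np.full(grid.shape, class_idx["dry_soil"], np.int8)
    base[mangrove] = class_idx["mangrove"]
    base[ocean] = class_idx["water"]
    base[agriculture] = class_idx["wet_soil"]

    endm = np.array([config.endmember_table[c] for c in class_names], float)

    rng = np.random.default_rng(config.seed)
    n_dates = len(dates)
    reflectance = np.empty((n_dates, len(BAND_NAMES), *grid.shape), np.float32)
    valid = np.empty((n_dates, *grid.shape), bool)
    post_idx = {
        ev.driver: class_idx[POST_CLASS[ev.driver]] for ev in config.event_specs
    }
    for t, date in enumerate(dates):
        cmap = base.copy()
        for ev, conv in zip(config.event_specs, converted_dates):
            if date >= conv:
                cmap[truth_driver == DRIVER_CODES[ev.driver]] = post_idx[ev.driver]
        clouds = rng.random(grid.shape) < config.cloud_fraction
        noise = rng.standard_normal(
            (len(BAND_NAMES), *grid.shape), dtype=np.float32)
        img = endm[cmap].transpose(2, 0, 1).astype(np.float32)
        img += noise * np.float32(config.noise_sigma)
        np.clip(img, 0.0, 1.0, out=img)
        img[:, clouds] = np.nan
        reflectance[t] = img
        valid[t] = ~clouds

    ancillary = AncillaryLayers(
        ocean_mask=ocean, roads=roads, settlement_mask=settlement,
        agriculture_mask=agriculture,
        region_polygons=_default_regions(config),
    )
    truth = GroundTruthMap(truth_driver, loss_epoch, true_areas)
    return SceneBundle(config, grid, dates, reflectance, valid,
                       mangrove_mask=mangrove, ancillary=ancillary, truth=truth)


def noise_free(config: SceneConfig) -> SceneConfig:
    """Copy of a config with noise and clouds switched off."""
    return replace(config, cloud_fraction=0.0, noise_sigma=0.0)


def sample_training_points(bundle: SceneBundle, n_per_class: int = 30,
                           seed: int = 0) -> list[tuple[float, float, str]]:
    """Labelled (x, y, label) training points drawn from scene truth.

    Stands in for photo-interpreted points: one pixel centre per sample,
    drawn from the interior (eroded by the buffer radius) of each
    end-of-record land cover class so the one-hectare buffers stay
    label-pure. Classes are the three trainable covers wet soil, dry
    soil and water.
    """
    from scipy import ndimage

    ocean = bundle.ancillary.ocean_mask
    agri = bundle.ancillary.agriculture_mask
    truth = bundle.truth.driver_label
    post_water = np.isin(truth, [DRIVER_CODES["ER"], DRIVER_CODES["CM"]])
    post_wet = np.isin(truth, [DRIVER_CODES["NPC"], DRIVER_CODES["EWE"]])
    post_dry = truth == DRIVER_CODES["ST"]
    background_dry = ~bundle.mangrove_mask & ~ocean & ~agri
    class_masks = {
        "water": ocean | post_water,
        "wet_soil": agri | post_wet,
        "dry_soil": background_dry | post_dry,
    }
    rng = np.random.default_rng(seed)
    ps = bundle.grid.pixel_size
    erode_px = math.ceil(math.sqrt(10_000 / math.pi) / ps) + 1
    points = []
    for label, mask in class_masks.items():
        interior = ndimage.binary_erosion(mask, iterations=erode_px)
        if not interior.any():
            interior = mask
        rows, cols = np.nonzero(interior)
        if rows.size == 0:
            raise ValueError(f"no candidate pixels for class {label!r}")
        pick = rng.choice(rows.size, size=min(n_per_class, rows.size),
                         replace=False)
        points += [(cols[i] * ps, rows[i] * ps, label) for i in pick]
    return points
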