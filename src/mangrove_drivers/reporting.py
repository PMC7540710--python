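"""Regional, epoch and driver-level reporting arithmetic.

Turns driver maps into per-region/per-epoch/per-driver area tables and
the derived headline numbers: integer percentage shares, the
anthropogenic (CM + ST + NPC) vs natural (ER + EWE) split, annualized
loss rates (area divided by nominal epoch length: 5, 5 and 6 years),
percent declines between the first and last epoch, and the primary
driver of a region. All outputs are pure functions of the area table.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

from .attribution import UNATTRIBUTED_CODE, DriverMap
from .grid import HA_PER_KM2, Grid
from .synthetic import DRIVER_FROM_CODE, DRIVERS, EPOCH_CODES, EPOCH_YEARS

ANTHROPOGENIC = ("CM", "ST", "NPC")
NATURAL = ("ER", "EWE")


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def regional_summary(driver_map: DriverMap, epoch_label: np.ndarray,
                     region_polygons: list[tuple[BaseGeometry, dict]],
                     grid: Grid) -> pd.DataFrame:
    """Area (km^2) per (region, epoch, driver), from pixel counts.

    Pixel membership is by pixel centre; pixels outside every polygon
    are reported under region ``unassigned``. Overlapping polygons are
    an error, so the region partition is unambiguous.
    """
    xs, ys = grid.pixel_centers()
    region = np.full(grid.shape, "unassigned", dtype=object)
    seen = np.zeros(grid.shape, bool)
    for geom, props in region_polygons:
        inside = contains_xy(geom, xs, ys)
        if (inside & seen).any():
            raise ValueError("region polygons overlap")
        region[inside] = props.get("region", "region")
        seen |= inside

    px_km2 = grid.pixel_area_ha / HA_PER_KM2
    rows = []
    attributed = (driver_map.drivers > 0) & (driver_map.drivers != UNATTRIBUTED_CODE)
    for name, code in EPOCH_CODES.items():
        if name == "none":
            continue
        in_epoch = (epoch_label == code) & attributed
        for reg in np.unique(region[in_epoch]) if in_epoch.any() else []:
            sel = in_epoch & (region == reg)
            for d in DRIVERS:
                n = int(np.sum(driver_map.drivers[sel] == _code(d)))
                if n:
                    rows.append({"region": reg, "epoch": name, "driver": d,
                                 "area_km2": n * px_km2})
    df = pd.DataFrame(rows, columns=["region", "epoch", "driver", "area_km2"])
    return df.sort_values(["region", "epoch", "driver"]).reset_index(drop=True)


def _code(driver: str) -> int:
    from .synthetic import DRIVER_CODES
    return DRIVER_CODES[driver]


def unattributed_area_km2(driver_map: DriverMap, grid: Grid) -> float:
    n = int(np.sum(driver_map.drivers == UNATTRIBUTED_CODE))
    return n * grid.pixel_area_ha / HA_PER_KM2


def driver_shares(areas: dict[str, float]) -> dict[str, int]:
    """Integer percentage share per driver (round half away from zero)."""
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("total area must be positive")
    return {d: _round_half_away(100.0 * a / total) for d, a in areas.items()}


def anthro_natural_split(areas: dict[str, float]) -> dict:
    """Anthropogenic (CM+ST+NPC) vs natural (ER+EWE) totals and shares."""
    anthro = sum(areas.get(d, 0.0) for d in ANTHROPOGENIC)
    natural = sum(areas.get(d, 0.0) for d in NATURAL)
    total = anthro + natural
    out = {"anthropogenic_km2": anthro, "natural_km2": natural}
    if total > 0:
        out["anthropogenic_pct"] = _round_half_away(100.0 * anthro / total)
        out["natural_pct"] = _round_half_away(100.0 * natural / total)
    return out


def epoch_rates(areas_by_epoch: dict[str, float],
                epoch_years: dict[str, int] = EPOCH_YEARS) -> dict[str, float]:
    """Annualized loss rate per epoch: area / nominal epoch length."""
    rates = {}
    for epoch, area in areas_by_epoch.items():
        if epoch not in epoch_years:
            raise ValueError(f"unknown epoch {epoch!r}")
        rates[epoch] = area / epoch_years[epoch]
    return rates


def percent_change(first_area: float, last_area: float) -> dict:
    """Percent decline from the first to the last epoch.

    Returns full precision plus two integer renderings (truncated and
    conventionally rounded); published declines mix the two conventions.
    """
    if first_area <= 0:
        raise ValueError("first-epoch area must be positive")
    exact = 100.0 * (first_area - last_area) / first_area
    return {"exact": exact, "truncated": math.trunc(exact),
            "rounded": _round_half_away(exact)}


def primary_driver(areas: dict[str, float]) -> str:
    """Driver with the largest area; ties break in the order ER<CM<ST<NPC<EWE."""
    positive = {d: a for d, a in areas.items() if a > 0}
    if not positive:
        raise ValueError("no positive driver area")
    return max(DRIVERS, key=lambda d: (positive.get(d, 0.0), -DRIVERS.index(d)))


def global_areas(summary: pd.DataFrame) -> dict[str, float]:
    """Total area per driver summed over regions and epochs."""
    g = summary.groupby("driver")["area_km2"].sum()
    return {d: float(g.get(d, 0.0)) for d in DRIVERS}


def epoch_areas(summary: pd.DataFrame, drivers=None) -> dict[str, float]:
    """Total area per epoch, optionally restricted to a driver subset."""
    df = summary if drivers is None else summary[summary["driver"].isin(drivers)]
    g = df.groupby("epoch")["area_km2"].sum()
    return {e: float(g.get(e, 0.0)) for e in EPOCH_YEARS}


def derived_columns(summary: pd.DataFrame) -> pd.DataFrame:
    """Long-format table with share, rate and anthropogenic columns added."""
    df = summary.copy()
    totals = df.groupby(["region", "epoch"])["area_km2"].transform("sum")
    df["share_pct"] = [
        _round_half_away(v) for v in 100.0 * df["area_km2"] / totals
    ] if len(df) else []
    df["rate_km2_yr"] = [
        a / EPOCH_YEARS[e] for a, e in zip(df["area_km2"], df["epoch"])
    ] if len(df) else []
    df["anthropogenic"] = df["driver"].isin(ANTHROPOGENIC)
    return df
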