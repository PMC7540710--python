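"""Proximate-driver attribution of classified loss pixels.

Each loss pixel, already labelled wet soil, dry soil or water, passes
through a fixed per-class rule cascade (a hand-built decision tree) that
uses ancillary evidence — ocean connectivity and distance to roads,
settlement, and agriculture/aquaculture — to assign one of five
proximate drivers:

* ER  — shoreline erosion (ocean-connected water, or wet soil in the
  shoreline band: retreating mudflat);
* CM  — commodities (enclosed water basins: aquaculture ponds; wet soil
  near mapped agriculture);
* ST  — settlement (dry soil near settlement footprints or roads);
* NPC — non-productive conversion (dieback within a human-influence
  radius of any infrastructure);
* EWE — extreme weather events (dieback isolated from infrastructure).

Rule order is fixed and first-match-wins, which removes ambiguity when
buffers overlap. "Presence" of infrastructure is distance-thresholded
rather than same-pixel because dieback patches sit near, not on,
infrastructure. All distances and the connectivity notion live in
:class:`RuleConfig`, never in code. Attribution is per-pixel and
independent of visit order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Grid
from .landcover import LANDCOVER_CODES, LandCoverMap
from .synthetic import DRIVER_CODES, EPOCH_CODES, AncillaryLayers

UNATTRIBUTED_CODE = 255


@dataclass(frozen=True)
class RuleConfig:
    connectivity: int = 8          # pixel connectivity for ocean linkage
    d_settlement: float = 500.0    # m; dry soil near settlement/roads -> ST
    d_agriculture: float = 500.0   # m; wet soil near agriculture -> CM
    d_infrastructure: float = 1000.0  # m; dieback human-influence radius -> NPC
    shoreline_band: float = 300.0  # m; wet soil near the ocean -> ER

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for name in ("d_settlement", "d_agriculture", "d_infrastructure",
                     "shoreline_band"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DriverMap:
    drivers: np.ndarray            # uint8 DRIVER_CODES; 255 = unattributed
    epoch_cuts: dict[str, np.ndarray] | None = None


def ocean_connected(water_mask: np.ndarray, ocean_mask: np.ndarray,
                    connectivity: int = 8) -> np.ndarray:
    """True where a water pixel's connected component touches the ocean."""
    water = np.asarray(water_mask, bool)
    ocean = np.asarray(ocean_mask, bool)
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, _ = ndimage.label(water | ocean, structure=structure)
    ocean_ids = np.unique(labels[ocean])
    ocean_ids = ocean_ids[ocean_ids > 0]
    return water & np.isin(labels, ocean_ids)


def proximity(mask: np.ndarray, distance_m: float, pixel_size: float) -> np.ndarray:
    """True within a centre-to-centre Euclidean distance of any true pixel."""
    if distance_m < 0:
        raise ValueError("distance must be >= 0")
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros_like(mask)
    dist = ndimage.distance_transform_edt(~mask, sampling=pixel_size)
    return dist <= distance_m


def attribute_drivers(landcover: LandCoverMap, loss_mask: np.ndarray,
                      ancillary: AncillaryLayers, grid: Grid,
                      rules: RuleConfig = RuleConfig()) -> DriverMap:
    """Assign one driver to every classified loss pixel.

    Unclassified land-cover pixels become ``unattributed`` (code 255)
    and are excluded from area accounting downstream.
    """
    ps = grid.pixel_size
    loss = np.asarray(loss_mask, bool)
    lc = landcover.classes
    infra = ancillary.roads | ancillary.settlement_mask | ancillary.agriculture_mask

    water_loss = loss & (lc == LANDCOVER_CODES["water"])
    to_ocean = ocean_connected(water_loss, ancillary.ocean_mask,
                               rules.connectivity)
    near_settlement = proximity(ancillary.settlement_mask | ancillary.roads,
                                rules.d_settlement, ps)
    near_agriculture = proximity(ancillary.agriculture_mask,
                                 rules.d_agriculture, ps)
    near_infra = proximity(infra, rules.d_infrastructure, ps)
    near_shore = proximity(ancillary.ocean_mask, rules.shoreline_band, ps)

    drivers = np.zeros(loss.shape, np.uint8)
    # water: ocean-connected erosion vs enclosed aquaculture
    drivers[water_loss & to_ocean] = DRIVER_CODES["ER"]
    drivers[water_loss & ~to_ocean] = DRIVER_CODES["CM"]
    # wet soil: agriculture > shoreline mudflat > human dieback > natural dieback
    wet = loss & (lc == LANDCOVER_CODES["wet_soil"])
    drivers[wet] = np.select(
        [near_agriculture[wet], near_shore[wet], near_infra[wet]],
        [DRIVER_CODES["CM"], DRIVER_CODES["ER"], DRIVER_CODES["NPC"]],
        DRIVER_CODES["EWE"])
    # dry soil: settlement > human dieback > natural dieback
    dry = loss & (lc == LANDCOVER_CODES["dry_soil"])
    drivers[dry] = np.select(
        [near_settlement[dry], near_infra[dry]],
        [DRIVER_CODES["ST"], DRIVER_CODES["NPC"]],
        DRIVER_CODES["EWE"])
    drivers[loss & (lc == LANDCOVER_CODES["unclassified"])] = UNATTRIBUTED_CODE
    return DriverMap(drivers)


def cut_by_epoch(driver_map: DriverMap, epoch_label: np.ndarray) -> DriverMap:
    """Restrict the full driver map to each epoch's loss extent.

    Driver maps are never regenerated per epoch; an epoch cut is simply
    the full map masked to pixels dated to that epoch.
    """
    if epoch_label.shape != driver_map.drivers.shape:
        raise ValueError("epoch raster does not match the driver map grid")
    cuts = {}
    for name, code in EPOCH_CODES.items():
        if name == "none":
            continue
        cut = np.zeros_like(driver_map.drivers)
        sel = epoch_label == code
        cut[sel] = driver_map.drivers[sel]
        cuts[name] = cut
    return DriverMap(driver_map.drivers.copy(), cuts)
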