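"""Spectral indices and the seven-variable predictor stack.

Band layout follows the six reflective Landsat TM/ETM+ bands in the
order (blue, green, red, nir, swir1, swir2). Index definitions are the
standard literature forms; ``ratio54`` and ``ratio35`` are read in
Landsat-5/7 band numbering (band5 = SWIR1, band4 = NIR, band3 = Red).
The bare "surface reflectance" predictor is the NIR band value, chosen
for its vegetation/water contrast.

Division by zero produces NaN at the affected pixel, never an exception;
downstream training and prediction drop pixels with any NaN feature.
"""

from __future__ import annotations

import numpy as np

BAND_NAMES = ("blue", "green", "red", "nir", "swir1", "swir2")
BAND_INDEX = {name: i for i, name in enumerate(BAND_NAMES)}

PREDICTOR_NAMES = (
    "ndvi", "ndmi", "mndwi", "gcvi", "surface_reflectance", "ratio54", "ratio35"
)


def _band(bands: np.ndarray, name: str) -> np.ndarray:
    return np.asarray(bands, dtype=float)[..., BAND_INDEX[name], :, :] \
        if bands.ndim > 3 else np.asarray(bands, dtype=float)[BAND_INDEX[name]]


def _normalized_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return out


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den != 0, num / den, np.nan)
    return out


def compute_index(bands: np.ndarray, index_name: str) -> np.ndarray:
    """Compute one of the seven predictor variables from a six-band raster.

    Parameters
    ----------
    bands
        Array of shape (6, rows, cols) or a bare length-6 vector, in the
        order (blue, green, red, nir, swir1, swir2). NaN marks nodata and
        propagates.
    index_name
        One of ``ndvi, ndmi, mndwi, gcvi, surface_reflectance, ratio54,
        ratio35`` (case-insensitive).
    """
    b = np.asarray(bands, dtype=float)
    if b.shape[0] != len(BAND_NAMES):
        raise ValueError(f"expected {len(BAND_NAMES)} bands, got {b.shape[0]}")
    name = index_name.lower()
    blue, green, red, nir, swir1, swir2 = (b[i] for i in range(6))
    if name == "ndvi":
        return _normalized_difference(nir, red)
    if name == "ndmi":
        return _normalized_difference(nir, swir1)
    if name == "mndwi":
        return _normalized_difference(green, swir1)
    if name == "gcvi":
        return _ratio(nir, green) - 1.0
    if name == "surface_reflectance":
        return nir.copy()
    if name == "ratio54":
        return _ratio(swir1, nir)
    if name == "ratio35":
        return _ratio(red, swir1)
    raise ValueError(f"unknown index {index_name!r}; choose from {PREDICTOR_NAMES}")


def ndvi_series(series: np.ndarray) -> np.ndarray:
    """NDVI for a (dates, 6, rows, cols) reflectance series."""
    s = np.asarray(series, dtype=float)
    nir = s[:, BAND_INDEX["nir"]]
    red = s[:, BAND_INDEX["red"]]
    return _normalized_difference(nir, red)


def predictor_stack(composite: np.ndarray) -> np.ndarray:
    """All seven predictors of a six-band composite, shape (7, rows, cols).

    NaN in any input band propagates jointly: a pixel with one NaN
    feature has all features set to NaN, so it is excluded as a unit.
    """
    feats = np.stack([compute_index(composite, n) for n in PREDICTOR_NAMES])
    bad = np.isnan(feats).any(axis=0)
    feats[:, bad] = np.nan
    return feats
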