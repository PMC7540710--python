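"""Three-class land cover classification of loss pixels.

Loss pixels are classified into wet soil, dry soil, or water from a
late-period (default 2014-2018) median composite using a random forest
over seven spectral predictors. Training data come from labelled points
expanded to circular one-hectare buffers (the stated "radius one
hectare" is read as a circle of *area* one hectare, radius ~56.42 m,
the only dimensionally sensible interpretation); every pixel whose
centre falls in a buffer becomes a sample with the point's label, and
pixels claimed by conflicting labels are dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .detection import LossMask, _window_slice
from .grid import M2_PER_HA, Grid
from .indices import predictor_stack

LANDCOVER_CLASSES = ("wet_soil", "dry_soil", "water")
LANDCOVER_CODES = {"unclassified": 0, "wet_soil": 1, "dry_soil": 2, "water": 3}
LANDCOVER_FROM_CODE = {v: k for k, v in LANDCOVER_CODES.items()}

DEFAULT_COMPOSITE_WINDOW = ("2014-01-01", "2019-01-01")  # 2014..2018
DEFAULT_N_TREES = 200
BUFFER_AREA_HA = 1.0


@dataclass
class TrainingSet:
    rows: np.ndarray       # pixel row per sample
    cols: np.ndarray       # pixel col per sample
    labels: np.ndarray     # str labels from LANDCOVER_CLASSES
    features: np.ndarray   # (n_samples, 7)


@dataclass
class LandCoverMap:
    classes: np.ndarray    # uint8 LANDCOVER_CODES, defined on loss pixels only
    composite_window: tuple


def build_composite(series: np.ndarray, dates: np.ndarray,
                    window=DEFAULT_COMPOSITE_WINDOW) -> np.ndarray:
    """Per-band median of valid observations in the window; NaN where none."""
    sel = _window_slice(dates, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN stacks
        return np.nanmedian(np.asarray(series, float)[sel], axis=0)


def buffer_radius_m(area_ha: float = BUFFER_AREA_HA) -> float:
    return math.sqrt(area_ha * M2_PER_HA / math.pi)


def rasterize_training(points: list[tuple[float, float, str]], grid: Grid,
                       composite: np.ndarray,
                       buffer_area_ha: float = BUFFER_AREA_HA) -> TrainingSet:
    """Expand labelled points to per-pixel training samples.

    Parameters
    ----------
    points
        (x, y, label) tuples in map coordinates (metres; pixel centre of
        row r, col c at x = c * pixel_size, y = r * pixel_size).
    grid, composite
        Scene grid and the six-band composite the features come from.

    Pixel membership is centre-in-disc. Duplicate samples with one label
    are de-duplicated; pixels claimed by more than one label are
    dropped. Samples with any NaN feature are dropped.
    """
    radius = buffer_radius_m(buffer_area_ha)
    ps = grid.pixel_size
    feats = predictor_stack(composite)
    claimed: dict[tuple[int, int], str | None] = {}  # None = conflict
    for x, y, label in points:
        if label not in LANDCOVER_CLASSES:
            raise ValueError(f"unknown training label {label!r}")
        r_pt, c_pt = y / ps, x / ps
        if not (-0.5 <= r_pt < grid.rows - 0.5 and -0.5 <= c_pt < grid.cols - 0.5):
            raise ValueError(f"training point ({x}, {y}) outside the grid")
        r_lo = max(0, math.ceil(r_pt - radius / ps))
        r_hi = min(grid.rows - 1, math.floor(r_pt + radius / ps))
        for r in range(r_lo, r_hi + 1):
            for c in range(max(0, math.ceil(c_pt - radius / ps)),
                           min(grid.cols - 1, math.floor(c_pt + radius / ps)) + 1):
                if (r - r_pt) ** 2 + (c - c_pt) ** 2 <= (radius / ps) ** 2:
                    prev = claimed.get((r, c), label)
                    claimed[(r, c)] = label if prev == label else None
    kept = [(r, c, lab) for (r, c), lab in sorted(claimed.items())
            if lab is not None and not np.isnan(feats[:, r, c]).any()]
    if not kept:
        raise ValueError("no usable training samples")
    rows = np.array([k[0] for k in kept])
    cols = np.array([k[1] for k in kept])
    labels = np.array([k[2] for k in kept])
    return TrainingSet(rows, cols, labels, feats[:, rows, cols].T.copy())


def train_landcover_model(samples: TrainingSet,
                          n_trees: int = DEFAULT_N_TREES,
                          seed: int = 0) -> RandomForestClassifier:
    """Fit the random forest; deterministic given the seed.

    Out-of-bag accuracy is exposed as ``model.oob_score_``.
    """
    classes = np.unique(samples.labels)
    if classes.size < 2:
        raise ValueError(
            f"training set contains a single class {classes[0]!r}; "
            "at least two classes are required")
    if not np.isfinite(samples.features).all():
        raise ValueError("training features must be finite")
    model = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1)
    model.fit(samples.features, samples.labels)
    return model


def classify_loss_pixels(model: RandomForestClassifier, feats: np.ndarray,
                         loss_mask: LossMask,
                         composite_window=DEFAULT_COMPOSITE_WINDOW) -> LandCoverMap:
    """Predict the land cover class at every loss pixel.

    Pixels with null features stay ``unclassified``; nothing is
    predicted outside the loss mask.
    """
    classes = np.zeros(loss_mask.loss.shape, np.uint8)
    rows, cols = np.nonzero(loss_mask.loss)
    x = feats[:, rows, cols].T
    ok = ~np.isnan(x).any(axis=1)
    if ok.any():
        pred = model.predict(x[ok])
        codes = np.array([LANDCOVER_CODES[p] for p in pred], np.uint8)
        classes[rows[ok], cols[ok]] = codes
    return LandCoverMap(classes, tuple(composite_window))
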