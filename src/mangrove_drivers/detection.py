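"""Mangrove loss detection from cumulative NDVI anomalies.

The decision variable is the mean change in NDVI relative to a
reference-period median: per pixel, NDVI differences from the reference
median are summed over the observation window (the cumulative anomaly)
and normalized by the number of non-null observations. A pixel inside
the baseline mangrove extent whose mean change falls at or below a
negative threshold (default -0.2, inclusive) is flagged as permanent
loss. NDVI is always recomputed from the band data so that QA masking
is applied exactly once.

Epoch dating repeats the analysis on temporal subsets (2000-2005,
2005-2010, 2010-2016), restricted to the full-window loss extent: a
loss pixel is dated to the earliest epoch whose own mean change crosses
the threshold; pixels crossing in no epoch fall back to the epoch with
the most negative mean change, which guarantees the epoch masks
partition the total loss mask.

The minimum-quality rule (default 10 valid observations) applies to the
reference window only; observation windows require at least one valid
observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .indices import ndvi_series
from .synthetic import EPOCH_CODES, EPOCH_WINDOWS

DEFAULT_THRESHOLD = -0.2
DEFAULT_MIN_QUALITY = 10
DEFAULT_REF_WINDOW = ("1998-01-01", "2002-01-01")   # Jan 1998 .. Dec 2001
DEFAULT_OBS_WINDOW = ("2001-01-01", "2017-01-01")   # Jan 2001 .. Dec 2016


@dataclass
class ReferenceRaster:
    median_ndvi: np.ndarray   # float, NaN where below min_quality
    quality_count: np.ndarray # int, valid observations in the window
    min_quality: int


@dataclass
class AnomalyStack:
    cumulative: np.ndarray    # sum of (NDVI_t - median) over the window
    obs_count: np.ndarray     # non-null observations in the window
    mean_change: np.ndarray   # cumulative / obs_count, NaN where undefined


@dataclass
class LossMask:
    loss: np.ndarray          # bool
    epoch_label: np.ndarray   # uint8, EPOCH_CODES; 0 until assign_epochs
    threshold: float


def _window_slice(dates: np.ndarray, window) -> np.ndarray:
    start, end = (np.datetime64(w) for w in window)
    if end <= start:
        raise ValueError(f"empty window {window}")
    sel = (dates >= start) & (dates < end)
    if not sel.any():
        raise ValueError(f"window {window} contains no acquisition dates")
    return sel


def build_reference(series: np.ndarray, dates: np.ndarray,
                    ref_window=DEFAULT_REF_WINDOW,
                    min_quality: int = DEFAULT_MIN_QUALITY) -> ReferenceRaster:
    """Per-pixel median NDVI over the reference window.

    Pixels with fewer than ``min_quality`` valid observations are set to
    NaN and excluded from all downstream analysis.
    """
    sel = _window_slice(dates, ref_window)
    ndvi = ndvi_series(series[sel])
    count = np.sum(~np.isnan(ndvi), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN stacks
        median = np.nanmedian(ndvi, axis=0)
    median[count < min_quality] = np.nan
    return ReferenceRaster(median, count, min_quality)


def cumulative_anomaly(series: np.ndarray, dates: np.ndarray,
                       reference: ReferenceRaster,
                       obs_window=DEFAULT_OBS_WINDOW) -> AnomalyStack:
    """Cumulative NDVI anomaly and mean change over an observation window."""
    sel = _window_slice(dates, obs_window)
    ndvi = ndvi_series(series[sel])
    diff = ndvi - reference.median_ndvi[None, :, :]
    obs_count = np.sum(~np.isnan(diff), axis=0)
    cumulative = np.nansum(diff, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_change = np.where(obs_count > 0, cumulative / obs_count, np.nan)
    undefined = np.isnan(reference.median_ndvi) | (obs_count == 0)
    cumulative = np.where(undefined, np.nan, cumulative)
    mean_change = np.where(undefined, np.nan, mean_change)
    return AnomalyStack(cumulative, obs_count, mean_change)


def detect_loss(anomaly: AnomalyStack, mangrove_mask: np.ndarray,
                threshold: float = DEFAULT_THRESHOLD) -> LossMask:
    """Threshold mean NDVI change inside the baseline mangrove extent.

    The comparison is inclusive (mean change <= threshold).
    """
    if threshold >= 0:
        raise ValueError("loss threshold must be negative")
    with np.errstate(invalid="ignore"):
        crossed = anomaly.mean_change <= threshold
    loss = crossed & np.asarray(mangrove_mask, bool) \
        & ~np.isnan(anomaly.mean_change)
    return LossMask(loss, np.zeros(loss.shape, np.uint8), threshold)


def assign_epochs(series: np.ndarray, dates: np.ndarray,
                  reference: ReferenceRaster, total_loss: LossMask,
                  epochs: dict | None = None) -> LossMask:
    """Date each total-loss pixel to one of the three epochs.

    Mean change is recomputed on each epoch's own observation window;
    a pixel gets the earliest epoch that crosses the threshold, falling
    back to the most negative epoch mean when none crosses.
    """
    if epochs is None:
        epochs = EPOCH_WINDOWS
    names = list(epochs)
    starts = sorted(np.datetime64(epochs[n][0]) for n in names)
    ends = sorted(np.datetime64(epochs[n][1]) for n in names)
    for prev_end, nxt_start in zip(ends[:-1], starts[1:]):
        if prev_end != nxt_start:
            raise ValueError("epoch windows must tile the full window")

    mean_by_epoch = np.stack([
        cumulative_anomaly(series, dates, reference, epochs[n]).mean_change
        for n in names
    ])
    crossed = np.zeros_like(mean_by_epoch, dtype=bool)
    with np.errstate(invalid="ignore"):
        np.less_equal(mean_by_epoch, total_loss.threshold, out=crossed,
                      where=~np.isnan(mean_by_epoch))

    epoch_label = np.zeros(total_loss.loss.shape, np.uint8)
    any_crossed = crossed.any(axis=0)
    first = crossed.argmax(axis=0)
    most_negative = np.nanargmin(
        np.where(np.isnan(mean_by_epoch), np.inf, mean_by_epoch), axis=0)
    chosen = np.where(any_crossed, first, most_negative)
    codes = np.array([EPOCH_CODES[n] for n in names], np.uint8)
    epoch_label[total_loss.loss] = codes[chosen[total_loss.loss]]
    return LossMask(total_loss.loss.copy(), epoch_label, total_loss.threshold)
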