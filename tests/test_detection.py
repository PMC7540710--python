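"""Loss detection: reference median, anomaly arithmetic, thresholding, epochs."""

import numpy as np
import pytest

from mangrove_drivers.detection import (AnomalyStack, assign_epochs,
                                        build_reference, cumulative_anomaly,
                                        detect_loss)
from mangrove_drivers.synthetic import EPOCH_CODES


def series_from_ndvi(ndvi_values, valid=None):
    """Single-pixel six-band series realizing a given NDVI sequence.

    Red is fixed at 0.1; NIR is solved from NDVI = (nir-red)/(nir+red).
    """
    ndvi_values = np.asarray(ndvi_values, float)
    red = 0.1
    nir = red * (1 + ndvi_values) / (1 - ndvi_values)
    series = np.zeros((len(ndvi_values), 6, 1, 1))
    series[:, 2, 0, 0] = red
    series[:, 3, 0, 0] = nir
    if valid is not None:
        series[~np.asarray(valid), :, 0, 0] = np.nan
    return series


def month_axis(n, start="1998-01"):
    months = np.arange(np.datetime64(start, "M"),
                       np.datetime64(start, "M") + n)
    return months.astype("datetime64[D]") + 14


class TestReference:
    def test_median_matches_sort_oracle(self, rng):
        vals = rng.uniform(0.3, 0.9, size=48)
        series = series_from_ndvi(vals)
        dates = month_axis(48)
        ref = build_reference(series, dates, ("1998-01-01", "2002-01-01"))
        sorted_vals = np.sort(vals)  # sort-based median oracle
        oracle = 0.5 * (sorted_vals[23] + sorted_vals[24])
        assert ref.median_ndvi[0, 0] == pytest.approx(oracle, abs=1e-9)
        assert ref.quality_count[0, 0] == 48

    def test_below_min_quality_is_null(self):
        valid = np.zeros(48, bool)
        valid[:9] = True  # 9 valid obs < 10
        series = series_from_ndvi(np.full(48, 0.7), valid)
        ref = build_reference(series, month_axis(48), min_quality=10)
        assert np.isnan(ref.median_ndvi[0, 0])
        assert ref.quality_count[0, 0] == 9

    def test_all_masked_is_null(self):
        series = series_from_ndvi(np.full(48, 0.7), np.zeros(48, bool))
        ref = build_reference(series, month_axis(48))
        assert np.isnan(ref.median_ndvi[0, 0])

    def test_empty_window_raises(self):
        series = series_from_ndvi(np.full(12, 0.7))
        with pytest.raises(ValueError):
            build_reference(series, month_axis(12), ("2002-01-01", "2002-01-01"))


class TestAnomaly:
    def test_identity_gives_zero_change(self):
        series = series_from_ndvi(np.full(60, 0.8))
        dates = month_axis(60)
        ref = build_reference(series, dates, ("1998-01-01", "2002-01-01"))
        anom = cumulative_anomaly(series, dates, ref, ("1998-01-01", "2003-01-01"))
        assert anom.cumulative[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert anom.mean_change[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_step_change_arithmetic(self):
        """Reference 0.8; 8 obs at 0.8 then 8 at 0.3 -> mean change -0.25."""
        ndvi = np.concatenate([np.full(48, 0.8), np.full(8, 0.8), np.full(8, 0.3)])
        series = series_from_ndvi(ndvi)
        dates = month_axis(64)
        ref = build_reference(series, dates, ("1998-01-01", "2002-01-01"))
        anom = cumulative_anomaly(series, dates, ref, ("2002-01-01", "2003-05-01"))
        assert anom.obs_count[0, 0] == 16
        assert anom.mean_change[0, 0] == pytest.approx(-0.25, abs=1e-9)
        # exact identity: mean_change * obs_count == cumulative
        assert anom.mean_change[0, 0] * 16 == pytest.approx(
            anom.cumulative[0, 0], abs=1e-12)

    def test_nulls_skipped_from_sum_and_count(self):
        valid = np.ones(64, bool)
        valid[48:52] = False  # 4 nulls inside the observation window
        series = series_from_ndvi(np.full(64, 0.8), valid)
        dates = month_axis(64)
        ref = build_reference(series, dates, ("1998-01-01", "2002-01-01"))
        anom = cumulative_anomaly(series, dates, ref, ("2002-01-01", "2003-05-01"))
        assert anom.obs_count[0, 0] == 12

    def test_disjoint_window_raises(self):
        series = series_from_ndvi(np.full(12, 0.8))
        dates = month_axis(12)
        ref = build_reference(series, dates, ("1998-01-01", "1999-01-01"),
                              min_quality=10)
        with pytest.raises(ValueError):
            cumulative_anomaly(series, dates, ref, ("2020-01-01", "2021-01-01"))


class TestDetect:
    @staticmethod
    def anomaly_of(mean_change):
        mc = np.array([[mean_change]])
        return AnomalyStack(mc.copy(), np.array([[10]]), mc)

    def test_threshold_inclusive_boundary(self):
        mask = np.array([[True]])
        assert detect_loss(self.anomaly_of(-0.25), mask).loss[0, 0]
        assert detect_loss(self.anomaly_of(-0.2), mask).loss[0, 0]  # inclusive
        assert not detect_loss(self.anomaly_of(-0.19), mask).loss[0, 0]

    def test_outside_mangrove_mask_is_not_loss(self):
        assert not detect_loss(self.anomaly_of(-0.25),
                               np.array([[False]])).loss[0, 0]

    def test_null_change_is_not_loss(self):
        assert not detect_loss(self.anomaly_of(np.nan),
                               np.array([[True]])).loss[0, 0]

    def test_nonnegative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_loss(self.anomaly_of(-0.25), np.array([[True]]), 0.1)

    def test_monotone_in_threshold(self, noise_free_scene):
        from mangrove_drivers.detection import build_reference as br
        b = noise_free_scene
        ref = br(b.reflectance, b.dates)
        anom = cumulative_anomaly(b.reflectance, b.dates, ref)
        loose = detect_loss(anom, b.mangrove_mask, -0.1).loss
        strict = detect_loss(anom, b.mangrove_mask, -0.3).loss
        default = detect_loss(anom, b.mangrove_mask, -0.2).loss
        assert (default >= strict).all()
        assert (loose >= default).all()


class TestEpochs:
    def run_scene(self, bundle):
        ref = build_reference(bundle.reflectance, bundle.dates)
        anom = cumulative_anomaly(bundle.reflectance, bundle.dates, ref)
        total = detect_loss(anom, bundle.mangrove_mask)
        return assign_epochs(bundle.reflectance, bundle.dates, ref, total)

    def test_epoch_masks_partition_total_loss(self, small_scene):
        loss = self.run_scene(small_scene)
        np.testing.assert_array_equal(loss.epoch_label > 0, loss.loss)

    def test_conversion_dates_map_to_expected_epochs(self, noise_free_scene):
        """Events converting mid-2003 / 2007 / 2010 date to their epochs."""
        loss = self.run_scene(noise_free_scene)
        truth = noise_free_scene.truth
        sel = truth.driver_label > 0
        np.testing.assert_array_equal(loss.epoch_label[sel],
                                      truth.loss_epoch[sel])

    def test_non_loss_pixels_get_none(self, small_scene):
        loss = self.run_scene(small_scene)
        assert (loss.epoch_label[~loss.loss] == 0).all()

    def test_non_tiling_epochs_rejected(self, small_scene):
        b = small_scene
        ref = build_reference(b.reflectance, b.dates)
        anom = cumulative_anomaly(b.reflectance, b.dates, ref)
        total = detect_loss(anom, b.mangrove_mask)
        gappy = {
            "loss2005": (np.datetime64("2000-01-01"), np.datetime64("2004-01-01")),
            "loss2010": (np.datetime64("2005-01-01"), np.datetime64("2010-01-01")),
            "loss2016": (np.datetime64("2010-01-01"), np.datetime64("2017-01-01")),
        }
        with pytest.raises(ValueError, match="tile"):
            assign_epochs(b.reflectance, b.dates, ref, total, gappy)

    def test_noise_free_detection_recovers_truth_exactly(self, noise_free_scene):
        loss = self.run_scene(noise_free_scene)
        np.testing.assert_array_equal(
            loss.loss, noise_free_scene.truth.driver_label > 0)
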