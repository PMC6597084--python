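"""Tests for duty-cycle aggregation, filtering, encoding and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boxid.preprocess import (
    FEATURES,
    aggregate_to_duty_cycle,
    encode_battery,
    filter_geo,
    normalize_features,
    preprocess,
    remove_outliers_3sd,
)
from boxid.synthetic import RawSensorLog, gen_shed_like


def _raw(gps=None, accel=None, battery=None, wifi=None):
    return RawSensorLog(
        gps=pd.DataFrame(
            gps or {"participant": [0], "timestamp": [50.0], "lat": [52.1], "lon": [-106.6]}
        ),
        accel=pd.DataFrame(
            accel
            or {
                "participant": [0, 0],
                "timestamp": [10.0, 20.0],
                "x": [3.0, 0.0],
                "y": [0.0, 4.0],
                "z": [0.0, 0.0],
            }
        ),
        battery=pd.DataFrame(
            battery or {"participant": [0], "timestamp": [30.0], "status": ["Charging AC"]}
        ),
        wifi=pd.DataFrame(
            wifi
            or {
                "participant": [0, 0, 0],
                "timestamp": [40.0, 41.0, 42.0],
                "mac": ["A", "A", "B"],
            }
        ),
        duty_period_s=300,
    )


class TestAggregation:
    def test_accel_norms_reduce_to_mean_and_population_sd(self):
        agg = aggregate_to_duty_cycle(_raw())
        row = agg.iloc[0]
        # samples (3,0,0) and (0,4,0): norms {3,4} -> mean 3.5, SD 0.5
        assert row["acc_mean"] == pytest.approx(3.5)
        assert row["acc_sd"] == pytest.approx(0.5)

    def test_wifi_counts_distinct_macs(self):
        agg = aggregate_to_duty_cycle(_raw())
        assert agg.iloc[0]["wifi_count"] == 2

    def test_cycle_without_gps_dropped_entirely(self):
        raw = _raw(gps={"participant": [0], "timestamp": [350.0],
                        "lat": [52.1], "lon": [-106.6]})
        # battery/accel/wifi live in cycle 0, the only GPS fix in cycle 1
        assert len(aggregate_to_duty_cycle(raw)) == 0

    def test_most_recent_value_wins_within_cycle(self):
        raw = _raw(battery={
            "participant": [0, 0],
            "timestamp": [30.0, 60.0],
            "status": ["Not Charging", "Charging USB"],
        })
        assert aggregate_to_duty_cycle(raw).iloc[0]["status"] == "Charging USB"

    def test_duplicate_timestamps_keep_last_with_warning(self, caplog):
        raw = _raw(gps={
            "participant": [0, 0],
            "timestamp": [50.0, 50.0],
            "lat": [52.10, 52.11],
            "lon": [-106.6, -106.61],
        })
        with caplog.at_level("WARNING"):
            agg = aggregate_to_duty_cycle(raw)
        assert agg.iloc[0]["lat"] == pytest.approx(52.11)
        assert "duplicate" in caplog.text

    def test_hour_derived_from_most_recent_timestamp(self):
        raw = _raw(gps={"participant": [0], "timestamp": [3700.0],
                        "lat": [52.1], "lon": [-106.6]},
                   accel={"participant": [0], "timestamp": [3650.0],
                          "x": [0.0], "y": [0.0], "z": [9.8]},
                   battery={"participant": [0], "timestamp": [3660.0],
                            "status": ["Not Charging"]},
                   wifi={"participant": [0], "timestamp": [3655.0], "mac": ["A"]})
        agg = aggregate_to_duty_cycle(raw)
        assert agg.iloc[0]["hour"] == 1


class TestGeoFilter:
    def test_point_outside_west_bound_removed(self):
        t = pd.DataFrame({"lon": [-106.9], "lat": [52.1]})
        assert len(filter_geo(t)) == 0

    def test_point_inside_bounds_kept(self):
        t = pd.DataFrame({"lon": [-106.6], "lat": [52.1]})
        assert len(filter_geo(t)) == 1

    def test_boundary_value_inclusive(self):
        t = pd.DataFrame({"lon": [-106.6], "lat": [52.058367]})
        assert len(filter_geo(t)) == 1

    def test_invalid_bounds_rejected(self):
        t = pd.DataFrame({"lon": [0.0], "lat": [0.0]})
        with pytest.raises(ValueError):
            filter_geo(t, 1.0, -1.0, 0.0, 1.0)


class TestOutlierRemoval:
    def test_gross_outlier_removed(self):
        # (in a tiny sample no point can sit 3 SDs out, since the outlier
        # itself inflates the SD: the max z-score of n values is (n-1)/sqrt(n))
        values = [1.0] * 20 + [100.0]
        keep = remove_outliers_3sd(values)
        assert keep[:20].all()
        assert not keep[20]

    def test_constant_vector_fully_kept(self):
        assert remove_outliers_3sd([5.0] * 10).all()

    def test_normal_tail_fraction(self):
        rng = np.random.default_rng(0)
        keep = remove_outliers_3sd(rng.standard_normal(100_000))
        frac_removed = 1.0 - keep.mean()
        assert frac_removed == pytest.approx(0.0027, abs=0.001)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers_3sd([1.0])


class TestBatteryEncoding:
    @pytest.mark.parametrize(
        "status,code",
        [
            ("Not Charging", 0.0),
            ("Charging AC", 0.25),
            ("Charging USB", 0.5),
            ("Charging Wireless", 1.0),
        ],
    )
    def test_printed_codes(self, status, code):
        assert encode_battery(status) == code

    def test_case_insensitive(self):
        assert encode_battery("not charging") == 0.0
        assert encode_battery("CHARGING AC") == 0.25

    def test_unknown_status_named_in_error(self):
        with pytest.raises(ValueError, match="Discharging"):
            encode_battery("Discharging")


def _cycle_table(**overrides):
    base = {
        "hour": [0, 12, 23],
        "lat": [52.06, 52.10, 52.21],
        "lon": [-106.76, -106.66, -106.53],
        "acc_mean": [9.8, 10.0, 10.4],
        "acc_sd": [0.1, 0.2, 0.4],
        "status": ["Not Charging", "Charging AC", "Charging Wireless"],
        "wifi_count": [1, 5, 9],
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestNormalization:
    def test_wifi_minmax(self):
        ds = normalize_features(_cycle_table())
        assert list(ds.records["wifi01"]) == [0.0, 0.5, 1.0]

    def test_hour_23_maps_to_one(self):
        ds = normalize_features(_cycle_table())
        assert ds.records["hour01"].iloc[-1] == 1.0
        assert ds.records["hour01"].iloc[0] == 0.0

    def test_zero_wifi_rows_removed_before_scaling(self):
        ds = normalize_features(_cycle_table(wifi_count=[0, 5, 9]))
        assert ds.n == 2
        assert list(ds.records["wifi01"]) == [0.0, 1.0]

    def test_exact_duplicates_dropped(self):
        t = pd.concat([_cycle_table(), _cycle_table()], ignore_index=True)
        ds = normalize_features(t)
        assert ds.n == 3

    def test_degenerate_feature_set_to_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ds = normalize_features(_cycle_table(lat=[52.1, 52.1, 52.1]))
        assert (ds.records["lat01"] == 0.0).all()
        assert "degenerate" in caplog.text

    def test_records_satisfy_unit_interval_invariant(self, shed_small_ds):
        rec = shed_small_ds.records
        assert list(rec.columns) == FEATURES
        assert (rec.to_numpy() >= 0).all() and (rec.to_numpy() <= 1).all()
        assert not rec.duplicated().any()

    def test_cleaning_stages_are_a_fixed_point_on_final_records(self, shed_small_ds):
        rec = shed_small_ds.records
        again = rec.drop_duplicates(keep="first")
        pd.testing.assert_frame_equal(rec, again)
        # min-max scaled features already span [0, 1]; rescaling changes nothing
        for col in ("lat01", "lon01", "acc01", "sd01", "wifi01"):
            lo, hi = rec[col].min(), rec[col].max()
            np.testing.assert_allclose((rec[col] - lo) / (hi - lo), rec[col])


class TestFullPipeline:
    def test_provenance_counts_monotone_non_increasing(self, shed_small_ds):
        p = shed_small_ds.provenance
        order = [
            "aggregated",
            "after_geo_filter",
            "after_outlier_removal",
            "after_wifi_nonzero",
            "after_dedup",
        ]
        counts = [p[k] for k in order]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert shed_small_ds.n == p["after_dedup"]

    @settings(deadline=None, derandomize=True, max_examples=5)
    @given(st.integers(0, 10_000))
    def test_random_study_yields_valid_records(self, seed):
        raw = gen_shed_like(1, 1, seed=seed)
        ds = preprocess(raw)
        arr = ds.to_points()
        assert arr.shape[1] == 7
        if len(arr):
            assert (arr >= 0).all() and (arr <= 1).all()
            assert len(np.unique(arr, axis=0)) == len(arr)
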