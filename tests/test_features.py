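"""Per-minute activity/jerk/entropy, average-day profiles and window means."""
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from actiday.errors import DataError, InputError
from actiday.features import (
    FEATURE_COLUMNS,
    average_day,
    five_point_slope,
    minute_activity,
    minute_entropy,
    minute_features,
    minute_jerk,
    segment_mean,
)
from actiday.preprocess import CalibrationModel
from actiday.weartime import DayRecord, classify_wear, qualify_days

from conftest import make_magnitude

DT = 0.02  # 50 Hz


# ---------------------------------------------------------------------------
# activity


def test_activity_of_zero_signal_is_zero():
    assert minute_activity(np.zeros(3000)) == 0.0


def test_activity_rectifies_square_wave():
    m = 100.0 * np.where(np.arange(3000) % 2 == 0, 1.0, -1.0)
    assert minute_activity(m) == pytest.approx(100.0)


def test_activity_of_gaussian_minute_matches_folded_normal():
    rng = np.random.default_rng(0)
    m = rng.normal(0.0, 80.0, 3000)
    expected = 80.0 * np.sqrt(2.0 / np.pi)
    assert abs(minute_activity(m) - expected) / expected < 0.05


# ---------------------------------------------------------------------------
# jerk


def test_jerk_of_constant_signal_is_zero():
    assert minute_jerk(np.full(3000, 42.0), DT) == 0.0


def test_jerk_recovers_linear_ramp_slope_exactly():
    s = 37.5  # mg/s
    t = np.arange(3000) * DT
    assert minute_jerk(s * t, DT) == pytest.approx(s, abs=1e-9)
    assert minute_jerk(-s * t, DT) == pytest.approx(s, abs=1e-9)


def test_jerk_of_sinusoid_matches_brute_force_estimator():
    # oracle: evaluate the 5-point regression slope directly on the analytic signal
    f, A = 1.0, 100.0
    t = np.arange(3000) * DT
    m = A * np.sin(2 * np.pi * f * t)
    slopes = []
    for i in range(2, 2998):
        window = m[i - 2 : i + 3]
        k = np.array([-2, -1, 0, 1, 2])
        slopes.append(np.sum(k * window) / (10 * DT))
    oracle = float(np.mean(np.abs(slopes)))
    assert minute_jerk(m, DT) == pytest.approx(oracle, rel=1e-12)
    # sanity: close to the rectified-sine mean (2/pi) * 2*pi*f*A times the
    # small-window regression gain at 1 Hz (slightly below 1)
    assert 0.9 * (2 / np.pi) * 2 * np.pi * f * A < oracle < (2 / np.pi) * 2 * np.pi * f * A


def test_five_point_slope_edges_are_nan():
    d = five_point_slope(np.arange(10.0), 1.0)
    assert np.isnan(d[:2]).all() and np.isnan(d[-2:]).all()
    np.testing.assert_allclose(d[2:-2], 1.0)


# ---------------------------------------------------------------------------
# entropy


def test_entropy_of_constant_minute_is_zero_bits():
    assert minute_entropy(np.full(3000, 12.3)) == 0.0


def test_entropy_of_uniform_64_bins_is_six_bits():
    # exactly equal occupancy of all 64 bins
    centers = -500.0 + 15.625 * (np.arange(64) + 0.5)
    m = np.repeat(centers, 50)
    assert minute_entropy(m) == pytest.approx(6.0, abs=1e-12)


def test_entropy_matches_independent_histogram_oracle():
    rng = np.random.default_rng(3)
    m = rng.normal(0.0, 50.0, 3000)
    # independent oracle: Counter over bin indices, plain Shannon formula
    idx = np.floor((m + 500.0) / 15.625).astype(int)
    idx = np.minimum(np.maximum(idx, 0), 63)
    counts = Counter(idx.tolist())
    p = np.array([c / 3000 for c in counts.values()])
    oracle = float(-(p * np.log2(p)).sum())
    assert minute_entropy(m) == pytest.approx(oracle, abs=1e-12)


def test_entropy_clamps_outliers_into_edge_bins():
    m = np.array([-1e6, 1e6] * 100, dtype=float)
    assert minute_entropy(m) == pytest.approx(1.0)  # two bins, 50/50


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-2000, 2000, allow_nan=False), min_size=1, max_size=400),
)
def test_entropy_bounds_invariant(vals):
    e = minute_entropy(np.array(vals))
    assert 0.0 <= e <= 6.0


# ---------------------------------------------------------------------------
# vectorised extraction consistent with the single-minute estimators


def test_minute_features_match_reference_estimators():
    rng = np.random.default_rng(9)
    sd = np.repeat(rng.uniform(5, 120, 10), 3000)  # 10 minutes, varying intensity
    m = rng.normal(0.0, 1.0, len(sd)) * sd
    mag = make_magnitude(m)
    feats = minute_features(mag, mask=None)
    assert len(feats) == 10
    for i in range(10):
        mi = m[i * 3000 : (i + 1) * 3000]
        assert feats["activity_mg"][i] == pytest.approx(minute_activity(mi), rel=1e-12)
        assert feats["entropy_bits"][i] == pytest.approx(minute_entropy(mi), rel=1e-12)
    # jerk: the batch path sees neighbours across minute boundaries, so
    # compare against the reference slope computed on the full series
    d = np.abs(five_point_slope(m, DT))
    for i in range(10):
        di = d[i * 3000 : (i + 1) * 3000]
        oracle = np.nanmean(di)
        assert feats["jerk_mg_s"][i] == pytest.approx(oracle, rel=1e-9)


def test_scale_equivariance_of_activity_and_jerk():
    rng = np.random.default_rng(4)
    m = rng.normal(0, 30, 3000)
    assert minute_activity(2.5 * m) == pytest.approx(2.5 * minute_activity(m), rel=1e-12)
    assert minute_jerk(2.5 * m, DT) == pytest.approx(2.5 * minute_jerk(m, DT), rel=1e-12)


def test_minutes_with_too_few_samples_are_missing():
    m = np.full(3000, 50.0)
    m[1000:3000] = np.nan  # 1000 valid samples < 1500
    feats = minute_features(make_magnitude(m), mask=None)
    assert np.isnan(feats["activity_mg"][0])
    assert feats["n_samples"][0] == 1000


# ---------------------------------------------------------------------------
# average day and window means


def day_frame(date, values):
    return pd.DataFrame(
        {
            "date": [date] * 1440,
            "minute_of_day": np.arange(1440),
            "activity_mg": values,
            "jerk_mg_s": values,
            "entropy_bits": np.zeros(1440),
            "worn": True,
            "n_samples": 3000,
        }
    )


def included_day(date):
    return DayRecord(date, 1440, 1440, True, "none")


def test_single_day_profile_equals_that_day():
    d = pd.Timestamp("2024-03-05").date()
    vals = np.random.default_rng(0).uniform(0, 60, 1440)
    prof = average_day(day_frame(d, vals), [included_day(d)])
    np.testing.assert_allclose(prof["activity_mg"].to_numpy(), vals)
    assert (prof["n_days"] == 1).all()


def test_two_day_profile_is_minute_wise_mean():
    d1, d2 = pd.Timestamp("2024-03-05").date(), pd.Timestamp("2024-03-06").date()
    v, w = np.full(1440, 10.0), np.full(1440, 30.0)
    minutes = pd.concat([day_frame(d1, v), day_frame(d2, w)], ignore_index=True)
    prof = average_day(minutes, [included_day(d1), included_day(d2)])
    np.testing.assert_allclose(prof["activity_mg"].to_numpy(), 20.0)


def test_excluded_day_does_not_contribute():
    d1, d2 = pd.Timestamp("2024-03-05").date(), pd.Timestamp("2024-03-06").date()
    minutes = pd.concat(
        [day_frame(d1, np.full(1440, 10.0)), day_frame(d2, np.full(1440, 99.0))],
        ignore_index=True,
    )
    days = [included_day(d1), DayRecord(d2, 100, 1440, False, "short_wear")]
    prof = average_day(minutes, days)
    np.testing.assert_allclose(prof["activity_mg"].to_numpy(), 10.0)


def test_weighted_mean_conservation():
    # profile mean weighted by n_days equals the mean over all worn minutes
    rng = np.random.default_rng(7)
    d1, d2 = pd.Timestamp("2024-03-05").date(), pd.Timestamp("2024-03-06").date()
    f1, f2 = day_frame(d1, rng.uniform(0, 50, 1440)), day_frame(d2, rng.uniform(0, 50, 1440))
    f2.loc[rng.choice(1440, 300, replace=False), "activity_mg"] = np.nan  # non-wear holes
    minutes = pd.concat([f1, f2], ignore_index=True)
    prof = average_day(minutes, [included_day(d1), included_day(d2)])
    weighted = (prof["activity_mg"] * prof["n_days"]).sum() / prof["n_days"].sum()
    oracle = minutes["activity_mg"].dropna().mean()
    assert weighted == pytest.approx(oracle, rel=1e-12)


def test_no_included_days_is_an_error():
    d = pd.Timestamp("2024-03-05").date()
    with pytest.raises(DataError):
        average_day(day_frame(d, np.zeros(1440)), [DayRecord(d, 0, 1440, False, "short_wear")])


def test_window_means_match_index_arithmetic():
    d = pd.Timestamp("2024-03-05").date()
    vals = np.zeros(1440)
    vals[360:720] = 1.0  # morning-only activity
    prof = average_day(day_frame(d, vals), [included_day(d)])
    assert segment_mean(prof, "morning")["activity_mg"] == pytest.approx(1.0)
    assert segment_mean(prof, "night")["activity_mg"] == pytest.approx(0.0)
    assert segment_mean(prof, "daytime")["activity_mg"] == pytest.approx(1.0 / 3.0)
    assert segment_mean(prof, "day")["activity_mg"] == pytest.approx(0.25)
    # arbitrary profile against a brute-force index-range oracle
    rng = np.random.default_rng(1)
    vals = rng.uniform(0, 80, 1440)
    prof = average_day(day_frame(d, vals), [included_day(d)])
    assert segment_mean(prof, "night")["activity_mg"] == pytest.approx(vals[0:360].mean())
    assert segment_mean(prof, "daytime")["activity_mg"] == pytest.approx(vals[360:1440].mean())


def test_unknown_window_rejected():
    d = pd.Timestamp("2024-03-05").date()
    prof = average_day(day_frame(d, np.zeros(1440)), [included_day(d)])
    with pytest.raises(InputError):
        segment_mean(prof, "brunch")


def test_constant_profile_has_equal_window_means():
    d = pd.Timestamp("2024-03-05").date()
    prof = average_day(day_frame(d, np.full(1440, 5.5)), [included_day(d)])
    for w in ("day", "night", "daytime", "morning"):
        assert segment_mean(prof, w)["activity_mg"] == pytest.approx(5.5)


def test_wear_mask_gates_minute_features():
    # 2 segments: first worn (SD 20), second non-wear (SD 2)
    rng = np.random.default_rng(5)
    m = np.concatenate(
        [rng.normal(0, 20.0, 90000) * 1.0, rng.normal(0, 2.0, 90000)]
    )
    mag = make_magnitude(m)
    mask = classify_wear(mag)
    feats = minute_features(mag, mask)
    assert feats["worn"][:30].all()
    assert not feats["worn"][30:].any()
    assert feats["activity_mg"][30:].isna().all()
    assert feats["activity_mg"][:30].notna().all()
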