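"""Per-minute signal characteristics and average-day profiles.

Three characteristics summarise each worn minute of the band-passed
magnitude signal:

* **activity** — mean absolute magnitude (mg). The band-passed signal is
  signed with zero mean, so it is rectified before averaging; for Gaussian
  motion of SD sigma the expected activity is the folded-normal mean
  sigma * sqrt(2/pi).
* **jerk** — mean absolute first derivative (mg/s), the derivative being
  the least-squares slope of a sliding 5-sample window. High jerk means
  sudden, "quick" movements.
* **entropy** — Shannon entropy (bits) of the minute's magnitude histogram
  over 64 fixed bins spanning [-500, 500) mg. Low entropy means stationary
  or repetitive movement; the maximum is log2(64) = 6 bits.

Average-day profiles average each minute-of-day across included days,
excluding non-wear, giving a 1440-minute circadian profile per participant.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, InputError
from .preprocess import MagnitudeSeries
from .weartime import MINUTES_PER_DAY, DayRecord, WearMask

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

ENTROPY_BINS = 64
ENTROPY_RANGE_MG = (-500.0, 500.0)
MIN_SAMPLES_PER_MINUTE = 1500  # half a minute at 50 Hz

#: analysis windows in minutes of day: [start, stop)
WINDOWS: dict[str, tuple[int, int]] = {
    "day": (0, 1440),
    "night": (0, 360),  # 00:00-06:00
    "daytime": (360, 1440),  # 06:00-24:00
    "morning": (360, 720),  # 06:00-12:00
}


# ---------------------------------------------------------------------------
# single-minute reference estimators (operate on one minute's sample array)


def minute_activity(values: np.ndarray) -> float:
    """Mean absolute band-passed magnitude of one minute, mg."""
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan")
    return float(np.mean(np.abs(v)))


def five_point_slope(values: np.ndarray, dt: float) -> np.ndarray:
    """Least-squares slope of a centred 5-sample window at each sample.

    For samples m[t-2..t+2] at spacing dt the regression slope is
    sum(k * m[t+k]) / (10 * dt), k = -2..2. The first/last two samples have
    no full window and are NaN.
    """
    kernel = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    d = np.full(len(values), np.nan)
    if len(values) >= 5:
        d[2:-2] = np.convolve(values, kernel[::-1], mode="valid") / (10.0 * dt)
    return d


def minute_jerk(values: np.ndarray, dt: float) -> float:
    """Mean absolute 5-point-regression derivative of one minute, mg/s."""
    d = five_point_slope(values, dt)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return float("nan")
    return float(np.mean(np.abs(d)))


def minute_entropy(
    values: np.ndarray,
    n_bins: int = ENTROPY_BINS,
    range_mg: tuple[float, float] = ENTROPY_RANGE_MG,
) -> float:
    """Shannon entropy (bits) of one minute's magnitude histogram.

    Fixed global bins keep the scale comparable across minutes and
    participants; samples outside the range are clamped into the edge bins.
    """
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan")
    lo, hi = range_mg
    width = (hi - lo) / n_bins
    idx = np.clip(np.floor((v - lo) / width).astype(np.int64), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    p = counts[counts > 0] / v.size
    return float(max(0.0, -np.sum(p * np.log2(p))))


# ---------------------------------------------------------------------------
# vectorised per-recording feature extraction


def _minute_stats_py(m, off, rate, first_min, n_min, lo, width, n_bins):
    rel = np.floor((off + np.arange(len(m)) / rate) / 60.0).astype(np.int64) - first_min
    valid = np.isfinite(m)
    counts = np.bincount(rel[valid], minlength=n_min)
    sums_abs = np.bincount(rel[valid], weights=np.abs(m[valid]), minlength=n_min)
    bin_idx = np.clip(np.floor((m[valid] - lo) / width).astype(np.int64), 0, n_bins - 1)
    hist = np.bincount(rel[valid] * n_bins + bin_idx, minlength=n_min * n_bins).reshape(
        n_min, n_bins
    )
    deriv = five_point_slope(m, 1.0 / rate)
    dvalid = np.isfinite(deriv)
    dcounts = np.bincount(rel[dvalid], minlength=n_min)
    dsums = np.bincount(rel[dvalid], weights=np.abs(deriv[dvalid]), minlength=n_min)
    return counts, sums_abs, hist, dcounts, dsums


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _minute_stats_nb(m, off, rate, first_min, n_min, lo, width, n_bins):  # pragma: no cover
        counts = np.zeros(n_min, dtype=np.int64)
        sums_abs = np.zeros(n_min)
        hist = np.zeros((n_min, n_bins), dtype=np.int64)
        dcounts = np.zeros(n_min, dtype=np.int64)
        dsums = np.zeros(n_min)
        n = m.shape[0]
        inv10dt = rate / 10.0
        for i in range(n):
            v = m[i]
            mi = np.int64((off + i / rate) // 60.0) - first_min
            if np.isfinite(v):
                counts[mi] += 1
                sums_abs[mi] += abs(v)
                b = np.int64((v - lo) // width)
                if b < 0:
                    b = 0
                elif b >= n_bins:
                    b = n_bins - 1
                hist[mi, b] += 1
            if 2 <= i < n - 2:
                m0, m1, m3, m4 = m[i - 2], m[i - 1], m[i + 1], m[i + 2]
                if (
                    np.isfinite(m0)
                    and np.isfinite(m1)
                    and np.isfinite(v)
                    and np.isfinite(m3)
                    and np.isfinite(m4)
                ):
                    d = (2.0 * (m4 - m0) + (m3 - m1)) * inv10dt
                    dcounts[mi] += 1
                    dsums[mi] += abs(d)
        return counts, sums_abs, hist, dcounts, dsums

    _minute_stats = _minute_stats_nb
else:  # pragma: no cover
    _minute_stats = _minute_stats_py


def minute_features(
    mag: MagnitudeSeries,
    mask: WearMask | None = None,
    min_samples: int = MIN_SAMPLES_PER_MINUTE,
    n_bins: int = ENTROPY_BINS,
    range_mg: tuple[float, float] = ENTROPY_RANGE_MG,
) -> pd.DataFrame:
    """Per-minute activity/jerk/entropy for a whole magnitude series.

    Minutes are aligned to local midnight (consistent with the wear grid:
    each 30 min wear segment covers exactly 30 feature minutes). Minutes
    that are unworn, or have fewer than ``min_samples`` valid samples, get
    NaN features. Columns: date, minute_of_day, activity_mg, jerk_mg_s,
    entropy_bits, worn, n_samples.
    """
    if mag.n_samples == 0:
        raise DataError("empty magnitude series")
    midnight = mag.t0.normalize()
    off = (mag.t0 - midnight).total_seconds()
    first = int(off // 60.0)
    last = int((off + (mag.n_samples - 1) / mag.rate_hz) // 60.0)
    n_min = last - first + 1

    lo, hi = range_mg
    width = (hi - lo) / n_bins
    counts, sums_abs, hist, dcounts, dsums = _minute_stats(
        mag.m, off, mag.rate_hz, first, n_min, lo, width, n_bins
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        activity = sums_abs / counts
        jerk = dsums / dcounts
        p = hist / np.maximum(counts, 1)[:, None]
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    entropy = np.maximum(-plogp.sum(axis=1), 0.0)

    minutes = np.arange(first, last + 1)
    if mask is not None:
        seg_first = int(mask.start_min[0]) // mask.segment_min
        seg_of_min = minutes // mask.segment_min - seg_first
        inside = (seg_of_min >= 0) & (seg_of_min < mask.n_segments)
        worn = np.zeros(n_min, dtype=bool)
        worn[inside] = mask.worn[seg_of_min[inside]]
    else:
        worn = np.ones(n_min, dtype=bool)

    ok = worn & (counts >= min_samples) & (dcounts > 0)
    activity = np.where(ok, activity, np.nan)
    jerk = np.where(ok, jerk, np.nan)
    entropy = np.where(ok & (counts > 0), entropy, np.nan)

    day_idx = minutes // MINUTES_PER_DAY
    base = pd.Timestamp(mag.t0.normalize())
    dates = (base + pd.to_timedelta(day_idx, unit="D")).date
    return pd.DataFrame(
        {
            "date": dates,
            "minute_of_day": minutes % MINUTES_PER_DAY,
            "activity_mg": activity,
            "jerk_mg_s": jerk,
            "entropy_bits": entropy,
            "worn": worn,
            "n_samples": counts,
        }
    )


FEATURE_COLUMNS = ["activity_mg", "jerk_mg_s", "entropy_bits"]


def average_day(minutes: pd.DataFrame, days: list[DayRecord]) -> pd.DataFrame:
    """Average each minute-of-day across included days.

    Non-wear and missing minutes are excluded from the per-minute means;
    ``n_days`` counts the days contributing to each minute (NaN features
    where no day contributes). Returns a 1440-row frame indexed by
    minute_of_day.
    """
    included = {d.date for d in days if d.included}
    if not included:
        raise DataError("participant has no included days")
    sub = minutes[minutes["date"].isin(included)]
    valid = sub.dropna(subset=["activity_mg"])
    grouped = valid.groupby("minute_of_day")[FEATURE_COLUMNS].mean()
    n_days = valid.groupby("minute_of_day")["activity_mg"].count()
    profile = pd.DataFrame(
        index=pd.RangeIndex(MINUTES_PER_DAY, name="minute_of_day"),
        columns=FEATURE_COLUMNS,
        dtype=float,
    )
    profile.loc[grouped.index] = grouped
    profile["n_days"] = 0
    profile.loc[n_days.index, "n_days"] = n_days
    profile["n_days"] = profile["n_days"].astype(int)
    return profile


def segment_mean(profile: pd.DataFrame, window: str) -> pd.Series:
    """Unweighted mean of an average-day profile over an analysis window.

    ``window`` is one of 'day' (whole average day, the quantity used for
    group tests), 'night' (00:00-06:00), 'daytime' (06:00-24:00) or
    'morning' (06:00-12:00). NaN when the window is fully missing.
    """
    if window not in WINDOWS:
        raise InputError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")
    lo, hi = WINDOWS[window]
    return profile.iloc[lo:hi][FEATURE_COLUMNS].mean()
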