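"""Wear-time classification and day-inclusion rules.

Each midnight-aligned 30 min segment is classified as wear when the SD of
the acceleration magnitude exceeds 13 mg (strict inequality). A calendar
day qualifies for analysis when the device was worn more than half the day
(> 720 min), the calibration succeeded and malfunction is ruled out;
partial first/last days usually fall to the half-day rule.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import CalibrationModel, MagnitudeSeries, SD_THRESHOLD_MG

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

SEGMENT_MIN = 30
MINUTES_PER_DAY = 1440
HALF_DAY_MIN = 720


@dataclass
class WearMask:
    """Wear classification on a grid of consecutive 30 min segments.

    ``start_min`` holds each segment's start in minutes since the midnight
    of ``day0`` (multiples of the segment length). ``sd_mg`` is NaN for
    segments without samples; ``flagged`` marks segments with fewer than
    half their samples present (classified from what is available).
    """

    day0: datetime.date
    start_min: np.ndarray
    worn: np.ndarray
    sd_mg: np.ndarray
    coverage: np.ndarray
    flagged: np.ndarray
    segment_min: int = SEGMENT_MIN

    @property
    def n_segments(self) -> int:
        return len(self.start_min)

    def dates(self) -> np.ndarray:
        """Calendar date of each segment."""
        days = self.start_min // MINUTES_PER_DAY
        base = pd.Timestamp(self.day0)
        return np.array([(base + pd.Timedelta(days=int(d))).date() for d in days])

    def to_frame(self, participant_id: str | None = None) -> pd.DataFrame:
        """Per-segment mask table (start minute, SD, wear flag, coverage)."""
        df = pd.DataFrame(
            {
                "start_min": self.start_min,
                "worn": self.worn,
                "sd_mg": self.sd_mg,
                "coverage": self.coverage,
                "flagged": self.flagged,
            }
        )
        if participant_id is not None:
            df.insert(0, "participant_id", participant_id)
        return df

    def worn_at_minute(self, abs_min: np.ndarray) -> np.ndarray:
        """Wear flag for absolute minutes (since day0 midnight)."""
        seg = abs_min // self.segment_min * self.segment_min
        lut = dict(zip(self.start_min.tolist(), self.worn.tolist()))
        return np.array([lut.get(int(s), False) for s in seg])


@dataclass
class DayRecord:
    """Inclusion bookkeeping for one calendar day of one participant."""

    date: datetime.date
    minutes_worn: int
    minutes_covered: int
    included: bool
    exclusion_reason: str = "none"  # none|short_wear|calibration_failure|malfunction|partial_day


def _segment_stats_py(m, off, rate, seg_len_s, first, n_seg):
    valid = np.isfinite(m)
    sec = off + np.arange(len(m)) / rate
    rel = np.floor(sec / seg_len_s).astype(np.int64) - first
    counts = np.bincount(rel[valid], minlength=n_seg).astype(float)
    sums = np.bincount(rel[valid], weights=m[valid], minlength=n_seg)
    sumsqs = np.bincount(rel[valid], weights=m[valid] ** 2, minlength=n_seg)
    return counts, sums, sumsqs


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _segment_stats_nb(m, off, rate, seg_len_s, first, n_seg):  # pragma: no cover
        counts = np.zeros(n_seg)
        sums = np.zeros(n_seg)
        sumsqs = np.zeros(n_seg)
        for i in range(m.shape[0]):
            v = m[i]
            if np.isfinite(v):
                s = np.int64((off + i / rate) // seg_len_s) - first
                counts[s] += 1.0
                sums[s] += v
                sumsqs[s] += v * v
        return counts, sums, sumsqs

    _segment_stats = _segment_stats_nb
else:  # pragma: no cover
    _segment_stats = _segment_stats_py


def classify_wear(
    mag: MagnitudeSeries,
    threshold_mg: float = SD_THRESHOLD_MG,
    segment_min: int = SEGMENT_MIN,
) -> WearMask:
    """Classify each 30 min segment by its magnitude SD (worn iff SD > 13 mg).

    Segments are aligned to local midnight. The SD is computed over the
    samples actually present in the segment; segments with under half their
    samples are still classified but flagged.
    """
    if not np.isfinite(mag.m).any():
        raise DataError("magnitude series contains no valid samples")
    midnight = mag.t0.normalize()
    off = (mag.t0 - midnight).total_seconds()
    seg_len_s = segment_min * 60.0
    first = int(off // seg_len_s)
    last = int((off + (mag.n_samples - 1) / mag.rate_hz) // seg_len_s)
    n_seg = int(last - first + 1)

    counts, sums, sumsqs = _segment_stats(mag.m, off, mag.rate_hz, seg_len_s, first, n_seg)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = np.maximum(sumsqs / counts - mean**2, 0.0)
        sd = np.sqrt(var)
    sd[counts == 0] = np.nan

    expected = seg_len_s * mag.rate_hz
    coverage = counts / expected
    worn = np.zeros(n_seg, dtype=bool)
    has = counts > 0
    worn[has] = sd[has] > threshold_mg
    flagged = coverage < 0.5

    return WearMask(
        day0=mag.t0.normalize().date(),
        start_min=(np.arange(first, last + 1) * segment_min).astype(np.int64),
        worn=worn,
        sd_mg=sd,
        coverage=coverage,
        flagged=flagged,
        segment_min=segment_min,
    )


def qualify_days(
    mask: WearMask,
    calib: CalibrationModel | None = None,
    malfunction: bool = False,
) -> list[DayRecord]:
    """Apply the day-inclusion rules to a wear mask.

    A day is included iff worn more than half the day (> 720 min), the
    calibration succeeded, and no malfunction was reported. Days the
    recording only partially covers (typically the first and last) that
    fail the half-day rule are recorded with reason ``partial_day``.
    """
    calib_ok = calib.success if calib is not None else True
    dates = mask.dates()
    records: list[DayRecord] = []
    for date in sorted(set(dates.tolist())):
        sel = dates == date
        minutes_worn = int(mask.worn[sel].sum()) * mask.segment_min
        covered = float(mask.coverage[sel].sum()) * mask.segment_min
        n_seg_day = int(sel.sum())
        partial = n_seg_day < MINUTES_PER_DAY // mask.segment_min or covered < 0.99 * MINUTES_PER_DAY
        included = minutes_worn > HALF_DAY_MIN and calib_ok and not malfunction
        if malfunction:
            reason = "malfunction"
        elif not calib_ok:
            reason = "calibration_failure"
        elif included:
            reason = "none"
        elif partial:
            reason = "partial_day"
        else:
            reason = "short_wear"
        records.append(
            DayRecord(
                date=date,
                minutes_worn=minutes_worn,
                minutes_covered=int(round(covered)),
                included=included,
                exclusion_reason=reason if not included else "none",
            )
        )
    return records


def compliance(days: list[DayRecord]) -> float | None:
    """Fraction of included-day time the device was actually worn.

    Total worn minutes on included days divided by total minutes on those
    days; ``None`` (missing) when no day was included.
    """
    included = [d for d in days if d.included]
    if not included:
        return None
    return sum(d.minutes_worn for d in included) / (MINUTES_PER_DAY * len(included))


def day_ledger(days: list[DayRecord], participant_id: str) -> pd.DataFrame:
    """Per-day ledger table (participant, date, minutes worn, inclusion)."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "date": [d.date.isoformat() for d in days],
            "minutes_worn": [d.minutes_worn for d in days],
            "minutes_covered": [d.minutes_covered for d in days],
            "included": [d.included for d in days],
            "exclusion_reason": [d.exclusion_reason for d in days],
        }
    )
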