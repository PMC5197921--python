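"""Raw-recording pre-processing.

Turns raw tri-axial wrist recordings into a calibrated, uniformly sampled,
gravity-removed acceleration-magnitude signal:

(i)   autocalibration — per-axis gain/offset estimated from still windows so
      that stationary magnitude sits on the 1 g sphere;
(ii)  interpolation to a uniform 50 Hz grid (piecewise cubic);
(iii) Euclidean acceleration magnitude;
(iv)  0.2–15 Hz Butterworth band-pass (zero phase) removing the gravity DC
      component and high-frequency sensor noise.

Plus merging of two-device changeover recordings onto a single clock.

Units: raw samples are in g (1 g = 9.81 m/s^2); magnitudes and thresholds
in mg (1/1000 g). The band-passed magnitude is signed (zero mean).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from ._interp import lagrange_cubic
from .errors import CalibrationError, InputError, MergeConflictError, MergeGapError

#: working sampling rate of the pipeline after interpolation, Hz
TARGET_RATE_HZ = 50.0
#: wear / stillness threshold on acceleration SD, mg
SD_THRESHOLD_MG = 13.0


@dataclass
class RawRecording:
    """Timestamped tri-axial acceleration for one participant/device.

    ``t`` holds sample times in seconds since ``start_time`` (strictly
    increasing, possibly irregular); ``a`` is the (n, 3) array of x/y/z
    samples in g. Rows of ``a`` may be NaN only to mark missing spans in a
    merged or resampled recording.
    """

    participant_id: str
    device_id: str
    start_time: pd.Timestamp
    t: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.a.ndim != 2 or self.a.shape[1] != 3:
            raise InputError("acceleration array must have shape (n, 3)")
        if self.t.shape[0] != self.a.shape[0]:
            raise InputError("t and a must have the same length")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples else 0.0

    @property
    def median_dt(self) -> float:
        # strided subsample: robust to isolated gaps, O(n/16) to compute
        return float(np.median(np.diff(self.t)[::16]))

    def validate(self, allow_missing: bool = False) -> None:
        """Check invariants: t strictly increasing, finite samples, duration > 0."""
        if self.n_samples < 2 or self.duration_s <= 0:
            raise InputError("recording must span a positive duration")
        if not np.all(np.diff(self.t) > 0):
            raise InputError("sample times must be strictly increasing")
        if not allow_missing and not np.all(np.isfinite(self.a)):
            raise InputError("acceleration samples must be finite")

    def segments(self, max_gap_s: float | None = None) -> list[slice]:
        """Contiguous sample runs, split at gaps larger than ``max_gap_s``.

        Default gap threshold is max(0.5 s, 5 median sample intervals).
        """
        dt = np.diff(self.t)
        if max_gap_s is None:
            max_gap_s = max(0.5, 5.0 * float(np.median(dt[::16])))
        breaks = np.nonzero(dt > max_gap_s)[0]
        edges = np.concatenate(([0], breaks + 1, [self.n_samples]))
        return [slice(int(edges[i]), int(edges[i + 1])) for i in range(len(edges) - 1)]


@dataclass
class CalibrationModel:
    """Per-axis gain/offset estimated by sphere-projection autocalibration.

    The sensor convention is ``measured = gain * true + offset``; applying
    the model computes ``true = (measured - offset) / gain``. Errors are the
    mean absolute deviation of still-window magnitude from 1 g, in mg.
    """

    gain: np.ndarray = field(default_factory=lambda: np.ones(3))
    offset_mg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pre_error_mg: float = float("nan")
    post_error_mg: float = float("nan")
    n_still: int = 0
    success: bool = False
    n_iter: int = 0
    message: str = ""


@dataclass
class MagnitudeSeries:
    """Uniformly sampled, band-passed acceleration magnitude in mg.

    ``m`` is signed (the band-pass removes DC) and NaN where samples are
    missing or inside trimmed filter edge transients. ``t0`` is the wall
    clock of sample 0; sample k occurs at ``t0 + k / rate_hz``.
    """

    participant_id: str
    t0: pd.Timestamp
    m: np.ndarray
    rate_hz: float = TARGET_RATE_HZ

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.float64)
        self.t0 = pd.Timestamp(self.t0)

    @property
    def n_samples(self) -> int:
        return self.m.shape[0]

    def seconds_of_day(self) -> np.ndarray:
        """Seconds since local midnight of each sample's day-0 midnight."""
        midnight = self.t0.normalize()
        off = (self.t0 - midnight).total_seconds()
        return off + np.arange(self.n_samples) / self.rate_hz


def _window_stats(rec: RawRecording, window_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean and SD vectors over non-overlapping windows."""
    w = int(round(window_s / rec.median_dt))
    if w < 2 or rec.n_samples < w:
        return np.empty((0, 3)), np.empty((0, 3))
    k = rec.n_samples // w
    blocks = rec.a[: k * w].reshape(k, w, 3)
    s1 = blocks.sum(axis=1)
    s2 = np.einsum("kwa,kwa->ka", blocks, blocks)
    means = s1 / w
    sds = np.sqrt(np.maximum(s2 / w - means**2, 0.0))
    ok = np.all(np.isfinite(means), axis=1)  # NaN samples propagate into the block mean
    return means[ok], sds[ok]


def find_still_windows(
    rec: RawRecording,
    window_s: float = 10.0,
    sd_threshold_mg: float = SD_THRESHOLD_MG,
) -> np.ndarray:
    """Mean acceleration vectors (in g) of still 10 s windows.

    A non-overlapping window is *still* when each axis's SD is below the
    threshold; still windows sample the local gravity vector and anchor the
    autocalibration fit. Returns an (n_still, 3) array (possibly empty).
    """
    if rec.duration_s < window_s:
        raise InputError(f"recording shorter than one {window_s:g} s window")
    means, sds = _window_stats(rec, window_s)
    still = np.all(sds < sd_threshold_mg / 1000.0, axis=1)
    return means[still]


def autocalibrate(
    rec: RawRecording,
    window_s: float = 10.0,
    sd_threshold_mg: float = SD_THRESHOLD_MG,
    spread_mg: float = 300.0,
    max_error_mg: float = 10.0,
    tol: float = 1e-9,
    max_iter: int = 1000,
    min_duration_s: float = 86400.0,
) -> CalibrationModel:
    """Estimate per-axis gain and offset from still-window gravity vectors.

    Iterative least squares: each still-window mean, corrected by the
    current parameters, is projected onto the unit sphere; per axis the
    projections are regressed on the corrected values and the parameters
    updated, until the relative parameter change falls below ``tol``.

    The fit is only attempted when each axis's still means reach both
    below ``-spread_mg`` and above ``+spread_mg`` (otherwise the sphere is
    sampled too narrowly for gain and offset to be identifiable and the
    model is returned unsuccessful with identity parameters). Success
    additionally requires a post-fit error under ``max_error_mg``.
    """
    if rec.duration_s < min_duration_s:
        raise InputError("autocalibration requires a recording spanning at least one day")
    still = find_still_windows(rec, window_s, sd_threshold_mg)
    model = CalibrationModel(n_still=len(still))
    if len(still) < 9:
        model.message = f"only {len(still)} still windows"
        return model
    model.pre_error_mg = float(np.mean(np.abs(np.linalg.norm(still, axis=1) - 1.0))) * 1000.0

    spread_g = spread_mg / 1000.0
    lo, hi = still.min(axis=0), still.max(axis=0)
    if np.any(lo > -spread_g) or np.any(hi < spread_g):
        model.message = "insufficient orientation spread for sphere fit"
        return model

    gain = np.ones(3)
    offset = np.zeros(3)  # in g
    for it in range(1, max_iter + 1):
        corrected = (still - offset) / gain
        radius = np.linalg.norm(corrected, axis=1)
        target = corrected / radius[:, None]
        new_gain = gain.copy()
        new_offset = offset.copy()
        for ax in range(3):
            # least squares target = a + b * corrected  (per axis)
            x = corrected[:, ax]
            b, a = np.polyfit(x, target[:, ax], 1)
            if b <= 0:
                model.message = "degenerate axis fit"
                model.pre_error_mg = model.pre_error_mg
                return model
            new_gain[ax] = gain[ax] / b
            new_offset[ax] = offset[ax] - a * gain[ax] / b
        dg = np.max(np.abs(new_gain - gain) / gain)
        do = np.max(np.abs(new_offset - offset))
        gain, offset = new_gain, new_offset
        if max(dg, do) < tol:
            break

    corrected = (still - offset) / gain
    post = float(np.mean(np.abs(np.linalg.norm(corrected, axis=1) - 1.0))) * 1000.0
    model.gain = gain
    model.offset_mg = offset * 1000.0
    model.post_error_mg = post
    model.n_iter = it
    model.success = post < max_error_mg and post <= model.pre_error_mg + 1e-9
    if not model.success:
        model.message = f"post-fit error {post:.2f} mg too large"
        model.gain = np.ones(3)
        model.offset_mg = np.zeros(3)
    return model


def apply_calibration(
    rec: RawRecording, model: CalibrationModel, inplace: bool = False
) -> RawRecording:
    """Invert the sensor model: corrected = (measured - offset) / gain.

    With ``inplace=True`` the recording's sample array is corrected in
    place (no copy), which matters at multi-day scale.
    """
    if not model.success:
        raise CalibrationError(
            f"calibration failed for {rec.participant_id}: {model.message or 'unsuccessful model'}"
        )
    if inplace:
        rec.a -= model.offset_mg / 1000.0
        rec.a /= model.gain
        return rec
    a = (rec.a - model.offset_mg / 1000.0) / model.gain
    return replace(rec, a=a)


def resample_to_50hz(rec: RawRecording, rate_hz: float = TARGET_RATE_HZ) -> RawRecording:
    """Interpolate each axis onto a uniform grid t0 + k/rate.

    Piecewise-cubic interpolation is applied within each contiguous run of
    samples; grid points falling into recording gaps (e.g. a device
    changeover) are set to NaN — missing spans are never zero-filled.
    """
    if rec.n_samples < 4:
        raise InputError("resampling requires at least 4 samples")
    t0 = rec.t[0]
    n_out = int(np.floor((rec.t[-1] - t0) * rate_hz)) + 1
    grid = t0 + np.arange(n_out) / rate_hz
    out = np.empty((n_out, 3))
    covered = 0  # NaN-fill only grid spans no segment covers
    for seg in rec.segments():
        ts, ys = rec.t[seg], rec.a[seg]
        if len(ts) < 4:
            continue
        i0 = int(np.searchsorted(grid, ts[0], side="left"))
        i1 = int(np.searchsorted(grid, ts[-1], side="right"))
        if i0 > covered:
            out[covered:i0] = np.nan
        if i1 > i0:
            lagrange_cubic(ts, ys, grid[i0:i1], out=out[i0:i1])
        covered = max(covered, i1)
    if covered < n_out:
        out[covered:] = np.nan
    return replace(rec, t=grid, a=out)


def _uniform_rate(rec: RawRecording, rate_hz: float) -> None:
    n = rec.n_samples
    if n < 2:
        raise InputError("series too short to filter")
    # uniform grid <=> endpoints and a probe set of interior points on-grid
    probe = np.unique(np.concatenate([np.arange(0, n, max(1, n // 4096)), [n - 1]]))
    expected = rec.t[0] + probe / rate_hz
    if np.max(np.abs(rec.t[probe] - expected)) > 1e-6:
        raise InputError(f"band-pass filtering requires a uniform {rate_hz:g} Hz grid")


def bandpass_magnitude(
    rec: RawRecording,
    low_hz: float = 0.2,
    high_hz: float = 15.0,
    order: int = 4,
    edge_trim_s: float = 5.0,
    rate_hz: float = TARGET_RATE_HZ,
) -> MagnitudeSeries:
    """Band-pass the Euclidean acceleration magnitude (gravity removal).

    The magnitude sqrt(x^2+y^2+z^2) is filtered with a zero-phase
    (forward-backward) Butterworth band-pass; the stationary 1 g gravity
    component is rejected as DC. The first/last ``edge_trim_s`` of every
    contiguous run are NaN'd as filter edge transients.
    """
    _uniform_rate(rec, rate_hz)
    x, y, z = rec.a[:, 0], rec.a[:, 1], rec.a[:, 2]
    mag = np.sqrt(x * x + y * y + z * z) * 1000.0  # mg
    out = np.full_like(mag, np.nan)
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos")
    trim = int(round(edge_trim_s * rate_hz))
    valid = np.isfinite(mag)
    edges = np.nonzero(np.diff(valid.astype(np.int8)))[0] + 1
    bounds = np.concatenate(([0], edges, [len(mag)]))
    for i in range(len(bounds) - 1):
        s, e = int(bounds[i]), int(bounds[i + 1])
        if not valid[s]:
            continue
        if e - s <= 2 * trim + 1:
            continue  # too short to yield any trusted samples
        filt = sosfiltfilt(sos, mag[s:e])
        filt[:trim] = np.nan
        filt[-trim:] = np.nan
        out[s:e] = filt
    t0 = rec.start_time + pd.Timedelta(seconds=float(rec.t[0]))
    return MagnitudeSeries(participant_id=rec.participant_id, t0=t0, m=out, rate_hz=rate_hz)


def merge_changeover(
    rec_a: RawRecording, rec_b: RawRecording, max_gap_s: float = 3600.0
) -> RawRecording:
    """Concatenate two device recordings from one participant onto one clock.

    The changeover gap is preserved as missing samples (a hole in the time
    base), never zero-filled; downstream stages treat the calendar day
    containing the changeover as a single day. Overlapping recordings are a
    conflict; gaps of ``max_gap_s`` or more are refused so the days can be
    reported separately.
    """
    if rec_a.participant_id != rec_b.participant_id:
        raise MergeConflictError(
            f"cannot merge recordings from {rec_a.participant_id!r} and {rec_b.participant_id!r}"
        )
    offset = (rec_b.start_time - rec_a.start_time).total_seconds()
    gap = offset + rec_b.t[0] - rec_a.t[-1]
    if gap <= 0:
        raise MergeConflictError("device recordings overlap in time")
    if gap >= max_gap_s:
        raise MergeGapError(f"changeover gap {gap:.0f} s exceeds {max_gap_s:.0f} s; not merged")
    return RawRecording(
        participant_id=rec_a.participant_id,
        device_id=f"{rec_a.device_id}+{rec_b.device_id}",
        start_time=rec_a.start_time,
        t=np.concatenate([rec_a.t, rec_b.t + offset]),
        a=np.vstack([rec_a.a, rec_b.a]),
    )
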