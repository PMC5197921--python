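"""Synthetic wrist-accelerometer cohort generator.

Emulates a case-control actigraphy study design: each participant wears a
tri-axial wrist device for ``n_days`` full days plus partial first/last
days, with a mid-week device changeover, per-device gain/offset
miscalibration, sampling-rate jitter, scheduled non-wear bouts, and a
circadian intensity profile (morning/afternoon/evening bumps over a
daytime plateau, quiescent/restless night mixture). The case group's
morning intensity (06:00-12:00) is attenuated by a configurable fraction.

Ground truth (per-minute intensity, wear schedule, calibration error,
covariates and outcome scores with planted partial correlations) is kept
alongside every recording so downstream stages have a recoverable target.

The *intensity* lambda of a minute is the standard deviation (mg) of the
dynamic acceleration component about gravity; the pipeline's "activity"
feature estimates the folded-normal mean lambda * sqrt(2/pi) of the
band-passed magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._interp import lagrange_cubic
from .errors import ConfigurationError
from .preprocess import RawRecording

try:
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: fixed calendar anchor for simulated recordings (a Monday)
DAY0 = pd.Timestamp("2024-03-04")
MINUTES_PER_DAY = 1440
#: morning attenuation window, minutes of day [06:00, 12:00)
MORNING_WINDOW = (360, 720)
DAYTIME_WINDOW = (360, 1440)


@dataclass(frozen=True)
class Bump:
    """Gaussian intensity bump of the circadian profile."""

    center_min: float
    width_min: float
    height_mg: float


@dataclass(frozen=True)
class OutcomeSpec:
    """Linear generative model of one clinical outcome score.

    The outcome is linear in the participant's true daytime intensity and
    confounds with Gaussian noise; the intensity coefficient is solved in
    closed form so the within-group partial correlation between daytime
    intensity and the outcome, given the confounds, equals ``rho``.
    """

    name: str
    mean_case: float
    mean_control: float
    sd: float
    rho: float
    coef_age: float = 0.0
    coef_bmi: float = 0.0
    coef_iq: float = 0.0
    coef_sex: float = 0.0


DEFAULT_OUTCOMES: tuple[OutcomeSpec, ...] = (
    OutcomeSpec("IADL", 20.0, 25.0, 3.0, 0.60, coef_age=-0.08, coef_iq=0.04, coef_sex=0.5),
    OutcomeSpec("SF36_MH", 55.0, 78.0, 10.0, 0.65, coef_age=-0.2, coef_bmi=-0.1, coef_iq=0.1),
    OutcomeSpec("MADRS", 22.0, 2.0, 4.0, -0.37, coef_age=0.05, coef_iq=-0.02),
    OutcomeSpec("PAL_errors", 30.0, 12.0, 8.0, 0.40, coef_age=0.3, coef_iq=-0.1),
)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Identical config + seed reproduces byte-identical output. Notable
    defaults: 30 Hz native sampling with multiplicative interval jitter,
    7 recording days, per-device offset ~ N(0, 20 mg) and gain ~ N(1, 0.01)
    per axis, 2 mg sensor noise, and a 0.3 fractional case-group morning
    attenuation.
    """

    n_per_group: int = 10
    n_days: int = 7
    native_rate_hz: float = 30.0
    timestamp_jitter_sd: float = 1e-4
    seed: int = 0

    # circadian intensity profile (mg)
    morning_attenuation: float = 0.3
    bumps: tuple[Bump, ...] = (
        Bump(540.0, 90.0, 55.0),  # 09:00 morning
        Bump(900.0, 120.0, 35.0),  # 15:00 afternoon
        Bump(1200.0, 90.0, 25.0),  # 20:00 evening
    )
    day_plateau_mg: float = 30.0
    day_start_min: int = 390  # 06:30 rise
    day_end_min: int = 1380  # 23:00 bed
    night_quiescent_prob: float = 0.65
    night_quiescent_mg: float = 2.0
    night_restless_mg: float = 45.0
    scale_sd: float = 0.10  # between-participant activity scale SD

    # non-wear schedule (30-min-epoch aligned bouts)
    nonwear_daily_prob: float = 0.3
    nonwear_epochs_min: int = 1
    nonwear_epochs_max: int = 4
    nonwear_start_epoch: int = 16  # 08:00
    nonwear_end_epoch: int = 44  # 22:00

    # sensor model
    offset_sd_mg: float = 20.0
    gain_sd: float = 0.01
    sensor_noise_sd_mg: float = 2.0

    # dynamic signal model
    swing_freq_hz: float = 2.0
    swing_variance_frac: float = 0.3
    bout_threshold_mg: float = 60.0
    noise_bandwidth_hz: float = 8.0
    posture_mean_min: float = 20.0
    drift_deg_s: float = 0.5
    drift_active_threshold_mg: float = 10.0

    # recording span and device changeover
    start_clock_min: int = 1260  # device delivered 21:00 on day 0
    end_clock_min: int = 420  # collected 07:00 after the last full day
    split_devices: bool = True
    changeover_clock_min: int = 902  # 15:02, on a minute boundary
    changeover_gap_s: float = 60.0

    # covariates and outcomes
    age_mean: float = 74.0
    age_sd: float = 6.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    iq_mean: float = 112.0
    iq_sd: float = 8.0
    sex_p: float = 0.5
    outcomes: tuple[OutcomeSpec, ...] = DEFAULT_OUTCOMES

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ConfigurationError("n_per_group must be positive")
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        if self.native_rate_hz <= 0:
            raise ConfigurationError("native_rate_hz must be positive")
        if not 0.0 <= self.morning_attenuation <= 1.0:
            raise ConfigurationError("morning_attenuation must lie in [0, 1]")
        for p in (self.nonwear_daily_prob, self.night_quiescent_prob, self.sex_p):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.swing_variance_frac < 1.0:
            raise ConfigurationError("swing_variance_frac must lie in [0, 1)")
        if self.nonwear_epochs_min > self.nonwear_epochs_max or self.nonwear_epochs_min <= 0:
            raise ConfigurationError("invalid non-wear bout epoch range")

    @property
    def span_start_min(self) -> int:
        return self.start_clock_min

    @property
    def span_end_min(self) -> int:
        return (self.n_days + 1) * MINUTES_PER_DAY + self.end_clock_min


@dataclass
class ParticipantTruth:
    """Ground truth for one simulated participant.

    ``lambda_min`` is the expected intensity per minute-of-day (1440
    values, mg); ``lambda_realized`` / ``worn_minutes`` are the realized
    per-minute intensity and wear flags over the whole recorded span,
    starting at absolute minute ``span_start_min`` from day-0 midnight.
    """

    participant_id: str
    index: int
    group: str  # "LLD" | "control"
    scale: float
    lambda_min: np.ndarray
    lambda_realized: np.ndarray
    worn_minutes: np.ndarray
    span_start_min: int
    device_gain: np.ndarray
    device_offset_mg: np.ndarray
    nonwear_intervals: list[tuple[int, int]]
    covariates: dict[str, float]
    outcomes: dict[str, float]


@dataclass
class CohortBundle:
    """Simulated recordings, per-participant truths and covariate table."""

    recordings: list[RawRecording]
    truths: list[ParticipantTruth]
    covariate_table: pd.DataFrame


def expected_profile(config: SimulationConfig, group: str) -> np.ndarray:
    """Unscaled expected intensity per minute-of-day (1440 values, mg)."""
    m = np.arange(MINUTES_PER_DAY, dtype=float)
    night = (m < config.day_start_min) | (m >= config.day_end_min)
    q = config.night_quiescent_prob
    night_mean = q * config.night_quiescent_mg + (1 - q) * config.night_restless_mg
    prof = np.full(MINUTES_PER_DAY, night_mean)
    day = config.day_plateau_mg + sum(
        b.height_mg * np.exp(-0.5 * ((m - b.center_min) / b.width_min) ** 2) for b in config.bumps
    )
    prof[~night] = day[~night]
    if group == "LLD":
        lo, hi = MORNING_WINDOW
        prof[lo:hi] *= 1.0 - config.morning_attenuation
    return prof


def true_daytime_mean(truth: ParticipantTruth) -> float:
    """Mean of the true intensity profile over daytime (06:00-24:00), mg."""
    lo, hi = DAYTIME_WINDOW
    return float(np.mean(truth.lambda_min[lo:hi]))


def _daytime_base(config: SimulationConfig, group: str) -> float:
    lo, hi = DAYTIME_WINDOW
    return float(np.mean(expected_profile(config, group)[lo:hi]))


def _simulate_one_truth(
    config: SimulationConfig, index: int, rng: np.random.Generator
) -> ParticipantTruth:
    group = "LLD" if index < config.n_per_group else "control"
    pid = f"P{index + 1:03d}"
    scale = float(np.clip(1.0 + config.scale_sd * rng.standard_normal(), 0.05, None))
    profile = scale * expected_profile(config, group)

    start, end = config.span_start_min, config.span_end_min
    abs_min = np.arange(start, end)
    mod = abs_min % MINUTES_PER_DAY
    realized = profile[mod].copy()

    # quiescent/restless night mixture (per-minute independent draws)
    night = (mod < config.day_start_min) | (mod >= config.day_end_min)
    draws = rng.random(len(abs_min))
    quiescent = draws < config.night_quiescent_prob
    night_val = np.where(quiescent, config.night_quiescent_mg, config.night_restless_mg)
    atten = np.ones(len(abs_min))
    if group == "LLD":
        lo, hi = MORNING_WINDOW
        atten[(mod >= lo) & (mod < hi)] = 1.0 - config.morning_attenuation
    realized[night] = scale * night_val[night] * atten[night]

    # scheduled non-wear bouts, snapped to the 30-min epoch grid
    worn = np.ones(len(abs_min), dtype=bool)
    intervals: list[tuple[int, int]] = []
    for day in range(config.n_days + 2):
        take = rng.random() < config.nonwear_daily_prob
        k = int(rng.integers(config.nonwear_epochs_min, config.nonwear_epochs_max + 1))
        e_lo, e_hi = config.nonwear_start_epoch, config.nonwear_end_epoch - k
        if day == 0:
            e_lo = max(e_lo, int(np.ceil(config.start_clock_min / 30)))
        if day == config.n_days + 1:
            e_hi = min(e_hi, config.end_clock_min // 30 - k)
        if not take or e_lo > e_hi:
            continue
        e0 = int(rng.integers(e_lo, e_hi + 1))
        s = day * MINUTES_PER_DAY + 30 * e0
        e = s + 30 * k
        intervals.append((s, e))
        sel = (abs_min >= s) & (abs_min < e)
        worn[sel] = False
        realized[sel] = 0.0

    covariates = {
        "age": float(rng.normal(config.age_mean, config.age_sd)),
        "sex": float(rng.random() < config.sex_p),
        "BMI": float(rng.normal(config.bmi_mean, config.bmi_sd)),
        "NART_IQ": float(rng.normal(config.iq_mean, config.iq_sd)),
    }

    base = _daytime_base(config, group)
    sigma_x = config.scale_sd * base
    x = scale * base  # true daytime mean of this participant
    outcomes: dict[str, float] = {}
    for spec in config.outcomes:
        mu = spec.mean_case if group == "LLD" else spec.mean_control
        y = mu
        if sigma_x > 0:
            y += spec.rho * spec.sd * (x - base) / sigma_x
        y += spec.coef_age * (covariates["age"] - config.age_mean)
        y += spec.coef_bmi * (covariates["BMI"] - config.bmi_mean)
        y += spec.coef_iq * (covariates["NART_IQ"] - config.iq_mean)
        y += spec.coef_sex * (covariates["sex"] - config.sex_p)
        y += rng.normal(0.0, spec.sd * np.sqrt(max(0.0, 1.0 - spec.rho**2)))
        outcomes[spec.name] = float(y)
    outcomes["log_WMH_ratio"] = float(rng.normal(-4.0 + (0.3 if group == "LLD" else 0.0), 0.4))

    return ParticipantTruth(
        participant_id=pid,
        index=index,
        group=group,
        scale=scale,
        lambda_min=profile,
        lambda_realized=realized,
        worn_minutes=worn,
        span_start_min=start,
        device_gain=1.0 + config.gain_sd * rng.standard_normal(3),
        device_offset_mg=config.offset_sd_mg * rng.standard_normal(3),
        nonwear_intervals=intervals,
        covariates=covariates,
        outcomes=outcomes,
    )


def simulate_truths(config: SimulationConfig) -> tuple[list[ParticipantTruth], pd.DataFrame]:
    """Draw the truth layer only (profiles, schedules, covariates, outcomes).

    Orders of magnitude cheaper than signal synthesis; used for
    statistical calibration studies that only need participant-level truth.
    """
    config.validate()
    truths = [
        _simulate_one_truth(config, i, np.random.default_rng([config.seed, i, 0]))
        for i in range(2 * config.n_per_group)
    ]
    return truths, covariate_table(truths)


def covariate_table(truths: list[ParticipantTruth]) -> pd.DataFrame:
    """Participant-level covariate/outcome table."""
    rows = []
    for t in truths:
        row = {"participant_id": t.participant_id, "group": t.group}
        row.update(t.covariates)
        row.update(t.outcomes)
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")


def _posture_orientation(
    config: SimulationConfig,
    t_abs: np.ndarray,
    active_time: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gravity direction per sample: great-circle drift within posture epochs.

    Posture epochs follow a Poisson process on the *active* clock
    (exponential durations in cumulative active seconds); each epoch starts
    at a fresh uniform orientation and drifts about a random axis at a rate
    ~ |N(0, drift_deg_s)|. Both the re-orientation jumps and the drift are
    therefore frozen during non-wear and quiescent periods (which is what
    makes still windows still and keeps non-wear magnitude flat).
    """
    span = active_time[-1] - active_time[0]
    mean_s = config.posture_mean_min * 60.0
    n_ep = max(4, int(span / mean_s * 2) + 8)
    durations = rng.exponential(mean_s, n_ep)
    bounds = active_time[0] + np.cumsum(durations)
    while bounds[-1] < active_time[-1]:  # pragma: no cover - n_ep overshoots by design
        extra = rng.exponential(mean_s, 8)
        bounds = np.concatenate((bounds, bounds[-1] + np.cumsum(extra)))
    idx = np.searchsorted(active_time, bounds, side="right")
    idx = idx[idx < len(active_time)]
    edges = np.concatenate(([0], idx, [len(t_abs)]))

    n_epochs = len(edges) - 1
    drift_rad = np.deg2rad(config.drift_deg_s)
    u0s = rng.standard_normal((n_epochs, 3))
    u0s /= np.linalg.norm(u0s, axis=1, keepdims=True)
    axes = rng.standard_normal((n_epochs, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    omegas = np.abs(rng.normal(0.0, drift_rad, n_epochs))

    ghat = np.empty((len(t_abs), 3))
    _rodrigues_epochs(ghat, edges.astype(np.int64), u0s, axes, omegas, active_time)
    return ghat


def _rodrigues_epochs_py(ghat, edges, u0s, axes, omegas, active_time):
    for i in range(len(edges) - 1):
        s, e = int(edges[i]), int(edges[i + 1])
        if s == e:
            continue
        u0, axis, omega = u0s[i], axes[i], omegas[i]
        theta = omega * (active_time[s:e] - active_time[s])
        ct, st = np.cos(theta), np.sin(theta)
        cross = np.cross(axis, u0)
        dot = float(axis @ u0)
        ghat[s:e] = ct[:, None] * u0 + st[:, None] * cross + ((1 - ct) * dot)[:, None] * axis


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _rodrigues_epochs_nb(ghat, edges, u0s, axes, omegas, active_time):  # pragma: no cover
        for i in range(len(edges) - 1):
            s, e = edges[i], edges[i + 1]
            if s == e:
                continue
            kx, ky, kz = axes[i, 0], axes[i, 1], axes[i, 2]
            ux, uy, uz = u0s[i, 0], u0s[i, 1], u0s[i, 2]
            cx, cy, cz = ky * uz - kz * uy, kz * ux - kx * uz, kx * uy - ky * ux
            dot = kx * ux + ky * uy + kz * uz
            a0 = active_time[s]
            om = omegas[i]
            for j in range(s, e):
                th = om * (active_time[j] - a0)
                ct = np.cos(th)
                st = np.sin(th)
                oc = (1.0 - ct) * dot
                ghat[j, 0] = ct * ux + st * cx + oc * kx
                ghat[j, 1] = ct * uy + st * cy + oc * ky
                ghat[j, 2] = ct * uz + st * cz + oc * kz

    _rodrigues_epochs = _rodrigues_epochs_nb
else:  # pragma: no cover
    _rodrigues_epochs = _rodrigues_epochs_py


def _assemble_measured_py(
    out, noise, u, u_scale, ghat, lam, t_abs, gain, off_g, noise_sd, f, bout_thr, w, phase
):
    bout = lam >= bout_thr
    sigma_g = lam / 1000.0 * np.sqrt(1.0 - f * bout)
    swing = (lam / 1000.0 * np.sqrt(2.0 * f) * bout) * np.sin(w * t_abs + phase)
    a_true = ghat * (1.0 + swing)[:, None] + (u * u_scale) * sigma_g[:, None]
    out[:] = a_true * gain + off_g + noise * noise_sd


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _assemble_measured_nb(
        out, noise, u, u_scale, ghat, lam, t_abs, gain, off_g, noise_sd, f, bout_thr, w, phase
    ):  # pragma: no cover - jitted
        n = lam.shape[0]
        sq2f = np.sqrt(2.0 * f)
        sq1f = np.sqrt(1.0 - f)
        for i in range(n):
            lg = lam[i] / 1000.0
            if lam[i] >= bout_thr:
                sig = lg * sq1f
                sw = lg * sq2f * np.sin(w * t_abs[i] + phase)
            else:
                sig = lg
                sw = 0.0
            for a in range(3):
                out[i, a] = (
                    (ghat[i, a] * (1.0 + sw) + u[i, a] * (u_scale[a] * sig)) * gain[a]
                    + off_g[a]
                    + noise[i, a] * noise_sd
                )

    _assemble_measured = _assemble_measured_nb
else:  # pragma: no cover
    _assemble_measured = _assemble_measured_py


def simulate_recording(
    truth: ParticipantTruth,
    config: SimulationConfig,
    seed: int | None = None,
) -> list[RawRecording]:
    """Synthesize the raw tri-axial recording(s) for one participant.

    Per sample, measured = gain * a_true + offset + sensor noise, with
    a_true a slowly reorienting unit-gravity vector plus a band-limited
    dynamic component whose per-minute SD equals the true intensity (zero
    during non-wear); vigorous minutes add a 2 Hz arm-swing sinusoid inside
    the same variance budget. Returns one recording, or two split at the
    device changeover when enabled.
    """
    config.validate()
    rng = (
        np.random.default_rng(seed)
        if seed is not None
        else np.random.default_rng([config.seed, truth.index, 1])
    )
    rate = config.native_rate_hz
    start_s = truth.span_start_min * 60.0
    span_s = (config.span_end_min - truth.span_start_min) * 60.0
    n = int(span_s * rate)

    jit = rng.standard_normal(n - 1, dtype=np.float32)
    steps = (1.0 / rate) * (1.0 + config.timestamp_jitter_sd * jit.astype(np.float64))
    t_abs = start_s + np.concatenate(([0.0], np.cumsum(steps)))

    mi = np.clip((t_abs // 60.0).astype(np.int64) - truth.span_start_min, 0, len(truth.lambda_realized) - 1)
    lam = truth.lambda_realized[mi]  # mg
    worn = truth.worn_minutes[mi]

    # band-limited unit-variance dynamic noise: white on a coarse grid,
    # cubic-interpolated to the jittered native timestamps
    crate = 2.0 * config.noise_bandwidth_hz
    nc = int(span_s * crate) + 16
    tc = start_s - 4.0 / crate + np.arange(nc) / crate
    u = lagrange_cubic(tc, rng.standard_normal((nc, 3)), t_abs)
    u_scale = 1.0 / u[: min(len(u), 1_000_000)].std(axis=0)

    dts = np.concatenate(([1.0 / rate], steps))
    active = worn & (lam > config.drift_active_threshold_mg)
    active_time = np.cumsum(active * dts)
    ghat = _posture_orientation(config, t_abs, active_time, rng)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    measured = rng.standard_normal((n, 3))  # sensor noise, overwritten in place
    _assemble_measured(
        measured,
        measured,
        u,
        u_scale,
        ghat,
        lam,
        t_abs,
        np.asarray(truth.device_gain, dtype=np.float64),
        np.asarray(truth.device_offset_mg, dtype=np.float64) / 1000.0,
        config.sensor_noise_sd_mg / 1000.0,
        config.swing_variance_frac,
        config.bout_threshold_mg,
        2.0 * np.pi * config.swing_freq_hz,
        phase,
    )

    def _make(lo: int, hi: int, device_id: str) -> RawRecording:
        tsel = t_abs[lo:hi]
        return RawRecording(
            participant_id=truth.participant_id,
            device_id=device_id,
            start_time=DAY0 + pd.Timedelta(seconds=float(tsel[0])),
            t=tsel - tsel[0],
            a=measured[lo:hi],
        )

    if config.split_devices and config.n_days >= 1:
        c_day = (config.n_days + 1) // 2
        c_s = (c_day * MINUTES_PER_DAY + config.changeover_clock_min) * 60.0
        i_a = int(np.searchsorted(t_abs, c_s))
        i_b = int(np.searchsorted(t_abs, c_s + config.changeover_gap_s))
        return [_make(0, i_a, "D1"), _make(i_b, n, "D2")]
    return [_make(0, n, "D1")]


def iter_participants(config: SimulationConfig):
    """Yield (truth, recordings) one participant at a time (bounded memory)."""
    truths, _ = simulate_truths(config)
    for truth in truths:
        yield truth, simulate_recording(truth, config)


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Simulate the full cohort: recordings, truths and covariate table.

    Holds every recording in memory; for large cohorts prefer
    :func:`iter_participants`.
    """
    truths, cov = simulate_truths(config)
    recordings: list[RawRecording] = []
    for truth in truths:
        recordings.extend(simulate_recording(truth, config))
    return CohortBundle(recordings=recordings, truths=truths, covariate_table=cov)


def true_wear_epochs(truth: ParticipantTruth, segment_min: int = 30) -> pd.DataFrame:
    """Scripted wear truth per 30-min epoch (worn iff majority of minutes worn)."""
    n_min = len(truth.worn_minutes)
    n_seg = n_min // segment_min
    worn = truth.worn_minutes[: n_seg * segment_min].reshape(n_seg, segment_min)
    start = truth.span_start_min + segment_min * np.arange(n_seg)
    return pd.DataFrame(
        {"start_min": start, "worn": worn.mean(axis=1) > 0.5}
    )
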