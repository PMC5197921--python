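"""Shared fixtures: small synthetic recordings and one processed cohort.

The cohort fixture is session-scoped because signal synthesis at 30 Hz over
multiple days is the expensive part of the suite; several recovery tests
share it read-only.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actiday.pipeline import PipelineConfig, process_participant
from actiday.preprocess import MagnitudeSeries, RawRecording
from actiday.simulate import SimulationConfig, simulate_recording, simulate_truths

START = pd.Timestamp("2024-03-04 00:00:00")


def make_magnitude(m: np.ndarray, t0=START, rate_hz: float = 50.0) -> MagnitudeSeries:
    return MagnitudeSeries(participant_id="T1", t0=t0, m=np.asarray(m, dtype=float), rate_hz=rate_hz)


def gravity_recording(
    duration_s: float,
    rate_hz: float = 5.0,
    g_vec=(0.0, 0.0, 1.0),
    noise_sd_g: float = 0.0,
    seed: int = 0,
) -> RawRecording:
    """Constant-orientation recording: gravity + optional white noise."""
    n = int(duration_s * rate_hz)
    t = np.arange(n) / rate_hz
    a = np.tile(np.asarray(g_vec, dtype=float), (n, 1))
    if noise_sd_g > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd_g, (n, 3))
    return RawRecording("T1", "D1", START, t, a)


def sphere_orientations(k: int) -> np.ndarray:
    """k roughly uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(k) + 0.5
    phi = np.arccos(1 - 2 * i / k)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def still_block_recording(
    orientations: np.ndarray,
    gain=(1.0, 1.0, 1.0),
    offset_mg=(0.0, 0.0, 0.0),
    block_s: float = 750.0,
    rate_hz: float = 1.0,
    noise_sd_g: float = 1e-4,
    seed: int = 0,
) -> RawRecording:
    """Recording made of long still blocks at the given orientations,
    measured through the gain-then-offset sensor model."""
    rng = np.random.default_rng(seed)
    n_b = int(block_s * rate_hz)
    true = np.repeat(orientations, n_b, axis=0)
    true = true + rng.normal(0.0, noise_sd_g, true.shape)
    measured = true * np.asarray(gain) + np.asarray(offset_mg) / 1000.0
    t = np.arange(len(measured)) / rate_hz
    return RawRecording("T1", "D1", START, t, measured)


@pytest.fixture(scope="session")
def wear_sim_config() -> SimulationConfig:
    """10-participant, 2-day cohort with one scripted 120-min non-wear bout
    per day (8.3% of the day), used for wear-detection and compliance
    recovery."""
    return SimulationConfig(
        n_per_group=5,
        n_days=2,
        nonwear_daily_prob=1.0,
        nonwear_epochs_min=4,
        nonwear_epochs_max=4,
        seed=20240307,
    )


@pytest.fixture(scope="session")
def wear_cohort(wear_sim_config):
    """Processed cohort: list of (truth, ParticipantResult)."""
    truths, _ = simulate_truths(wear_sim_config)
    out = []
    for truth in truths:
        recs = simulate_recording(truth, wear_sim_config)
        out.append((truth, process_participant(recs, PipelineConfig())))
    return out


@pytest.fixture(scope="session")
def two_day_recording():
    """One participant, 2 full days, single device, with its truth."""
    sim = SimulationConfig(n_per_group=1, n_days=2, split_devices=False, seed=99)
    truths, _ = simulate_truths(sim)
    truth = truths[0]
    rec = simulate_recording(truth, sim)[0]
    return sim, truth, rec
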