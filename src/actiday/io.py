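"""Delimited-text file formats of the pipeline.

All formats are plain text with a versioned schema tag so stages can be
run and inspected independently. Raw recordings use a one-line comment
header (participant, device, ISO 8601 start) above a t,x,y,z CSV body; t
is seconds since the recording start and x/y/z are in g.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .preprocess import CalibrationModel, MagnitudeSeries, RawRecording

SCHEMA_VERSION = "1"
FORMAT_MANIFEST = {
    "raw_recording": f"actiday-raw v{SCHEMA_VERSION}: header + t,x,y,z CSV (s, g)",
    "magnitude": f"actiday-mag v{SCHEMA_VERSION}: header + t,m_mg CSV",
    "covariates": f"CSV, participant_id index, group + numeric columns (v{SCHEMA_VERSION})",
    "day_ledger": f"CSV: participant_id,date,minutes_worn,minutes_covered,included,exclusion_reason (v{SCHEMA_VERSION})",
    "minute_features": f"CSV: participant_id,date,minute_of_day,activity_mg,jerk_mg_s,entropy_bits,worn,n_samples (v{SCHEMA_VERSION})",
    "profile": f"CSV: participant_id,minute_of_day,activity_mg,jerk_mg_s,entropy_bits,n_days (v{SCHEMA_VERSION})",
}


def write_raw_recording(rec: RawRecording, path: str | Path) -> Path:
    path = Path(path)
    header = (
        f"# actiday-raw v{SCHEMA_VERSION} participant={rec.participant_id} "
        f"device={rec.device_id} start={rec.start_time.isoformat()}\n"
    )
    body = pd.DataFrame({"t": rec.t, "x": rec.a[:, 0], "y": rec.a[:, 1], "z": rec.a[:, 2]})
    with open(path, "w") as fh:
        fh.write(header)
        body.to_csv(fh, index=False, float_format="%.6f", lineterminator="\n")
    return path


def read_raw_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# actiday-raw"):
            raise InputError(f"{path}: not an actiday raw recording (missing header)")
        meta = dict(tok.split("=", 1) for tok in header.split()[3:])
        body = pd.read_csv(fh)
    missing = {"t", "x", "y", "z"} - set(body.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    rec = RawRecording(
        participant_id=meta["participant"],
        device_id=meta["device"],
        start_time=pd.Timestamp(meta["start"]),
        t=body["t"].to_numpy(),
        a=body[["x", "y", "z"]].to_numpy(),
    )
    rec.validate()
    return rec


def write_magnitude(mag: MagnitudeSeries, path: str | Path) -> Path:
    path = Path(path)
    header = (
        f"# actiday-mag v{SCHEMA_VERSION} participant={mag.participant_id} "
        f"rate_hz={mag.rate_hz:g} t0={mag.t0.isoformat()}\n"
    )
    t = np.arange(mag.n_samples) / mag.rate_hz
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame({"t": t, "m_mg": mag.m}).to_csv(
            fh, index=False, float_format="%.4f", lineterminator="\n"
        )
    return path


def read_magnitude(path: str | Path) -> MagnitudeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# actiday-mag"):
            raise InputError(f"{path}: not an actiday magnitude file")
        meta = dict(tok.split("=", 1) for tok in header.split()[3:])
        body = pd.read_csv(fh)
    return MagnitudeSeries(
        participant_id=meta["participant"],
        t0=pd.Timestamp(meta["t0"]),
        m=body["m_mg"].to_numpy(),
        rate_hz=float(meta["rate_hz"]),
    )


def write_calibration_report(models: dict[str, CalibrationModel], path: str | Path) -> Path:
    path = Path(path)
    payload = {
        pid: {
            "gain": [round(float(g), 9) for g in m.gain],
            "offset_mg": [round(float(o), 6) for o in m.offset_mg],
            "pre_error_mg": None if np.isnan(m.pre_error_mg) else round(m.pre_error_mg, 6),
            "post_error_mg": None if np.isnan(m.post_error_mg) else round(m.post_error_mg, 6),
            "n_still": m.n_still,
            "n_iter": m.n_iter,
            "success": bool(m.success),
            "message": m.message,
        }
        for pid, m in models.items()
    }
    path.write_text(json.dumps({"schema": SCHEMA_VERSION, "calibration": payload}, indent=1))
    return path


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, index=index, float_format="%.6f", lineterminator="\n")
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
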