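"""Readers/writers: CSV and EDF signal files, JSON session logs,
adherence summaries.

Signals travel as CSV (header ``time_s,C3_uV,C4_uV``, UTF-8, '.' decimal)
or EDF, the standard clinical EEG container (16-bit samples, so the EDF
round-trip is exact only up to quantisation).  Session records are stored
as versioned JSON logs under a pseudonymous participant ID; the adherence
summary — sessions completed, score trajectories, between-session trend —
is the local analogue of a trial-oversight dashboard.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import BaselineProfile
from .feedback import RoundResult
from .protocol import ImpedanceReading, SessionPlan, SessionRecord
from .synthsig import EegSegment

__all__ = [
    "SCHEMA_VERSION",
    "SessionLog",
    "AdherenceSummary",
    "write_segment",
    "read_segment",
    "write_session_log",
    "read_session_log",
    "summarize_adherence",
    "adherence_to_csv",
]

SCHEMA_VERSION = 1
EXPECTED_CHANNELS = ("C3", "C4")
CSV_HEADER = "time_s,C3_uV,C4_uV"


# --- signal files ---------------------------------------------------------

def write_segment(segment: EegSegment, path, format: str | None = None) -> None:
    """Write a two-channel segment to CSV or EDF (inferred from suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        _write_csv(segment, path)
    elif fmt == "edf":
        _write_edf(segment, path)
    else:
        raise ValueError(f"unsupported signal format {fmt!r} (use csv or edf)")


def read_segment(path, format: str | None = None) -> EegSegment:
    """Read a two-channel segment from CSV or EDF."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported signal format {fmt!r} (use csv or edf)")


def _write_csv(segment: EegSegment, path: Path) -> None:
    if tuple(segment.channels) != EXPECTED_CHANNELS:
        raise ValueError(
            f"expected montage {EXPECTED_CHANNELS}, got {tuple(segment.channels)}"
        )
    t = segment.times()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(CSV_HEADER + "\n")
        for i in range(segment.n_samples):
            fh.write(
                f"{t[i]:.6f},{segment.data[0, i]:.8f},{segment.data[1, i]:.8f}\n"
            )


def _read_csv(path: Path) -> EegSegment:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header != CSV_HEADER:
        raise ValueError(
            f"malformed CSV header {header!r}; expected {CSV_HEADER!r} "
            f"(montage {EXPECTED_CHANNELS})"
        )
    df = pd.read_csv(path)
    if list(df.columns) != CSV_HEADER.split(","):
        raise ValueError(f"unexpected columns {list(df.columns)}")
    t = df["time_s"].to_numpy()
    dts = np.diff(t)
    if len(t) < 2:
        raise ValueError("need at least two samples to infer the sampling rate")
    if np.any(dts <= 0):
        raise ValueError("non-monotonic time column")
    dt_med = float(np.median(dts))
    if np.max(np.abs(dts - dt_med)) > 0.01 * dt_med:
        raise ValueError("non-uniform sampling in time column")
    fs = round(1.0 / dt_med, 6)
    data = df[["C3_uV", "C4_uV"]].to_numpy().T
    return EegSegment(channels=EXPECTED_CHANNELS, fs=fs, data=data, t0=float(t[0]))


# --- minimal EDF codec ----------------------------------------------------
# EDF: 256-byte fixed header + 256 bytes per signal header, then 1 s data
# records of little-endian int16 samples scaled between the physical and
# digital extrema.  Only the subset needed for two-channel µV EEG with an
# integer sampling rate is implemented; no library in the runtime stack
# can write EDF.

_DIG_MIN, _DIG_MAX = -32768, 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(segment: EegSegment, path: Path) -> None:
    if tuple(segment.channels) != EXPECTED_CHANNELS:
        raise ValueError(
            f"expected montage {EXPECTED_CHANNELS}, got {tuple(segment.channels)}"
        )
    fs = segment.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1 s record
    n = segment.n_samples
    n_records = math.ceil(n / spr)
    ns = segment.n_channels

    data = segment.data
    pad = n_records * spr - n
    if pad:
        data = np.pad(data, ((0, 0), (0, pad)), mode="edge")

    phys_min = np.floor(data.min(axis=-1) - 1.0)
    phys_max = np.ceil(data.max(axis=-1) + 1.0)
    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    start = dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _edf_field("0", 8),  # version
            _edf_field("X X X X", 80),  # local patient id (pseudonymous)
            _edf_field("Startdate X X X X", 80),  # local recording id
            _edf_field(start.strftime("%d.%m.%y"), 8),
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(str(256 * (1 + ns)), 8),  # header bytes
            _edf_field("", 44),  # reserved
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),  # record duration, s
            _edf_field(str(ns), 4),
        ]
    )
    sig_headers = b"".join(
        [
            b"".join(_edf_field(f"EEG {ch}", 16) for ch in segment.channels),
            b"".join(_edf_field("AgAgCl sponge electrode", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_min[c]:.1f}", 8) for c in range(ns)),
            b"".join(_edf_field(f"{phys_max[c]:.1f}", 8) for c in range(ns)),
            b"".join(_edf_field(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_edf_field(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_edf_field("HP:0.5Hz LP:45Hz", 80) for _ in range(ns)),
            b"".join(_edf_field(str(spr), 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),  # reserved
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        for r in range(n_records):
            for c in range(ns):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path) -> EegSegment:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise ValueError("truncated EDF header")

    def fld(off, width):
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    n_records = int(fld(236, 8))
    record_dur = float(fld(244, 8))
    ns = int(fld(252, 4))
    off = 256
    labels = [fld(off + 16 * c, 16) for c in range(ns)]
    off += 16 * ns + 80 * ns + 8 * ns
    phys_min = np.array([float(fld(off + 8 * c, 8)) for c in range(ns)])
    off += 8 * ns
    phys_max = np.array([float(fld(off + 8 * c, 8)) for c in range(ns)])
    off += 8 * ns
    dig_min = np.array([int(fld(off + 8 * c, 8)) for c in range(ns)])
    off += 8 * ns
    dig_max = np.array([int(fld(off + 8 * c, 8)) for c in range(ns)])
    off += 8 * ns + 80 * ns
    spr = [int(fld(off + 8 * c, 8)) for c in range(ns)]

    channels = tuple(lbl.removeprefix("EEG ").strip() for lbl in labels)
    if channels != EXPECTED_CHANNELS:
        raise ValueError(
            f"expected montage {EXPECTED_CHANNELS}, got {channels}"
        )
    if len(set(spr)) != 1:
        raise ValueError("mixed per-channel sampling rates are not supported")
    fs = spr[0] / record_dur

    body = raw[256 * (1 + ns) :]
    rec_len = sum(spr)
    samples = np.frombuffer(body, dtype="<i2", count=n_records * rec_len)
    samples = samples.reshape(n_records, ns, spr[0])
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (
        samples.transpose(1, 0, 2).reshape(ns, -1).astype(float) - dig_min[:, None]
    ) * gain[:, None] + phys_min[:, None]
    return EegSegment(channels=channels, fs=fs, data=data)


# --- session logs ---------------------------------------------------------

@dataclass
class SessionLog:
    """One participant's serialized session records."""

    participant_id: str
    records: list[SessionRecord]
    schema_version: int = SCHEMA_VERSION


def _record_to_dict(record: SessionRecord) -> dict:
    plan = record.plan
    out = {
        "session_index": plan.session_index,
        "scheduled_day": plan.scheduled_day,
        "date": plan.date.isoformat(),
        "game_id": plan.game_id,
        "n_rounds": plan.n_rounds,
        "round_duration_s": plan.round_duration,
        "break_duration_s": plan.break_duration,
        "resting_duration_s": plan.resting_duration,
        "started_at": record.started_at,
        "completed": record.completed,
        "failure_reason": record.failure_reason,
        "impedance_readings": [
            {"timestamp_s": r.timestamp, "impedances_kohm": r.impedances_kohm}
            for r in record.impedance_readings
        ],
        "rounds": [asdict(r) for r in record.round_results],
        "qc": [
            {
                "n_epochs": q.n_epochs,
                "fraction_clean": q.fraction_clean,
                "channel_rms_uv": [float(v) for v in q.channel_rms],
            }
            for q in record.qc_reports
        ],
    }
    if record.baseline is not None:
        b = record.baseline
        out["baseline"] = {
            "channels": list(b.channels),
            "band_names": list(b.band_names),
            "baseline_power": b.baseline_power.tolist(),
            "threshold": b.threshold.tolist(),
            "n_epochs_used": b.n_epochs_used,
            "recording_duration_s": b.recording_duration,
            "session_id": b.session_id,
        }
    else:
        out["baseline"] = None
    return out


def _record_from_dict(d: dict) -> SessionRecord:
    plan = SessionPlan(
        session_index=d["session_index"],
        scheduled_day=d["scheduled_day"],
        date=dt.date.fromisoformat(d["date"]),
        game_id=d["game_id"],
        n_rounds=d["n_rounds"],
        round_duration=d["round_duration_s"],
        break_duration=d["break_duration_s"],
        resting_duration=d["resting_duration_s"],
    )
    baseline = None
    if d.get("baseline"):
        b = d["baseline"]
        baseline = BaselineProfile(
            channels=tuple(b["channels"]),
            band_names=tuple(b["band_names"]),
            baseline_power=np.array(b["baseline_power"]),
            threshold=np.array(b["threshold"]),
            n_epochs_used=b["n_epochs_used"],
            recording_duration=b["recording_duration_s"],
            session_id=b["session_id"],
        )
    return SessionRecord(
        plan=plan,
        baseline=baseline,
        round_results=tuple(RoundResult(**r) for r in d["rounds"]),
        impedance_readings=tuple(
            ImpedanceReading(
                impedances_kohm=r["impedances_kohm"], timestamp=r["timestamp_s"]
            )
            for r in d["impedance_readings"]
        ),
        completed=d["completed"],
        started_at=d["started_at"],
        failure_reason=d.get("failure_reason"),
    )


def write_session_log(log: SessionLog, path) -> None:
    """Serialize a session log to JSON (sorted keys: byte-reproducible)."""
    payload = {
        "schema_version": log.schema_version,
        "participant_id": log.participant_id,
        "records": [_record_to_dict(r) for r in log.records],
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_session_log(path) -> SessionLog:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported session-log schema version {version!r} "
            f"(this build reads version {SCHEMA_VERSION})"
        )
    return SessionLog(
        participant_id=payload["participant_id"],
        records=[_record_from_dict(d) for d in payload["records"]],
        schema_version=version,
    )


# --- adherence ------------------------------------------------------------

@dataclass
class AdherenceSummary:
    """Engagement and progression metrics across a participant's sessions."""

    participant_id: str
    sessions_completed: int  # of 20
    sessions_planned: int
    days_elapsed: int
    per_session_scores: list[int]  # total score per completed session
    session_indices: list[int]
    round_trajectory: list[float]  # mean score of round r across sessions
    between_session_slope: float | None  # OLS, points per session
    missing_sessions: list[int]


def summarize_adherence(
    logs: list[SessionLog], n_planned: int = 20
) -> AdherenceSummary:
    """Adherence and progression summary across one participant's logs.

    The between-session trend is the ordinary-least-squares slope of
    total session score against session index, reported only once ≥ 3
    completed sessions exist.  The round trajectory (mean score of rounds
    1→5 across sessions) shows within-session progression.
    """
    if not logs:
        raise ValueError("need at least one session log")
    pid = logs[0].participant_id
    records = [r for log in logs for r in log.records]
    records.sort(key=lambda r: r.plan.session_index)
    completed = [r for r in records if r.completed]
    indices = [r.plan.session_index for r in completed]
    scores = [r.total_score for r in completed]

    slope = None
    if len(completed) >= 3:
        slope = float(stats.linregress(indices, scores).slope)

    n_rounds = max((len(r.round_results) for r in completed), default=0)
    trajectory = []
    for j in range(n_rounds):
        vals = [r.round_results[j].score for r in completed if len(r.round_results) > j]
        trajectory.append(float(np.mean(vals)) if vals else float("nan"))

    if completed:
        days = (
            completed[-1].plan.date - completed[0].plan.date
        ).days + 1
    else:
        days = 0
    missing = sorted(set(range(1, n_planned + 1)) - set(indices))
    return AdherenceSummary(
        participant_id=pid,
        sessions_completed=len(completed),
        sessions_planned=n_planned,
        days_elapsed=days,
        per_session_scores=scores,
        session_indices=indices,
        round_trajectory=trajectory,
        between_session_slope=slope,
        missing_sessions=missing,
    )


def adherence_to_csv(summary: AdherenceSummary, path) -> None:
    """Per-session score table with the headline metrics as a CSV."""
    df = pd.DataFrame(
        {
            "session_index": summary.session_indices,
            "total_score": summary.per_session_scores,
        }
    )
    df["participant_id"] = summary.participant_id
    df["between_session_slope"] = summary.between_session_slope
    df.to_csv(path, index=False)
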