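"""Data-quality checks: artifact detection and session-level review.

Mirrors the oversight a trial team would do on stored home recordings —
flag epochs that are contaminated rather than neural.  Three rules,
checked per channel in this order:

* ``amplitude`` — peak-to-peak above 200 µV (blinks, movement);
* ``flatline``  — RMS below 0.1 µV (lost electrode contact);
* ``clipping``  — more than 1 % of samples at the amplifier rail.

Thresholds are conventional scalp-EEG values and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QcThresholds",
    "QcReport",
    "SessionQualitySummary",
    "detect_artifacts",
    "epoch_is_clean",
    "session_quality_summary",
]


@dataclass(frozen=True)
class QcThresholds:
    pp_max_uv: float = 200.0  # peak-to-peak amplitude limit
    rms_min_uv: float = 0.1  # flatline floor
    rail_uv: float = 400.0  # |sample| at or above this counts as railed
    clip_fraction: float = 0.01  # railed-sample fraction that flags clipping


DEFAULT_THRESHOLDS = QcThresholds()


@dataclass
class QcReport:
    """Per-epoch clean flags for one segment."""

    epoch_duration: float
    clean: np.ndarray  # (n_epochs,) bool
    reasons: tuple[str | None, ...]  # rejection reason per epoch, None if clean
    channel_rms: np.ndarray  # (n_channels,) µV over the whole segment

    @property
    def n_epochs(self) -> int:
        return len(self.clean)

    @property
    def fraction_clean(self) -> float:
        return float(np.mean(self.clean)) if self.n_epochs else 1.0


def _epoch_reason(epoch: np.ndarray, thr: QcThresholds) -> str | None:
    """First matching rejection reason for one (n_channels, n) epoch."""
    pp = epoch.max(axis=-1) - epoch.min(axis=-1)
    if np.any(pp > thr.pp_max_uv):
        return "amplitude"
    rms = np.sqrt(np.mean(epoch**2, axis=-1))
    if np.any(rms < thr.rms_min_uv):
        return "flatline"
    railed = np.mean(np.abs(epoch) >= thr.rail_uv, axis=-1)
    if np.any(railed > thr.clip_fraction):
        return "clipping"
    return None


def epoch_is_clean(
    epoch_data: np.ndarray, thresholds: QcThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Whether one (n_channels, n_samples) epoch passes all QC rules."""
    return _epoch_reason(np.asarray(epoch_data, float), thresholds) is None


def detect_artifacts(
    segment,
    epoch: float = 1.0,
    thresholds: QcThresholds = DEFAULT_THRESHOLDS,
) -> QcReport:
    """Flag contaminated epochs of a segment.

    The segment is cut into consecutive non-overlapping ``epoch``-second
    windows (a trailing partial window is ignored); an epoch is rejected
    if any channel trips a rule, and carries the first matching reason.
    """
    if epoch <= 0:
        raise ValueError(f"epoch must be > 0 s, got {epoch}")
    n_per = int(round(epoch * segment.fs))
    n_epochs = segment.n_samples // n_per
    clean = np.ones(n_epochs, dtype=bool)
    reasons: list[str | None] = []
    for i in range(n_epochs):
        reason = _epoch_reason(
            segment.data[:, i * n_per : (i + 1) * n_per], thresholds
        )
        reasons.append(reason)
        clean[i] = reason is None
    rms = np.sqrt(np.mean(segment.data**2, axis=-1))
    return QcReport(
        epoch_duration=epoch,
        clean=clean,
        reasons=tuple(reasons),
        channel_rms=rms,
    )


@dataclass
class SessionQualitySummary:
    status: str  # "pass" or "warn"
    warnings: tuple[str, ...]
    fraction_clean: float
    n_rounds: int


def session_quality_summary(
    record,
    min_fraction_clean: float = 0.8,
    expected_rounds: int = 5,
) -> SessionQualitySummary:
    """Aggregate round-level QC into a pass/warn verdict for one session.

    Warns when the pooled clean-epoch fraction drops below
    ``min_fraction_clean`` or when rounds are missing from the record.
    """
    reports = list(getattr(record, "qc_reports", []) or [])
    n_rounds = len(getattr(record, "round_results", []) or [])
    warnings: list[str] = []
    if n_rounds < expected_rounds:
        warnings.append(
            f"only {n_rounds} of {expected_rounds} rounds recorded"
        )
    if reports:
        total = sum(r.n_epochs for r in reports)
        clean = sum(int(r.clean.sum()) for r in reports)
        frac = clean / total if total else 1.0
    else:
        frac = 1.0
        warnings.append("no QC reports attached to session")
    if frac < min_fraction_clean:
        warnings.append(
            f"clean-epoch fraction {frac:.2f} below {min_fraction_clean:.2f}"
        )
    return SessionQualitySummary(
        status="warn" if warnings else "pass",
        warnings=tuple(warnings),
        fraction_clean=frac,
        n_rounds=n_rounds,
    )
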