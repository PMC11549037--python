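"""Per-session resting-state baseline calibration.

Before each session's games the participant records two minutes of
eyes-open resting EEG while fixating a cross.  That recording sets the
participant's own thresholds for the three targeted bands: the recording
is cut into 2 s epochs (50 % overlap), artifact epochs are rejected, and
the per-channel per-band threshold is the median clean-epoch band power
times a configurable multiplier (default 1.0 — success means crossing
one's own resting median in the trained direction).  The median is used
rather than the mean so residual artifacts cannot drag the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import qc
from .spectral import BandScheme, welch_band_powers

__all__ = ["BaselineProfile", "CalibrationError", "compute_baseline",
           "recalibrate_each_session"]

REQUIRED_CHANNELS = ("C3", "C4")
DEFAULT_RESTING_DURATION = 120.0  # s
BASELINE_EPOCH = 2.0  # s
BASELINE_OVERLAP = 0.5
MIN_CLEAN_EPOCHS = 10


class CalibrationError(ValueError):
    """Raised when a resting recording cannot yield usable thresholds."""


@dataclass
class BaselineProfile:
    """Per-channel, per-band resting statistics and decision thresholds."""

    channels: tuple[str, ...]
    band_names: tuple[str, ...]
    baseline_power: np.ndarray  # (n_channels, n_bands), µV², median
    threshold: np.ndarray  # (n_channels, n_bands), µV²
    n_epochs_used: int
    recording_duration: float  # s
    session_id: int = 0

    def __post_init__(self) -> None:
        self.baseline_power = np.asarray(self.baseline_power, float)
        self.threshold = np.asarray(self.threshold, float)
        if np.any(self.threshold <= 0) or not np.all(np.isfinite(self.threshold)):
            raise CalibrationError("thresholds must be positive and finite")
        if self.n_epochs_used < MIN_CLEAN_EPOCHS:
            raise CalibrationError(
                f"baseline built from {self.n_epochs_used} epochs; "
                f"need ≥ {MIN_CLEAN_EPOCHS}"
            )

    def channel_mean_threshold(self) -> np.ndarray:
        """Thresholds averaged across channels, per band."""
        return self.threshold.mean(axis=0)


def compute_baseline(
    resting,
    scheme: BandScheme,
    threshold_multiplier: float = 1.0,
    min_duration: float = DEFAULT_RESTING_DURATION,
    session_id: int = 0,
    qc_thresholds: qc.QcThresholds = qc.DEFAULT_THRESHOLDS,
) -> BaselineProfile:
    """Thresholds for the three targeted bands from a resting recording.

    Parameters
    ----------
    resting : EegSegment
        ≥ ``min_duration`` seconds of C3/C4 resting EEG.
    scheme : BandScheme
    threshold_multiplier : float
        Threshold = multiplier × median resting band power.  1.0 places
        the bar at the participant's own resting median.

    Raises
    ------
    CalibrationError
        If the recording is too short, the montage is wrong, fewer than
        10 clean epochs survive artifact rejection, or the resulting
        thresholds are degenerate (e.g. an all-zero recording) — in the
        app flow these all mean "re-record the baseline".
    """
    if tuple(resting.channels) != REQUIRED_CHANNELS:
        raise CalibrationError(
            f"expected channels {REQUIRED_CHANNELS}, got {tuple(resting.channels)}"
        )
    if resting.duration < min_duration:
        raise CalibrationError(
            f"resting recording of {resting.duration:.1f} s is shorter than "
            f"the required {min_duration:.0f} s; re-record"
        )
    step = BASELINE_EPOCH * (1 - BASELINE_OVERLAP)
    starts = np.arange(0.0, resting.duration - BASELINE_EPOCH + 1e-9, step)
    epoch_powers = []
    for s in starts:
        ep = resting.slice(s, s + BASELINE_EPOCH)
        if not qc.epoch_is_clean(ep.data, qc_thresholds):
            continue
        # full-epoch window: 0.5 Hz resolution keeps band-edge leakage small
        bp = welch_band_powers(ep, scheme, window=BASELINE_EPOCH, overlap=0.0)
        epoch_powers.append(bp.powers)
    if len(epoch_powers) < MIN_CLEAN_EPOCHS:
        raise CalibrationError(
            f"only {len(epoch_powers)} clean epochs after artifact rejection "
            f"(need ≥ {MIN_CLEAN_EPOCHS}); re-record the resting baseline"
        )
    baseline = np.median(np.stack(epoch_powers), axis=0)
    threshold = baseline * threshold_multiplier
    if np.any(threshold <= 0):
        raise CalibrationError(
            "degenerate resting recording: zero median band power; "
            "check electrode contact and re-record"
        )
    return BaselineProfile(
        channels=REQUIRED_CHANNELS,
        band_names=scheme.names,
        baseline_power=baseline,
        threshold=threshold,
        n_epochs_used=len(epoch_powers),
        recording_duration=resting.duration,
        session_id=session_id,
    )


def recalibrate_each_session(history: list[BaselineProfile]) -> BaselineProfile:
    """Baseline policy: each session uses its own (latest) resting profile.

    The baseline is deliberately per-session, not pooled across sessions —
    the app records a fresh resting baseline before every session's games.
    Exposed as an explicit operation so the policy is testable and could
    be swapped (e.g. for a pooled or shrunk estimate) in one place.
    """
    if not history:
        raise ValueError("no baseline profiles recorded yet")
    return max(history, key=lambda p: p.session_id)
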