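"""Real-time regulation decisions, feedback smoothing and round scoring.

Every second of gameplay, band powers from the latest 1 s epoch are
compared to the session's resting thresholds: a suppress band is
regulated when its power is strictly below threshold, a reinforce band
when strictly above.  The participant scores a point for each second in
which *all three* targeted bands are regulated simultaneously.  A
smoothed (EWMA) success level drives the game display — character motion
and background colour — while the integer score is only revealed at the
end of each 2.5-minute round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import BaselineProfile
from .spectral import BandPowerVector, BandScheme

__all__ = [
    "RegulationDecision",
    "RoundResult",
    "decide_epoch",
    "feedback_level",
    "score_round",
    "display_state",
    "ROUND_DURATION",
    "DECISION_EPOCH",
]

ROUND_DURATION = 150.0  # s, one 2.5-min round
DECISION_EPOCH = 1.0  # s, the "score for every second" grain
DEFAULT_SMOOTHING_TAU = 3.0  # s, EWMA time constant of the display level
N_MOTION_STEPS = 5  # character-motion quantisation of the display


@dataclass(frozen=True)
class RegulationDecision:
    """Outcome of one decision epoch."""

    epoch_index: int
    band_names: tuple[str, ...]
    regulated: tuple[bool, ...]  # per band, in band_names order
    all_regulated: bool
    feedback_level: float = 0.0  # smoothed display level in [0, 1]

    def __post_init__(self) -> None:
        if self.all_regulated != all(self.regulated):
            raise ValueError("all_regulated must be the AND of the band flags")
        if not 0.0 <= self.feedback_level <= 1.0:
            raise ValueError("feedback_level must lie in [0, 1]")


@dataclass(frozen=True)
class RoundResult:
    """Score summary of one round, shown to the participant at round end."""

    round_index: int  # 1–5
    score: int  # seconds with all three bands regulated
    n_epochs: int
    success_fraction: float
    game_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.score <= self.n_epochs:
            raise ValueError("score must lie in [0, n_epochs]")


def decide_epoch(
    powers: BandPowerVector,
    profile: BaselineProfile,
    scheme: BandScheme,
    epoch_index: int = 0,
    combine: str = "mean",
) -> RegulationDecision:
    """Regulation decision for one epoch.

    Band powers are combined across C3 and C4 (``combine="mean"``:
    channel-averaged power against the channel-averaged threshold;
    ``combine="and"``: each channel must comply individually) and compared
    strictly to the trained direction: suppress bands must be *below*
    threshold, reinforce bands *above*.  Ties fail — a power exactly at
    threshold is not a success.
    """
    if tuple(powers.channels) != tuple(profile.channels):
        raise ValueError(
            f"channel mismatch: powers {powers.channels} vs profile {profile.channels}"
        )
    if tuple(powers.band_names) != tuple(profile.band_names) or tuple(
        powers.band_names
    ) != scheme.names:
        raise ValueError(
            f"band mismatch: powers {powers.band_names}, profile "
            f"{profile.band_names}, scheme {scheme.names}"
        )
    if combine not in ("mean", "and"):
        raise ValueError(f"combine must be 'mean' or 'and', got {combine!r}")
    flags = []
    for j, band in enumerate(scheme):
        p = powers.powers[:, j]
        thr = profile.threshold[:, j]
        if combine == "mean":
            ok = p.mean() < thr.mean() if band.direction == "suppress" \
                else p.mean() > thr.mean()
        else:
            ok = bool(np.all(p < thr)) if band.direction == "suppress" \
                else bool(np.all(p > thr))
        flags.append(bool(ok))
    return RegulationDecision(
        epoch_index=epoch_index,
        band_names=scheme.names,
        regulated=tuple(flags),
        all_regulated=all(flags),
        feedback_level=1.0 if all(flags) else 0.0,
    )


def feedback_level(
    decisions,
    smoothing: float = DEFAULT_SMOOTHING_TAU,
    epoch: float = DECISION_EPOCH,
) -> float:
    """Smoothed display level from a decision history.

    Exponentially weighted moving average of the per-epoch all-regulated
    flag (as 0/1) with time constant ``smoothing`` seconds: each step the
    level moves a fraction ``1 - exp(-epoch/smoothing)`` toward the new
    flag.  Converges to 1 under sustained success, 0 under sustained
    failure, and oscillates about 0.5 under alternation.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("need at least one decision")
    alpha = 1.0 - math.exp(-epoch / smoothing)
    level = 0.0
    for d in decisions:
        x = 1.0 if d.all_regulated else 0.0
        level += alpha * (x - level)
    return level


def score_round(
    decisions,
    round_index: int = 1,
    game_id: str = "jellyfish",
    epoch: float = DECISION_EPOCH,
) -> RoundResult:
    """Integer round score: one point per fully regulated second.

    The score is returned as a round summary, not streamed — the in-game
    point counter was removed in favour of a score display at round end.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("cannot score an empty round")
    score = sum(1 for d in decisions if d.all_regulated)
    n = len(decisions)
    return RoundResult(
        round_index=round_index,
        score=score,
        n_epochs=n,
        success_fraction=score / n,
        game_id=game_id,
    )


def display_state(level: float) -> dict:
    """Map a smoothed feedback level to the game display.

    The character motion is quantised to 5 steps (0 = idle, 4 = full
    speed/height) and the background colour interpolates linearly from the
    "unregulated" to the "regulated" palette.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    motion = min(int(level * N_MOTION_STEPS), N_MOTION_STEPS - 1)
    return {"motion_step": motion, "background_mix": float(level)}
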