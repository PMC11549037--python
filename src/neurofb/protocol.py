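"""Intervention scheduling and the per-session closed loop.

The intervention is one neurofeedback session per day for 20 days over a
four-week period, five sessions per week on weekdays.  Each session runs:
electrode impedance check (< 50 kΩ on every electrode) → two-minute
resting recording → baseline calibration → five 2.5-minute rounds of a
game with 30 s breaks.  Four games (jellyfish, bird, plane, rocket) are
introduced one per week, each for a block of five sessions, in the same
order for every participant.  :func:`run_session` simulates one full
session against a synthetic participant; :func:`run_intervention` chains
all 20 with overnight relaxation of the participant's state.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from . import qc
from .calibration import BaselineProfile, CalibrationError, compute_baseline
from .feedback import (
    DECISION_EPOCH,
    ROUND_DURATION,
    RoundResult,
    decide_epoch,
    score_round,
)
from .spectral import BandScheme, default_scheme, welch_band_powers
from .synthsig import (
    DEFAULT_FS,
    ParticipantModel,
    generate_segment,
    relax_model,
    step_learner,
)

__all__ = [
    "ELECTRODES",
    "GAME_ORDER",
    "ImpedanceReading",
    "GateResult",
    "SessionPlan",
    "InterventionSchedule",
    "SessionRecord",
    "impedance_gate",
    "build_intervention_schedule",
    "simulate_impedance",
    "run_session",
    "run_intervention",
]

#: Montage: two sensors over sensorimotor cortex plus two ear-clip references.
ELECTRODES = ("C3", "C4", "ear_left", "ear_right")

#: Fixed game rotation, one game per block of five sessions.
GAME_ORDER = ("jellyfish", "bird", "plane", "rocket")

IMPEDANCE_LIMIT_KOHM = 50.0
N_SESSIONS = 20
SESSIONS_PER_GAME = 5
MAX_SPAN_DAYS = 28
N_ROUNDS = 5
BREAK_DURATION = 30.0  # s
RESTING_DURATION = 120.0  # s
BREAK_RELAX_TAU = 60.0  # s, state relaxation time constant during breaks
MAX_IMPEDANCE_RETRIES = 5


@dataclass(frozen=True)
class ImpedanceReading:
    """Electrode–skin impedances (kΩ) at one moment."""

    impedances_kohm: dict[str, float]
    timestamp: float = 0.0  # s since session start

    def __post_init__(self) -> None:
        for name, z in self.impedances_kohm.items():
            if z < 0:
                raise ValueError(
                    f"electrode {name!r}: negative impedance {z} kΩ (sensor fault)"
                )


@dataclass(frozen=True)
class GateResult:
    passed: bool
    failing_electrodes: tuple[str, ...]
    limit_kohm: float


def impedance_gate(
    reading: ImpedanceReading, limit_kohm: float = IMPEDANCE_LIMIT_KOHM
) -> GateResult:
    """Pass iff every electrode impedance is strictly below the limit.

    On failure the failing electrode labels are returned so the app can
    surface the matching troubleshooting steps (re-soak sponges, adjust
    ear-clips, …).  An impedance exactly at the limit fails.
    """
    failing = tuple(
        name for name, z in reading.impedances_kohm.items() if not z < limit_kohm
    )
    return GateResult(
        passed=not failing, failing_electrodes=failing, limit_kohm=limit_kohm
    )


@dataclass(frozen=True)
class SessionPlan:
    """One scheduled session of the 20-session plan."""

    session_index: int  # 1–20
    scheduled_day: int  # 1–28, day within the intervention window
    date: dt.date
    game_id: str
    n_rounds: int = N_ROUNDS
    round_duration: float = ROUND_DURATION
    break_duration: float = BREAK_DURATION
    resting_duration: float = RESTING_DURATION

    def __post_init__(self) -> None:
        if not 1 <= self.session_index <= N_SESSIONS:
            raise ValueError("session_index must lie in 1–20")
        if self.game_id not in GAME_ORDER:
            raise ValueError(f"unknown game {self.game_id!r}")


@dataclass(frozen=True)
class InterventionSchedule:
    """The full 20-session, four-game, ≤ 28-day plan."""

    sessions: tuple[SessionPlan, ...]

    def __post_init__(self) -> None:
        if len(self.sessions) != N_SESSIONS:
            raise ValueError(f"need exactly {N_SESSIONS} sessions")
        span = (self.sessions[-1].date - self.sessions[0].date).days
        if span > MAX_SPAN_DAYS - 1:
            raise ValueError(f"schedule spans {span + 1} days, above {MAX_SPAN_DAYS}")

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)


def game_for_session(session_index: int) -> str:
    """Game for a 1-based session index: blocks of five, fixed order."""
    if not 1 <= session_index <= N_SESSIONS:
        raise ValueError("session_index must lie in 1–20")
    return GAME_ORDER[(session_index - 1) // SESSIONS_PER_GAME]


def build_intervention_schedule(start_day: dt.date) -> InterventionSchedule:
    """Place 20 daily sessions on consecutive weekdays from ``start_day``.

    Five sessions per week keeps 20 sessions inside the four-week window
    from any starting weekday (weekend starts roll to Monday).  Sessions
    1–5 play jellyfish, 6–10 bird, 11–15 plane, 16–20 rocket.
    """
    day = start_day
    while day.weekday() >= 5:  # roll a weekend start to Monday
        day += dt.timedelta(days=1)
    first = day
    sessions = []
    for i in range(1, N_SESSIONS + 1):
        while day.weekday() >= 5:
            day += dt.timedelta(days=1)
        sessions.append(
            SessionPlan(
                session_index=i,
                scheduled_day=(day - first).days + 1,
                date=day,
                game_id=game_for_session(i),
            )
        )
        day += dt.timedelta(days=1)
    return InterventionSchedule(sessions=tuple(sessions))


@dataclass
class SessionRecord:
    """Everything stored for one (simulated) session."""

    plan: SessionPlan
    baseline: BaselineProfile | None
    round_results: tuple[RoundResult, ...]
    impedance_readings: tuple[ImpedanceReading, ...]
    qc_reports: tuple[qc.QcReport, ...] = ()
    completed: bool = False
    started_at: float = 0.0  # epoch seconds of session start
    failure_reason: str | None = None
    final_model: ParticipantModel | None = field(default=None, repr=False)

    @property
    def total_score(self) -> int:
        return sum(r.score for r in self.round_results)


def simulate_impedance(
    rng: np.random.Generator,
    median_kohm: float = 20.0,
    sigma: float = 0.4,
    outlier_prob: float = 0.05,
    timestamp: float = 0.0,
) -> ImpedanceReading:
    """Draw a plausible impedance reading.

    Lognormal around ~20 kΩ per electrode, with occasional high outliers
    (a dry sponge or loose ear-clip) so the gate-failure and
    troubleshooting paths get exercised.
    """
    z = {}
    for name in ELECTRODES:
        val = median_kohm * np.exp(sigma * rng.standard_normal())
        if rng.uniform() < outlier_prob:
            val *= rng.uniform(3.0, 8.0)
        z[name] = float(val)
    return ImpedanceReading(impedances_kohm=z, timestamp=timestamp)


def run_session(
    model: ParticipantModel,
    plan: SessionPlan,
    seed: int,
    scheme: BandScheme | None = None,
    fs: float = DEFAULT_FS,
    threshold_multiplier: float = 1.0,
    started_at: float = 0.0,
) -> SessionRecord:
    """Simulate one complete session against a synthetic participant.

    Flow: impedance gate (re-drawn after simulated troubleshooting until
    it passes, up to 5 retries) → resting recording → baseline
    calibration → five rounds of 1 s generate/estimate/decide/learn
    epochs with 30 s breaks, during which the participant's state relaxes
    toward its trait profile.  Deterministic given (model, plan, seed).
    The evolved participant model is returned on the record
    (``final_model``) so multi-session simulations can chain sessions.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(seed)
    clock = 0.0

    readings = []
    for attempt in range(MAX_IMPEDANCE_RETRIES + 1):
        # troubleshooting (re-soaking sponges, adjusting ear-clips) lowers
        # the expected impedance on each retry
        reading = simulate_impedance(
            rng, median_kohm=20.0 * 0.7**attempt, timestamp=clock
        )
        readings.append(reading)
        if impedance_gate(reading).passed:
            break
        clock += 60.0  # simulated troubleshooting takes a minute
    else:
        return SessionRecord(
            plan=plan, baseline=None, round_results=(),
            impedance_readings=tuple(readings), completed=False,
            started_at=started_at, failure_reason="impedance", final_model=model,
        )

    resting = generate_segment(
        model, plan.resting_duration, fs=fs,
        seed=int(rng.integers(2**31)), t0=clock,
    )
    try:
        baseline = compute_baseline(
            resting, scheme,
            threshold_multiplier=threshold_multiplier,
            min_duration=plan.resting_duration,
            session_id=plan.session_index,
        )
    except CalibrationError as err:
        return SessionRecord(
            plan=plan, baseline=None, round_results=(),
            impedance_readings=tuple(readings), completed=False,
            started_at=started_at, failure_reason=f"calibration: {err}",
            final_model=model,
        )
    clock += plan.resting_duration

    round_results = []
    qc_reports = []
    n_epochs = int(round(plan.round_duration / DECISION_EPOCH))
    for round_index in range(1, plan.n_rounds + 1):
        decisions = []
        epoch_data = []
        for epoch_index in range(n_epochs):
            seg = generate_segment(
                model, DECISION_EPOCH, fs=fs,
                seed=int(rng.integers(2**31)), t0=clock,
            )
            epoch_data.append(seg.data)
            powers = welch_band_powers(seg, scheme, window=DECISION_EPOCH, overlap=0.0)
            decision = decide_epoch(powers, baseline, scheme, epoch_index=epoch_index)
            decisions.append(decision)
            model = step_learner(model, decision)
            clock += DECISION_EPOCH
        round_seg_data = np.concatenate(epoch_data, axis=-1)
        round_seg = resting.__class__(
            channels=("C3", "C4"), fs=fs, data=round_seg_data,
            t0=clock - plan.round_duration,
        )
        qc_reports.append(qc.detect_artifacts(round_seg, epoch=DECISION_EPOCH))
        round_results.append(
            score_round(decisions, round_index=round_index, game_id=plan.game_id)
        )
        if round_index < plan.n_rounds:
            model = relax_model(model, plan.break_duration, tau=BREAK_RELAX_TAU)
            clock += plan.break_duration

    return SessionRecord(
        plan=plan,
        baseline=baseline,
        round_results=tuple(round_results),
        impedance_readings=tuple(readings),
        qc_reports=tuple(qc_reports),
        completed=True,
        started_at=started_at,
        final_model=model,
    )


def run_intervention(
    model: ParticipantModel,
    schedule: InterventionSchedule,
    seed: int,
    scheme: BandScheme | None = None,
    fs: float = DEFAULT_FS,
) -> list[SessionRecord]:
    """Simulate all 20 sessions, carrying the participant across days.

    Between sessions the momentary regulated state fully relaxes back to
    the trait profile (overnight), while accumulated skill persists —
    what the participant retains is the learned ability to regulate, not
    the regulated state itself.
    """
    rng = np.random.default_rng(seed)
    records = []
    for plan in schedule:
        record = run_session(
            model, plan, seed=int(rng.integers(2**31)), scheme=scheme, fs=fs,
            started_at=float(
                dt.datetime.combine(plan.date, dt.time(9, 0))
                .replace(tzinfo=dt.timezone.utc).timestamp()
            ),
        )
        records.append(record)
        model = record.final_model
        # overnight reset of the momentary state; skill persists
        model = replace(model, band_amplitudes=dict(model.trait_amplitudes))
    return records
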