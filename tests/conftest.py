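"""Shared fixtures: deterministic synthetic signals and one session-scoped
closed-loop Monte Carlo used by the slower end-to-end checks."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from neurofb import (
    EegSegment,
    build_intervention_schedule,
    default_scheme,
    make_pain_profile,
    run_intervention,
)

FS = 250.0


def sinusoid_segment(
    freqs_amps: list[tuple[float, float]],
    duration: float = 2.0,
    fs: float = FS,
    phase: float = 0.3,
) -> EegSegment:
    """Noise-free multi-sinusoid two-channel segment.

    Amplitudes are peak values; a frequency f contributes power A²/2.
    Use bin-centred frequencies (multiples of 1/duration) for exact
    spectral accounting.
    """
    t = np.arange(int(round(duration * fs))) / fs
    x = np.zeros_like(t)
    for f, a in freqs_amps:
        x = x + a * np.sin(2 * np.pi * f * t + phase)
    return EegSegment(channels=("C3", "C4"), fs=fs, data=np.stack([x, x]))


@pytest.fixture
def scheme():
    return default_scheme()


@pytest.fixture
def pain_model():
    return make_pain_profile(seed=1)


@pytest.fixture(scope="session")
def closed_loop_runs():
    """Full 20-session interventions over 20 seeds for a responsive
    (responsiveness 0.5) and a non-responsive participant.

    Expensive (~40 simulated interventions), so computed once per test
    session and shared; returns {responsiveness: (n_seeds, 20) scores}.
    """
    schedule = build_intervention_schedule(dt.date(2025, 1, 6))
    out = {}
    for resp in (0.5, 0.0):
        scores = []
        for seed in range(20):
            model = make_pain_profile(seed, responsiveness=resp)
            records = run_intervention(model, schedule, seed=1000 + seed)
            assert all(r.completed for r in records)
            scores.append([r.total_score for r in records])
        out[resp] = np.asarray(scores)
    return out
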