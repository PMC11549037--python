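# neurofb

A home-based, closed-loop EEG neurofeedback engine for chronic neuropathic
pain, with a synthetic participant simulator for end-to-end testing.

## The problem

Chronic neuropathic pain — for example after spinal cord injury — is
associated with a characteristic shift in the resting EEG over sensorimotor
cortex: **elevated theta (θ, 4–7 Hz) and high-beta (high-β, 20–30 Hz)
power, and reduced power in the sensorimotor rhythm (SMR, 10–15 Hz:
high-alpha 10–12 Hz plus low-beta 13–15 Hz)**. Neurofeedback training
presents a participant's own band power back to them in real time so they
can learn to push it in the healthy direction: suppress θ and high-β,
reinforce SMR, at electrode sites C3 and C4 (ear-clip references).

`neurofb` implements the full computational core of such a home-based
intervention:

* **spectral** — Welch band-power estimation over half-open bands, plus an
  independent full-length-DFT oracle with Parseval normalisation;
* **calibration** — per-session thresholds from a 2-minute resting
  recording: median clean-epoch band power per channel and band;
* **feedback** — the per-second regulation decision
  (θ power < threshold ∧ SMR power > threshold ∧ high-β power < threshold,
  channel-averaged, strict inequalities), an EWMA display level, and
  integer round scores (one point per fully regulated second, shown at
  round end);
* **protocol** — the impedance gate (< 50 kΩ on every electrode), the
  session flow (impedance → resting baseline → 5 × 2.5-min rounds with
  30 s breaks), and the 20-session/4-week schedule with four games
  (jellyfish → bird → plane → rocket, one per block of five sessions);
* **qc** — artifact rejection (peak-to-peak > 200 µV, flatline, clipping)
  and session-quality review;
* **synthsig** — the simulator: band oscillations + 1/f noise + blink
  transients, pain and pain-free spectral profiles, and a "responsive"
  participant whose regulation ability improves with practice, closing the
  loop for testing;
* **io / cli** — CSV and EDF signal files, versioned JSON session logs,
  adherence summaries, and a `neurofb` command-line tool.

There is no claim here about clinical efficacy: the simulator is a test
harness that lets every part of the engine be verified quantitatively
(see `docs/methods.md`).

## Worked example

Simulate a pain-profile participant, calibrate a baseline from its resting
EEG, and run one session:

```bash
$ neurofb simulate --seed 2 --duration 120 --profile pain --out rest.csv
$ neurofb calibrate --resting rest.csv
{
  "band_names": ["theta", "smr", "high_beta"],
  "baseline_power_uv2": [[163.79, 87.02, 52.75], [163.37, 86.37, 49.78]],
  "threshold_uv2":      [[163.79, 87.02, 52.75], [163.37, 86.37, 49.78]],
  "n_epochs_used": 119,
  ...
}
$ neurofb run-session --seed 7 --session 1
{"completed": true, "round_scores": [4, 10, 4, 9, 5], "session_index": 1, "total_score": 32}
```

The baseline is the per-channel, per-band median power (µV²) of the 119
clean 2 s epochs in the recording — here ~164 µV² of theta power at C3 —
and, with the default multiplier 1.0,
is itself the in-game threshold.
In the session, each of the five 150 s rounds scores one point per second
in which all three bands were simultaneously on the trained side of their
thresholds: this simulated participant managed 32 such seconds in session 1.
A responsive participant improves across the 20-session course; the
between-session score slope is what the adherence summary
(`neurofb summarize`) reports.

In Python the same loop is:

```python
import datetime as dt
from neurofb import (build_intervention_schedule, make_pain_profile,
                     run_intervention)

schedule = build_intervention_schedule(dt.date(2025, 1, 6))
model = make_pain_profile(seed=0, responsiveness=0.5)
records = run_intervention(model, schedule, seed=42)
print([r.total_score for r in records])   # rising across sessions
```

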