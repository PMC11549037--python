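# Methods

`neurofb` implements the computational engine of a home-based, self-directed
EEG neurofeedback intervention for chronic neuropathic pain, together with a
synthetic participant simulator that lets the whole closed loop be tested
without hardware or trial data. This note documents the models, the defaults
and why they were chosen, and what the simulator does and does not show.

## The training model

Individuals with chronic neuropathic pain tend to show elevated EEG power in
the theta (4–7 Hz) and high-beta (20–30 Hz) bands and reduced power in the
high-alpha (10–12 Hz) and low-beta (13–15 Hz) bands over sensorimotor cortex.
The training protocol therefore *suppresses* theta and high-beta and
*reinforces* high-alpha plus low-beta, treated as one sensorimotor-rhythm
(SMR, 10–15 Hz) band, at electrode sites C3 and C4 (International 10–20
system) referenced to ear-clips.

The engine treats the three targeted bands as a fixed `BandScheme` of exactly
three non-overlapping `BandDefinition`s, because the decision rule is a
conjunction over all targeted bands. The SMR band is deliberately one
10–15 Hz band rather than two sub-bands: the regulation decision and scoring
operate on three targeted quantities (θ, SMR, high-β).

### Band power

Per-epoch band power (µV²) is the one-sided Welch PSD (Hann window, detrended
by per-epoch mean removal, `scipy.signal.welch` normalisation) integrated
over the half-open interval [f_low, f_high), so adjacent bands never
double-count a frequency bin. Defaults:

| context            | epoch  | window   | overlap |
|--------------------|--------|----------|---------|
| real-time decision | 1 s    | 1 s      | —       |
| baseline / resting | 2 s    | 2 s      | 50 % between epochs |

The baseline epochs use the full 2 s window (0.5 Hz resolution) rather than
averaging two 1 s halves: at 1 Hz resolution the Hann main lobe of an
oscillation near a band edge (e.g. low-beta near 15 Hz) leaks measurably past
the half-open edge and biases the band estimate low; at 0.5 Hz resolution
this leakage is negligible. Averaging across the ~119 epochs of a recording
supplies the variance reduction Welch segment-averaging would otherwise give.

An independent estimator, `dft_band_power_oracle`, computes band power from a
single full-length DFT with Parseval normalisation (per-bin powers over any
partition of [0, fs/2] sum to the mean-square amplitude). On noise-free
sinusoids at bin-centred frequencies the Welch estimate with window = full
segment equals the oracle to better than 10⁻⁶ relative, which is the
cross-check used in the tests; the oracle shares no code with the Welch path.

### Baseline calibration

Each session starts with a two-minute resting recording (fixation cross).
The recording is cut into 2 s epochs at 50 % overlap (119 epochs), epochs
failing QC are rejected, and the per-channel, per-band **median** clean-epoch
power becomes the baseline. The decision threshold is the baseline times a
configurable multiplier, default 1.0: success means crossing one's own
resting median in the trained direction. The median (not the mean) is used
so residual artifacts cannot drag the threshold; injecting artifacts into
20 % of a recording moves the baseline by well under 15 %. Fewer than 10
clean epochs, a wrong montage, a short recording, or degenerate (zero)
thresholds raise `CalibrationError` — in the app flow all of these mean
"re-record". The baseline is per-session (latest-wins policy in
`recalibrate_each_session`), matching an app flow that records a fresh
baseline before every session's games.

### Decision, feedback, scoring

Every second of gameplay, band powers of the latest 1 s epoch are averaged
across C3 and C4 and compared strictly to the channel-averaged thresholds
(ties fail; a `combine="and"` mode requiring each channel to comply
individually is available). A second counts toward the score only when all
three bands are regulated simultaneously. The display level is an EWMA of
the per-second success flag with a 3 s time constant, quantised to five
character-motion steps plus a linear background-colour mix; the integer score
is revealed only at the end of each 2.5-minute round. Under strict
alternation of success and failure the EWMA oscillates between two fixed
points whose mean is exactly 0.5 and whose half-spread is α/2 with
α = 1 − e^(−1/τ).

### Protocol

Twenty sessions over at most 28 days, five per week on weekdays (a weekend
start rolls to Monday); each session is impedance check → 2-minute resting
baseline → 5 × 2.5-minute rounds with 30 s breaks. The impedance gate passes
only when every electrode (C3, C4, both ear-clips) is strictly below
50 kΩ, and on failure reports the failing electrodes so the caller can
surface troubleshooting steps. Four games — jellyfish, bird, plane, rocket —
rotate in that fixed order, one per block of five sessions. The listing
order of the games was adopted as the (unspecified but fixed) rotation
order; weekday placement is a configurable default, since only "20 days over
four weeks" is fixed by the protocol.

## The synthetic participant

`ParticipantModel` generates two-channel EEG as, per channel:

* one sinusoid per band (theta, high-alpha, low-beta, high-beta) with random
  phase, RMS amplitude from the model, and a per-realisation frequency
  jitter of ±10 % around the band's geometric centre, clipped to stay
  0.5 Hz inside the band edges (so a band's power actually lands in the
  band — sinusoids rather than filtered noise were chosen to give exact
  analytic power targets for testing);
* 1/f^α pink noise (FFT-shaped, realisation renormalised to the target RMS),
  default α = 1, scale 20 µV RMS;
* biphasic 0.5 s transients (one sine cycle, peak 5 × background RMS,
  identical on both channels like a blink) at Poisson times, default
  1 event/min.

Defaults put the total signal at ≈ 25 µV RMS — a realistic central-scalp
magnitude — which makes the artifact transients (~250 µV peak-to-peak)
large enough for amplitude QC to flag while clean data passes. The pain
profile multiplies theta and high-beta amplitudes by 1.5 and high-alpha and
low-beta by 0.67 relative to the pain-free reference; the biomarker
literature gives directions, not magnitudes, so these effect sizes are
documented, configurable defaults. Sampling rate defaults to 250 Hz
(typical of the consumer biosensing board family the headset uses); 60 Hz
(twice the highest band edge) is the enforced minimum.

### Closed-loop dynamics

The responsive participant ("responsiveness" r ∈ [0, 1]) is a test harness,
not a claim about human physiology. On each successfully regulated second
its band amplitudes step multiplicatively in the trained direction by
r × 0.02 × (1 + 2 × skill), and a `skill` state consolidates by
r × 2·10⁻⁴ × (1 − skill); on failed seconds the state relaxes toward the
trait profile (2 % per second), during breaks it relaxes with a 60 s time
constant, and between sessions it resets to the trait entirely while skill
persists.

The skill state is the deliberate design choice here. A purely
multiplicative learner cannot show between-session improvement under
per-session median recalibration: band powers and thresholds scale together,
so every session would be statistically identical by scale invariance. What
can improve across sessions is the *ability to move away from one's own
resting state during the games* — modelled as practice (skill) that
amplifies the attainable within-session modulation and survives the
overnight reset. The gain 2·10⁻⁴ per successful second makes skill
accumulate over the whole 20-session course (a few thousand successful
seconds to approach ceiling) rather than saturating in the first days.
With these dynamics a responsiveness-0.5 pain-profile participant roughly
doubles-to-triples its mean session score from sessions 1–5 to 16–20, while
a responsiveness-0 participant shows no trend — the engine-level signature
the adherence dashboard is meant to surface.

Simulated impedance is lognormal (median 20 kΩ, σ = 0.4) with 5 %
high-outlier electrodes; each troubleshooting retry lowers the median by
×0.7, reflecting that re-soaking sponges and adjusting clips genuinely
improves contact, so the failure path is exercised but sessions eventually
proceed.

### What the simulator does not capture

No volume conduction or realistic topography (two independent channels with
a fixed asymmetry ratio); no non-stationarity beyond the learner dynamics
(no drowsiness, no line noise, no electrode drift); artifacts are a single
stereotyped biphasic shape; the learner is memoryless apart from amplitudes
and scalar skill. Passing closed-loop tests therefore demonstrates that the
*engine* — estimation, thresholding, scoring, scheduling — behaves correctly
and detects a learning participant; it says nothing about whether humans
learn under this protocol, which is precisely the question the clinical
trial exists to answer.

## Quality control

Epochs (default 1 s, aligned with the decision grain) are rejected for
peak-to-peak amplitude > 200 µV, RMS < 0.1 µV (flatline), or > 1 % of
samples at the ±400 µV rail (clipping) — conventional scalp-EEG criteria,
checked per channel in that order, first match reported as the reason.
A session summary warns when the pooled clean fraction drops below 0.8 or
rounds are missing.

## Storage and formats

Signals travel as CSV (`time_s,C3_uV,C4_uV`, 8-decimal µV, lossless to
10⁻⁶ µV) or EDF. The EDF codec is a minimal writer/reader for two-channel
µV EEG with integer sampling rate (16-bit samples, 1 s records; a trailing
partial record is edge-padded), validated in the tests against an
independent EDF reader; round-trips are exact to one 16-bit quantisation
step of the physical range. Session logs are versioned JSON with
pseudonymous participant IDs and byte-reproducible serialisation; times are
seconds since session start plus one absolute session timestamp. The
adherence summary reports sessions completed, per-session scores, the
round-1→5 trajectory, and the OLS slope of total score against session
index (reported only from three completed sessions).

## Problem sizes in the test suite

The spectral and calibration checks use 2–120 s synthetic segments and
20-seed Monte Carlo; parameter recovery uses 30 simulated participants with
amplitudes varied ×0.5–2; the closed-loop checks simulate the full
20-session intervention for 20 seeds in each responsiveness condition.
These sizes give comfortable statistical margins for every asserted effect
while keeping the full suite and the acceptance script each within a few
minutes of a single CPU core.
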