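"""Synthetic two-channel EEG: participant models and segment generation.

No deposited recordings exist for this intervention, so the engine is
exercised end-to-end against simulated participants.  A participant is a
small generative model: one random-phase sinusoid per EEG band (theta,
high-alpha, low-beta, high-beta) riding on 1/f^α pink noise, with
Poisson-scheduled blink/movement transients, recorded at C3 and C4.  The
chronic neuropathic-pain profile has elevated theta and high-beta and
reduced high-alpha and low-beta amplitudes relative to a pain-free
reference.  A "responsive" participant adapts its band amplitudes under
feedback so that closed-loop training can be simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BAND_CENTRES",
    "BAND_RANGES",
    "EegSegment",
    "ParticipantModel",
    "make_painfree_profile",
    "make_pain_profile",
    "generate_segment",
    "step_learner",
    "relax_model",
    "expected_band_power",
]

#: Oscillator bands of the generative model (Hz).  high-alpha and low-beta
#: together make up the reinforced sensorimotor rhythm (SMR, 10–15 Hz).
BAND_RANGES: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "high_alpha": (10.0, 12.0),
    "low_beta": (13.0, 15.0),
    "high_beta": (20.0, 30.0),
}

#: Geometric-centre frequency of each oscillator band.
BAND_CENTRES: dict[str, float] = {
    name: math.sqrt(lo * hi) for name, (lo, hi) in BAND_RANGES.items()
}

#: Bands whose amplitude training pushes up (reinforce) / down (suppress).
REINFORCED_BANDS = ("high_alpha", "low_beta")
SUPPRESSED_BANDS = ("theta", "high_beta")

#: Pain-free reference RMS amplitudes (µV) per oscillator band.  Scaled so
#: that, with the default pink noise, total signal RMS is ~25 µV — a
#: realistic scalp EEG magnitude at central sites.
PAINFREE_AMPLITUDES: dict[str, float] = {
    "theta": 8.0,
    "high_alpha": 10.0,
    "low_beta": 8.0,
    "high_beta": 4.0,
}

#: Multipliers applied to the pain-free profile to obtain the neuropathic
#: pain spectral profile: theta and high-beta power elevated, high-alpha
#: and low-beta reduced.  The cited biomarker literature gives directions,
#: not magnitudes; these effect sizes are configurable defaults.
PAIN_UP_FACTOR = 1.5
PAIN_DOWN_FACTOR = 0.67

DEFAULT_FS = 250.0  # Hz; typical for the consumer biosensing board used
MIN_FS = 60.0  # Hz; 2 × highest band edge (30 Hz)

#: Frequency-jitter margin (Hz) kept between a drawn oscillator frequency
#: and its band edges, so spectral leakage stays inside the band.
_EDGE_MARGIN = 0.5
_FREQ_JITTER = 0.10  # ±10 % around the band centre

_ARTIFACT_DURATION = 0.5  # s, biphasic blink/movement transient
_ARTIFACT_RMS_FACTOR = 5.0  # transient peak = 5 × background RMS


@dataclass(frozen=True)
class EegSegment:
    """A fixed-rate two-channel EEG time series in µV."""

    channels: tuple[str, ...]
    fs: float
    data: np.ndarray  # (n_channels, n_samples), µV
    t0: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {data.shape} does not match {len(self.channels)} channels"
            )
        if self.fs < MIN_FS:
            raise ValueError(f"fs={self.fs} Hz below the {MIN_FS} Hz minimum")
        if not np.all(np.isfinite(data)):
            raise ValueError("EEG samples must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def slice(self, start: float, stop: float) -> "EegSegment":
        """Sub-segment between two times (s, relative to segment start)."""
        i0 = int(round(start * self.fs))
        i1 = int(round(stop * self.fs))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError(f"slice [{start}, {stop}) s outside segment")
        return EegSegment(
            channels=self.channels,
            fs=self.fs,
            data=self.data[:, i0:i1],
            t0=self.t0 + i0 / self.fs,
        )


@dataclass(frozen=True)
class ParticipantModel:
    """Generative model of one simulated participant.

    ``band_amplitudes`` is the current per-band oscillator RMS (µV);
    ``trait_amplitudes`` the participant's resting set point, toward which
    the state relaxes between rounds and sessions.  ``responsiveness`` in
    [0, 1] scales how strongly feedback moves the state; ``skill`` in
    [0, 1] is accumulated practice, which widens the modulation the
    participant can sustain and persists across sessions.
    """

    band_amplitudes: dict[str, float]
    pink_noise_scale: float = 20.0  # µV RMS of the 1/f background
    pink_noise_exponent: float = 1.0  # power ∝ 1/f^α
    artifact_rate: float = 1.0  # transients per minute
    responsiveness: float = 0.0
    channel_asymmetry: float = 1.0  # C3 amplitude / C4 amplitude
    seed: int = 0
    trait_amplitudes: dict[str, float] = field(default=None)
    skill: float = 0.0

    def __post_init__(self) -> None:
        for name, amp in self.band_amplitudes.items():
            if name not in BAND_RANGES:
                raise ValueError(f"unknown band {name!r}")
            if amp < 0:
                raise ValueError(f"band {name!r}: amplitude must be ≥ 0")
        if self.pink_noise_scale < 0:
            raise ValueError("pink_noise_scale must be ≥ 0")
        if not 0.5 <= self.pink_noise_exponent <= 2.0:
            raise ValueError("pink_noise_exponent must lie in [0.5, 2]")
        if not 0.0 <= self.responsiveness <= 1.0:
            raise ValueError("responsiveness must lie in [0, 1]")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be ≥ 0")
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError("skill must lie in [0, 1]")
        if self.trait_amplitudes is None:
            object.__setattr__(
                self, "trait_amplitudes", dict(self.band_amplitudes)
            )

    def background_rms(self) -> float:
        """RMS (µV) of the artifact-free signal on the stronger channel."""
        asym = max(self.channel_asymmetry, 1.0)
        osc = sum((a * asym) ** 2 for a in self.band_amplitudes.values())
        return math.sqrt(osc + (self.pink_noise_scale * asym) ** 2)


def make_painfree_profile(seed: int = 0, **overrides) -> ParticipantModel:
    """Reference participant without the neuropathic-pain spectral shift.

    The profile itself is deterministic; ``seed`` is stored and only used
    by downstream segment generation.
    """
    params = dict(
        band_amplitudes=dict(PAINFREE_AMPLITUDES),
        pink_noise_scale=20.0,
        pink_noise_exponent=1.0,
        artifact_rate=1.0,
        responsiveness=0.0,
        channel_asymmetry=1.0,
        seed=seed,
    )
    params.update(overrides)
    return ParticipantModel(**params)


def make_pain_profile(
    seed: int = 0,
    up_factor: float = PAIN_UP_FACTOR,
    down_factor: float = PAIN_DOWN_FACTOR,
    **overrides,
) -> ParticipantModel:
    """Chronic neuropathic-pain spectral profile.

    Theta and high-beta oscillator amplitudes are elevated by
    ``up_factor`` and high-alpha and low-beta reduced by ``down_factor``
    relative to :func:`make_painfree_profile`.  Note the factors act on
    amplitude; band *power* shifts by the squared factor.
    """
    base = make_painfree_profile(seed=seed)
    amps = dict(base.band_amplitudes)
    for b in SUPPRESSED_BANDS:
        amps[b] *= up_factor
    for b in REINFORCED_BANDS:
        amps[b] *= down_factor
    params = dict(
        band_amplitudes=amps,
        pink_noise_scale=base.pink_noise_scale,
        pink_noise_exponent=base.pink_noise_exponent,
        artifact_rate=base.artifact_rate,
        responsiveness=base.responsiveness,
        channel_asymmetry=base.channel_asymmetry,
        seed=seed,
    )
    params.update(overrides)
    return ParticipantModel(**params)


def _pink_noise(
    rng: np.random.Generator, n: int, fs: float, scale: float, alpha: float
) -> np.ndarray:
    """1/f^alpha noise of length n, RMS = scale (in expectation exact:
    the realisation is renormalised to the target RMS)."""
    if scale == 0.0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    nonzero = freqs > 0
    gain[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    spec = gain * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x * (scale / rms) if rms > 0 else x


def _draw_band_frequency(rng: np.random.Generator, band: str) -> float:
    """Oscillator frequency: jittered around the band centre, kept a
    margin away from the band edges so leakage stays in-band."""
    lo, hi = BAND_RANGES[band]
    c = BAND_CENTRES[band]
    f_min = max(lo + _EDGE_MARGIN, c * (1 - _FREQ_JITTER))
    f_max = min(hi - _EDGE_MARGIN, c * (1 + _FREQ_JITTER))
    if f_max <= f_min:
        return c
    return rng.uniform(f_min, f_max)


def generate_segment(
    model: ParticipantModel,
    duration: float,
    fs: float = DEFAULT_FS,
    seed: int | None = None,
    t0: float = 0.0,
) -> EegSegment:
    """Simulate a two-channel (C3, C4) EEG segment.

    Each oscillator band contributes a sinusoid with random phase and a
    per-realisation frequency jitter (±10 % of the band centre, clipped
    inside the band); the 1/f^α background and Poisson-scheduled biphasic
    transients (0.5 s, peak 5 × background RMS) are added per channel.
    The same (model, duration, fs, seed) tuple is bit-reproducible.

    Parameters
    ----------
    model : ParticipantModel
    duration : float
        Segment length in seconds, > 0.
    fs : float
        Sampling rate (Hz), ≥ 60 (2 × the highest band edge).
    seed : int, optional
        Overrides ``model.seed`` for this realisation.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if fs < MIN_FS:
        raise ValueError(
            f"fs={fs} Hz is below Nyquist for the 30 Hz band edge; need ≥ {MIN_FS}"
        )
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    data = np.zeros((2, n))
    chan_gain = (model.channel_asymmetry, 1.0)  # (C3, C4)
    for ch in range(2):
        for band, amp in model.band_amplitudes.items():
            f = _draw_band_frequency(rng, band)
            phase = rng.uniform(0, 2 * np.pi)
            if amp > 0:
                # amp is RMS; sinusoid peak = amp * sqrt(2)
                data[ch] += (
                    amp * chan_gain[ch] * np.sqrt(2.0)
                    * np.sin(2 * np.pi * f * t + phase)
                )
        data[ch] += _pink_noise(
            rng, n, fs,
            model.pink_noise_scale * chan_gain[ch],
            model.pink_noise_exponent,
        )
    _add_artifacts(rng, data, fs, model)
    return EegSegment(channels=("C3", "C4"), fs=fs, data=data, t0=t0)


def _add_artifacts(
    rng: np.random.Generator, data: np.ndarray, fs: float, model: ParticipantModel
) -> None:
    """Inject biphasic blink/movement transients at Poisson times.

    One full sine cycle over 0.5 s, identical on both channels (blinks
    project symmetrically to C3/C4), peak 5 × background RMS — so the
    peak-to-peak excursion is large enough for amplitude QC to flag.
    """
    n = data.shape[-1]
    duration_min = n / fs / 60.0
    n_events = rng.poisson(model.artifact_rate * duration_min)
    if n_events == 0:
        return
    peak = _ARTIFACT_RMS_FACTOR * model.background_rms()
    width = int(round(_ARTIFACT_DURATION * fs))
    shape = peak * np.sin(2 * np.pi * np.arange(width) / width)
    starts = rng.integers(0, max(n - width, 1), size=n_events)
    for s in np.sort(starts):
        seg = min(width, n - s)
        data[:, s : s + seg] += shape[:seg]


# --- closed-loop participant dynamics -------------------------------------

#: Multiplicative per-epoch amplitude step on a successfully regulated epoch.
LEARN_STEP = 0.02
#: Fractional relaxation toward the trait set point on a failed epoch.
RELAX_STEP = 0.02
#: Skill consolidation per successful epoch (saturating toward 1).  Sized
#: so that practice accumulates over the whole 20-session course rather
#: than saturating in the first days (a few thousand successful epochs to
#: approach ceiling).
SKILL_GAIN = 2e-4
#: How strongly accumulated skill amplifies the per-epoch step.
SKILL_BOOST = 2.0


def step_learner(
    model: ParticipantModel,
    decision,
    step_size: float = LEARN_STEP,
) -> ParticipantModel:
    """Advance the simulated participant by one feedback epoch.

    On a successfully regulated epoch (``decision.all_regulated``) the
    reinforced bands (high-alpha, low-beta) step up and the suppressed
    bands (theta, high-beta) step down multiplicatively by
    ``responsiveness × step_size × (1 + SKILL_BOOST × skill)``, and skill
    consolidates.  Otherwise the state relaxes toward the trait profile.
    Amplitudes are clipped to ≥ 0; a responsiveness-0 participant never
    changes.
    """
    r = model.responsiveness
    if r == 0.0:
        return model
    amps = dict(model.band_amplitudes)
    if getattr(decision, "all_regulated", False):
        step = r * step_size * (1.0 + SKILL_BOOST * model.skill)
        for b in REINFORCED_BANDS:
            amps[b] = max(amps[b] * (1.0 + step), 0.0)
        for b in SUPPRESSED_BANDS:
            amps[b] = max(amps[b] * (1.0 - step), 0.0)
        skill = model.skill + r * SKILL_GAIN * (1.0 - model.skill)
    else:
        for b in amps:
            amps[b] += r * RELAX_STEP * (model.trait_amplitudes[b] - amps[b])
            amps[b] = max(amps[b], 0.0)
        skill = model.skill
    return replace(model, band_amplitudes=amps, skill=min(skill, 1.0))


def relax_model(
    model: ParticipantModel, duration: float, tau: float = 60.0
) -> ParticipantModel:
    """Relax the participant's state toward the trait profile.

    Used for the 30 s between-round breaks (exponential relaxation with
    time constant ``tau`` seconds) and, with large ``duration``, for the
    overnight reset between sessions.  Skill is retained — practice
    persists, the momentary regulated state does not.
    """
    if duration < 0:
        raise ValueError("duration must be ≥ 0")
    keep = math.exp(-duration / tau)
    amps = {
        b: model.trait_amplitudes[b]
        + (model.band_amplitudes[b] - model.trait_amplitudes[b]) * keep
        for b in model.band_amplitudes
    }
    return replace(model, band_amplitudes=amps)


def expected_band_power(
    model: ParticipantModel,
    f_low: float,
    f_high: float,
    fs: float = DEFAULT_FS,
    channel: str = "C4",
) -> float:
    """Analytic expected power (µV²) in [f_low, f_high) for a model.

    Oscillator sinusoids contribute their full RMS² when their band lies
    inside the query band; the pink-noise contribution is the 1/f^α
    spectral mass of the band relative to the whole 0–fs/2 axis.  Used as
    generative ground truth in calibration-recovery checks.
    """
    gain = model.channel_asymmetry if channel == "C3" else 1.0
    power = 0.0
    for band, amp in model.band_amplitudes.items():
        lo, hi = BAND_RANGES[band]
        c = BAND_CENTRES[band]
        f_min = max(lo + _EDGE_MARGIN, c * (1 - _FREQ_JITTER))
        f_max = min(hi - _EDGE_MARGIN, c * (1 + _FREQ_JITTER))
        # fraction of the uniform frequency draw that lands in the query band
        if f_max > f_min:
            frac = np.clip(
                (min(f_max, f_high) - max(f_min, f_low)) / (f_max - f_min), 0, 1
            )
        else:
            frac = 1.0 if f_low <= c < f_high else 0.0
        power += frac * (amp * gain) ** 2
    if model.pink_noise_scale > 0:
        # spectral mass of f^-alpha between the band edges, relative to the
        # full axis; evaluated on a fine grid to mirror the DFT shaping
        freqs = np.linspace(0, fs / 2, 4097)[1:]
        dens = freqs ** (-model.pink_noise_exponent)
        mask = (freqs >= f_low) & (freqs < f_high)
        power += (model.pink_noise_scale * gain) ** 2 * dens[mask].sum() / dens.sum()
    return power
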