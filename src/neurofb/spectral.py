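"""Band-power estimation for short EEG epochs.

The regulation decision and the resting-state summaries both reduce an EEG
epoch to one power value (µV²) per frequency band per channel.  Powers are
estimated with a Welch-averaged Hann periodogram and integrated over
half-open bands [f_low, f_high), so adjacent literature bands never
double-count a frequency bin.  A direct full-length DFT estimator with a
Parseval normalisation is provided as an independent oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "BandScheme",
    "BandPowerVector",
    "default_scheme",
    "welch_band_powers",
    "dft_band_power_oracle",
    "resting_spectrum_report",
    "TOTAL_POWER_BAND",
]

#: Frequency range (Hz) over which "total" power is integrated for
#: relative-power summaries.  Below 0.5 Hz is drift; above 45 Hz is
#: dominated by line noise and EMG on a consumer headset.
TOTAL_POWER_BAND = (0.5, 45.0)


@dataclass(frozen=True)
class BandDefinition:
    """One targeted frequency band and its training direction.

    ``direction`` is ``"suppress"`` (success means in-game power below the
    resting threshold) or ``"reinforce"`` (success means power above it).
    """

    name: str
    f_low: float
    f_high: float
    direction: str

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )
        if self.direction not in ("suppress", "reinforce"):
            raise ValueError(
                f"band {self.name!r}: direction must be 'suppress' or "
                f"'reinforce', got {self.direction!r}"
            )


@dataclass(frozen=True)
class BandScheme:
    """The three targeted bands of the neurofeedback protocol.

    The decision rule is a conjunction over all targeted bands, so the
    scheme is fixed at exactly three non-overlapping bands: theta
    (4–7 Hz, suppress), SMR (10–15 Hz, reinforce — high-alpha 10–12 Hz
    plus low-beta 13–15 Hz over sensorimotor cortex) and high-beta
    (20–30 Hz, suppress).
    """

    bands: tuple[BandDefinition, ...]

    def __post_init__(self) -> None:
        if len(self.bands) != 3:
            raise ValueError(
                f"a band scheme has exactly three targeted bands, got {len(self.bands)}"
            )
        ordered = sorted(self.bands, key=lambda b: b.f_low)
        for lo, hi in zip(ordered, ordered[1:]):
            if hi.f_low < lo.f_high:
                raise ValueError(
                    f"bands {lo.name!r} and {hi.name!r} overlap"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def __iter__(self):
        return iter(self.bands)

    def max_frequency(self) -> float:
        return max(b.f_high for b in self.bands)


def default_scheme() -> BandScheme:
    """Theta suppress, SMR reinforce, high-beta suppress."""
    return BandScheme(
        bands=(
            BandDefinition("theta", 4.0, 7.0, "suppress"),
            BandDefinition("smr", 10.0, 15.0, "reinforce"),
            BandDefinition("high_beta", 20.0, 30.0, "suppress"),
        )
    )


@dataclass
class BandPowerVector:
    """Per-channel, per-band power (µV²) for one analysis epoch."""

    channels: tuple[str, ...]
    band_names: tuple[str, ...]
    powers: np.ndarray  # shape (n_channels, n_bands), µV²
    t0: float  # epoch start, seconds
    duration: float  # epoch length, seconds

    def __post_init__(self) -> None:
        self.powers = np.asarray(self.powers, dtype=float)
        if self.powers.shape != (len(self.channels), len(self.band_names)):
            raise ValueError(
                f"powers shape {self.powers.shape} does not match "
                f"{len(self.channels)} channels × {len(self.band_names)} bands"
            )
        if not np.all(np.isfinite(self.powers)) or np.any(self.powers < 0):
            raise ValueError("band powers must be finite and non-negative")

    def band(self, name: str) -> np.ndarray:
        """Power in one band, per channel."""
        return self.powers[:, self.band_names.index(name)]

    def channel_mean(self) -> np.ndarray:
        """Band powers averaged across channels."""
        return self.powers.mean(axis=0)


def _band_slice(freqs: np.ndarray, f_low: float, f_high: float) -> np.ndarray:
    # half-open [f_low, f_high)
    return (freqs >= f_low) & (freqs < f_high)


_HANN_CACHE: dict[int, tuple[np.ndarray, float]] = {}


def _hann_periodogram(data: np.ndarray, fs: float):
    """One-segment Hann PSD, density scaling, mean removed (= scipy Welch
    with nperseg equal to the signal length)."""
    n = data.shape[-1]
    if n not in _HANN_CACHE:
        w = sps.get_window("hann", n)
        _HANN_CACHE[n] = (w, float((w**2).sum()))
    w, wss = _HANN_CACHE[n]
    x = data - data.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x * w, axis=-1)
    psd = (np.abs(spec) ** 2) / (fs * wss)
    psd[..., 1:] *= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def welch_band_powers(
    segment,
    scheme: BandScheme,
    window: float = 1.0,
    overlap: float = 0.5,
) -> BandPowerVector:
    """Welch-averaged band powers for one epoch.

    The per-epoch mean is removed (hardware DC offset is not neural
    signal), a Hann window of ``window`` seconds with fractional
    ``overlap`` is applied, and the one-sided PSD is integrated over each
    band's half-open interval.  With ``window`` equal to the full segment
    length this reduces to a single Hann periodogram and matches
    :func:`dft_band_power_oracle` on noise-free bin-centred sinusoids.

    Parameters
    ----------
    segment : EegSegment
        Two-channel epoch, at least ``window`` seconds long.
    scheme : BandScheme
        The three targeted bands.
    window, overlap
        Welch segment length (s) and fractional overlap in [0, 1).

    Returns
    -------
    BandPowerVector
        Power in µV² per channel per band.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    fs = segment.fs
    nperseg = int(round(window * fs))
    n = segment.n_samples
    if n < nperseg:
        raise ValueError(
            f"segment of {n / fs:.3f} s is shorter than the {window:.3f} s "
            f"analysis window; need at least {nperseg} samples at fs={fs} Hz"
        )
    if scheme.max_frequency() > fs / 2:
        raise ValueError(
            f"band scheme extends to {scheme.max_frequency()} Hz, above "
            f"Nyquist {fs / 2} Hz"
        )
    noverlap = int(round(overlap * nperseg))
    if nperseg == n:
        # single-window case: one Hann periodogram, same normalisation as
        # scipy's Welch but without its slicing machinery (hot path of the
        # per-second decision loop)
        freqs, psd = _hann_periodogram(segment.data, fs)
    else:
        freqs, psd = sps.welch(
            segment.data,
            fs=fs,
            window="hann",
            nperseg=nperseg,
            noverlap=noverlap,
            detrend="constant",
            scaling="density",
            axis=-1,
        )
    df = freqs[1] - freqs[0]
    powers = np.empty((segment.n_channels, len(scheme.bands)))
    for j, band in enumerate(scheme):
        mask = _band_slice(freqs, band.f_low, band.f_high)
        powers[:, j] = psd[:, mask].sum(axis=-1) * df
    return BandPowerVector(
        channels=segment.channels,
        band_names=scheme.names,
        powers=powers,
        t0=segment.t0,
        duration=n / fs,
    )


def dft_band_power_oracle(segment, band: BandDefinition) -> np.ndarray:
    """Band power per channel from a single full-length DFT.

    Normalised so that summing the per-bin powers over any partition of
    [0, fs/2] equals the mean-square amplitude of the (mean-removed)
    signal — the Parseval identity.  Used as the independent reference
    for the Welch estimator.
    """
    x = segment.data - segment.data.mean(axis=-1, keepdims=True)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / segment.fs)
    # one-sided per-bin power with Parseval normalisation
    binpow = (np.abs(spec) ** 2) / n**2
    scale = np.full(freqs.shape, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    binpow = binpow * scale
    mask = _band_slice(freqs, band.f_low, band.f_high)
    return binpow[:, mask].sum(axis=-1)


@dataclass
class RestingSpectrumReport:
    """Median per-band absolute and relative power of a resting recording."""

    channels: tuple[str, ...]
    band_names: tuple[str, ...]
    absolute: np.ndarray  # (n_channels, n_bands) µV²
    relative: np.ndarray  # (n_channels, n_bands), band / total(0.5–45 Hz)
    total: np.ndarray = field(default=None)  # (n_channels,) µV²
    n_epochs_used: int = 0
    n_epochs_total: int = 0


def resting_spectrum_report(
    segment,
    scheme: BandScheme,
    epoch: float = 2.0,
    overlap: float = 0.5,
    min_clean_epochs: int = 10,
) -> RestingSpectrumReport:
    """Artifact-rejected band-power summary of a resting recording.

    The recording is cut into ``epoch``-second windows with fractional
    ``overlap``; artifact epochs are rejected (amplitude / flatline /
    clipping rules from :mod:`neurofb.qc`); clean-epoch band powers are
    aggregated by median.  Relative power is band power divided by total
    0.5–45 Hz power of the same epoch, aggregated the same way.
    """
    from . import qc  # local import: qc depends on segment type only

    if segment.duration < 60.0:
        raise ValueError(
            f"resting summaries need ≥ 60 s of data, got {segment.duration:.1f} s"
        )
    total_band = BandDefinition("total", *TOTAL_POWER_BAND, direction="suppress")
    step = epoch * (1 - overlap)
    starts = np.arange(0.0, segment.duration - epoch + 1e-9, step)
    abs_pows, rel_pows, tot_pows = [], [], []
    n_total = 0
    for s in starts:
        ep = segment.slice(s, s + epoch)
        n_total += 1
        if not qc.epoch_is_clean(ep.data):
            continue
        bp = welch_band_powers(ep, scheme, window=epoch, overlap=0.0)
        freqs_pow = bp.powers
        tot = _welch_total_power(ep, total_band)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(tot[:, None] > 0, freqs_pow / tot[:, None], 0.0)
        abs_pows.append(freqs_pow)
        rel_pows.append(rel)
        tot_pows.append(tot)
    if len(abs_pows) < min_clean_epochs:
        raise ValueError(
            f"only {len(abs_pows)} clean epochs (need ≥ {min_clean_epochs}); "
            "re-record the resting baseline"
        )
    return RestingSpectrumReport(
        channels=segment.channels,
        band_names=scheme.names,
        absolute=np.median(np.stack(abs_pows), axis=0),
        relative=np.median(np.stack(rel_pows), axis=0),
        total=np.median(np.stack(tot_pows), axis=0),
        n_epochs_used=len(abs_pows),
        n_epochs_total=n_total,
    )


def _welch_total_power(segment, band: BandDefinition) -> np.ndarray:
    freqs, psd = sps.welch(
        segment.data,
        fs=segment.fs,
        window="hann",
        nperseg=int(round(1.0 * segment.fs)),
        noverlap=int(round(0.5 * segment.fs)),
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    df = freqs[1] - freqs[0]
    mask = _band_slice(freqs, band.f_low, band.f_high)
    return psd[:, mask].sum(axis=-1) * df
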