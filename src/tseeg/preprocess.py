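"""Resampling, cropping, FIR rhythm extraction, and z-score normalisation.

An :class:`EEGTrial` is the unit the pipeline transforms: a channels-by-samples
matrix with a sampling rate and (subject, session, trial, label) metadata.
The canonical preprocessing order is resample -> crop -> band-pass filter ->
z-score, applied per rhythm by :func:`extract_bands`.

Rhythm extraction uses linear-phase FIR band-pass filters (Hamming window,
2 Hz transition band by default) applied forward and backward so the net
phase response is zero; phase distortion would otherwise skew the window-local
amplitude distributions the entropy features are built on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class EEGTrial:
    """One trial of multichannel EEG: data in microvolts, channels x samples."""

    data: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    subject: str = ""
    session: str = ""
    trial: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("trial data must be a 2-D channels x samples matrix")
        if data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{data.shape[0]} data rows but {len(self.channel_labels)} channel labels"
            )
        if data.shape[1] < 1:
            raise ValueError("trial must contain at least one sample")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(data)):
            raise ValueError("trial data contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band; ``low_hz = 0`` means a plain low-pass."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges {self.low_hz}-{self.high_hz} Hz")


#: The rhythms analysed: theta, alpha, beta, gamma plus the full 0-75 Hz range.
#: The delta band is deliberately absent (sleep-related, not analysed here).
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 15.0),
    BandSpec("beta", 16.0, 31.0),
    BandSpec("gamma", 32.0, 55.0),
    BandSpec("full", 0.0, 75.0),
)

TARGET_RATE = 200.0
CROP_SECONDS = 60.0
#: Widest allowed FIR transition band; narrow rhythms get bandwidth/8 instead
#: so the transition skirts stay small relative to the passband.
MAX_TRANSITION_HZ = 2.0


@dataclass(frozen=True)
class ZScoreParams:
    """Per-channel sample mean and sample (n-1) standard deviation."""

    mean: np.ndarray
    std: np.ndarray


@dataclass(frozen=True)
class FilterSpec:
    """A designed FIR band-pass: symmetric taps plus design metadata."""

    band: BandSpec
    coefficients: np.ndarray
    rate: float
    order: int
    window: str
    transition_hz: float


def resample(trial: EEGTrial, target_rate: float) -> EEGTrial:
    """Downsample to ``target_rate`` with polyphase anti-alias filtering.

    Upsampling is refused: the pipeline only ever reduces rate (e.g. to the
    200 Hz working rate), and silently inventing samples would be a bug.
    """
    if target_rate > trial.rate:
        raise ValueError(
            f"cannot upsample from {trial.rate} Hz to {target_rate} Hz"
        )
    if target_rate == trial.rate:
        return trial
    ratio = Fraction(target_rate).limit_denominator(10**6) / Fraction(
        trial.rate
    ).limit_denominator(10**6)
    out = signal.resample_poly(trial.data, ratio.numerator, ratio.denominator, axis=1)
    return replace(trial, data=out, rate=float(target_rate))


def crop_middle(trial: EEGTrial, duration_s: float) -> EEGTrial:
    """Extract the centred ``duration_s`` window of the trial.

    The output holds ``round(duration_s * rate)`` samples starting at index
    ``(n_samples - out_len) // 2`` (0-based, half-open interval).
    """
    out_len = int(round(duration_s * trial.rate))
    if out_len > trial.n_samples:
        raise ValueError(
            f"cannot crop {duration_s} s from a {trial.duration_s:.3f} s trial"
        )
    start = (trial.n_samples - out_len) // 2
    return replace(trial, data=trial.data[:, start : start + out_len])


def design_bandpass(
    band: BandSpec,
    rate: float,
    transition_hz: float | None = None,
    window: str = "hamming",
) -> FilterSpec:
    """Design a linear-phase FIR band-pass (low-pass when ``low_hz`` is 0).

    The transition width defaults to one eighth of the bandwidth, capped at
    ``MAX_TRANSITION_HZ`` — constant fractional bandwidth, so narrow rhythms
    (theta spans only 3 Hz) keep their transition skirts proportionally small.
    Cutoffs are pushed half a transition band outward so the passband plateau
    reaches the nominal edges and the stopband floor sits ``transition_hz``
    beyond them; a Hamming window gives > 50 dB stopband attenuation there.
    """
    nyq = rate / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band {band.name}: high edge {band.high_hz} Hz >= Nyquist {nyq} Hz"
        )
    if transition_hz is None:
        transition_hz = min(MAX_TRANSITION_HZ, (band.high_hz - band.low_hz) / 8.0)
    # Hamming main-lobe rule: transition width ~ 3.3 / numtaps (normalised).
    numtaps = int(np.ceil(3.3 * rate / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> type-I linear phase
    half = transition_hz / 2.0
    lo = band.low_hz - half
    hi = band.high_hz + half
    if lo <= 0:
        taps = signal.firwin(numtaps, hi, window=window, fs=rate, pass_zero=True)
    else:
        taps = signal.firwin(
            numtaps, [lo, hi], window=window, fs=rate, pass_zero=False
        )
    return FilterSpec(
        band=band,
        coefficients=taps,
        rate=float(rate),
        order=numtaps - 1,
        window=window,
        transition_hz=float(transition_hz),
    )


def _filtfilt_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Zero-phase forward-backward FIR filtering along the last axis.

    Matches ``scipy.signal.filtfilt(taps, 1, x, padlen=len(taps))``
    (odd-reflection padding of one filter length, which fully covers an FIR
    transient) but runs the two passes as FFT convolutions, which is much
    faster for the long filters used here.
    """
    n = x.shape[-1]
    ntaps = taps.size
    padlen = ntaps
    if n <= padlen:
        raise ValueError(
            f"signal of {n} samples too short for filter order {ntaps - 1}"
        )
    left = 2 * x[..., :1] - x[..., padlen:0:-1]
    right = 2 * x[..., -1:] - x[..., -2 : -padlen - 2 : -1]
    xp = np.concatenate([left, x, right], axis=-1)
    m = xp.shape[-1]
    fwd = signal.fftconvolve(xp, taps[np.newaxis, :], mode="full", axes=-1)[..., :m]
    bwd = signal.fftconvolve(
        fwd[..., ::-1], taps[np.newaxis, :], mode="full", axes=-1
    )[..., :m][..., ::-1]
    return bwd[..., padlen : padlen + n]


def apply_filter(trial: EEGTrial, spec: FilterSpec) -> EEGTrial:
    """Filter every channel with zero net phase; output length = input length."""
    if trial.rate != spec.rate:
        raise ValueError(
            f"trial rate {trial.rate} Hz does not match filter design rate {spec.rate} Hz"
        )
    out = _filtfilt_fir(trial.data, np.asarray(spec.coefficients, dtype=float))
    return replace(trial, data=out)


def zscore(trial: EEGTrial, ddof: int = 1) -> tuple[EEGTrial, ZScoreParams]:
    """Standardise each channel to zero mean and unit sample standard deviation.

    Z = (Y - mean(Y)) / std(Y), computed per channel with the n-1 denominator.
    A constant channel has no scale and is rejected by name.
    """
    mean = trial.data.mean(axis=1)
    std = trial.data.std(axis=1, ddof=ddof)
    dead = np.flatnonzero(std == 0)
    if dead.size:
        names = [trial.channel_labels[i] for i in dead]
        raise ValueError(f"constant channel(s) cannot be z-scored: {names}")
    out = (trial.data - mean[:, None]) / std[:, None]
    return replace(trial, data=out), ZScoreParams(mean=mean, std=std)


def extract_bands(
    trial: EEGTrial,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    target_rate: float | None = TARGET_RATE,
    crop_seconds: float | None = CROP_SECONDS,
    transition_hz: float | None = None,
    normalize: bool = True,
) -> dict[str, EEGTrial]:
    """Run the full preprocessing chain and split a trial into rhythms.

    Order: resample -> centre crop -> band-pass -> per-channel z-score, the
    filter and normalisation applied independently per band. ``target_rate``
    or ``crop_seconds`` set to None skip those stages (for inputs already at
    the working rate/length).
    """
    if target_rate is not None and target_rate < trial.rate:
        trial = resample(trial, target_rate)
    if crop_seconds is not None and crop_seconds * trial.rate < trial.n_samples:
        trial = crop_middle(trial, crop_seconds)
    out: dict[str, EEGTrial] = {}
    for band in bands:
        spec = design_bandpass(band, trial.rate, transition_hz=transition_hz)
        filtered = apply_filter(trial, spec)
        if normalize:
            filtered, _ = zscore(filtered)
        out[band.name] = filtered
    return out
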