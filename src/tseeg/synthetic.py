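"""SEED-shaped synthetic EEG with plantable class-discriminative complexity.

Real SEED recordings (62 channels, 200 Hz, one-minute emotion trials) are
access-gated, so the pipeline is exercised on surrogates built to the same
shape. Each class is a :class:`ClassProfile` whose *complexity* parameter
``c`` mixes, inside one frequency band, a deterministic tone mixture (low
amplitude-distribution entropy) with band-limited Gaussian noise (high
entropy):

    channel = background_noise + gain_ch * [(1 - c) * tones + c * band_noise]

Both components are normalised to unit standard deviation before mixing, so
the class difference is planted in *complexity*, not raw power — deliberate,
because per-band z-scoring erases power differences and the entropy features
are exactly what should detect the remainder. Channels with zero gain carry
only the shared background and are identical in distribution across classes.

Inter-subject variability is emulated by per-subject gain jitter and a
per-subject spectral tilt of the background noise, both sub-seeded from the
master seed so generation is a pure function of (profiles, counts, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import windows

from .montage import load_montage
from .preprocess import BandSpec, EEGTrial, design_bandpass, _filtfilt_fir

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass(frozen=True)
class ClassProfile:
    """Generation recipe for one class.

    band           (low, high) Hz where the class structure lives
    complexity     c in [0, 1]: 0 = pure tones (orderly), 1 = pure band noise
    channel_gains  label -> gain of the structured component; unlisted
                   channels get ``default_gain``
    tone_freqs     in-band tone frequencies (Hz) of the deterministic part
    background_scale  std of the shared broadband noise floor
    """

    label: str
    band: tuple[float, float] = (32.0, 55.0)
    complexity: float = 0.5
    channel_gains: Mapping[str, float] = field(default_factory=dict)
    default_gain: float = 0.0
    tone_freqs: tuple[float, ...] = (40.0,)
    background_scale: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.complexity <= 1:
            raise ValueError("complexity must lie in [0, 1]")
        if any(g < 0 for g in self.channel_gains.values()) or self.default_gain < 0:
            raise ValueError("channel gains must be nonnegative")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"invalid profile band {self.band}")
        if self.background_scale < 0:
            raise ValueError("background scale must be nonnegative")

    def gain(self, channel: str) -> float:
        return float(self.channel_gains.get(channel, self.default_gain))


@dataclass
class SyntheticDataset:
    trials: list[EEGTrial]
    manifest: dict


def _unit_std(x: np.ndarray) -> np.ndarray:
    s = x.std(axis=-1, keepdims=True)
    return x / np.where(s == 0, 1.0, s)


def _tilted_noise(rng: np.random.Generator, shape: tuple[int, int], tilt: float) -> np.ndarray:
    """Gaussian noise with spectrum scaled by f^(-tilt/2) (0 = white)."""
    white = rng.standard_normal(shape)
    if tilt == 0:
        return white
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    shape_f = np.ones_like(f)
    shape_f[1:] = f[1:] ** (-tilt / 2.0)
    return _unit_std(np.fft.irfft(spec * shape_f, n=shape[-1], axis=-1))


def generate_trial(
    profile: ClassProfile,
    channels: int | Sequence[str],
    rate: float,
    duration_s: float,
    seed: int,
    noise_tilt: float = 0.0,
    gain_scale: float = 1.0,
    edge_ramp_s: float = 2.0,
    subject: str = "",
    session: str = "1",
    trial: str = "",
) -> EEGTrial:
    """One synthetic trial; deterministic given the seed.

    ``channels`` is a channel count (62 selects the bundled SEED montage,
    other counts get generic labels) or an explicit label sequence.

    The structured component ramps on and off over ``edge_ramp_s`` seconds
    (raised-cosine taper), like a stimulus onset/offset. Without the taper a
    narrowband component ends abruptly at the trial boundary and zero-phase
    filtering smears a broadband edge transient into every band — a boundary
    artifact, not class structure, so the generator excludes it by design.
    """
    if isinstance(channels, int):
        labels = (
            load_montage().channel_labels
            if channels == 62
            else tuple(f"CH{i + 1}" for i in range(channels))
        )
    else:
        labels = tuple(channels)
    n = int(round(duration_s * rate))
    if n < 1:
        raise ValueError("duration * rate must be at least one sample")
    rng = np.random.default_rng(seed)
    n_ch = len(labels)

    x = profile.background_scale * _tilted_noise(rng, (n_ch, n), noise_tilt)

    gains = gain_scale * np.array([profile.gain(ch) for ch in labels])
    active = np.flatnonzero(gains > 0)
    if active.size:
        t = np.arange(n) / rate
        phases = rng.uniform(0, 2 * np.pi, size=(active.size, len(profile.tone_freqs)))
        tones = np.zeros((active.size, n))
        for j, f0 in enumerate(profile.tone_freqs):
            tones += np.sin(2 * np.pi * f0 * t[None, :] + phases[:, j : j + 1])
        tones = _unit_std(tones)
        spec = design_bandpass(BandSpec("component", *profile.band), rate)
        raw = rng.standard_normal((active.size, n))
        band_noise = _unit_std(_filtfilt_fir(raw, spec.coefficients))
        c = profile.complexity
        component = (1.0 - c) * tones + c * band_noise
        if edge_ramp_s > 0:
            alpha = min(1.0, 2.0 * edge_ramp_s * rate / n)
            component *= windows.tukey(n, alpha=alpha)[None, :]
        x[active] += gains[active, None] * component

    return EEGTrial(
        data=x,
        rate=float(rate),
        channel_labels=labels,
        subject=subject,
        session=session,
        trial=trial,
        label=profile.label,
    )


def generate_dataset(
    profiles: tuple[ClassProfile, ClassProfile],
    n_subjects: int,
    trials_per_class: int,
    rate: float = 200.0,
    duration_s: float = 60.0,
    seed: int = 0,
    channels: int | Sequence[str] = 62,
    subject_gain_jitter: float = 0.15,
    subject_tilt_range: float = 0.4,
) -> SyntheticDataset:
    """A balanced two-class dataset of n_subjects x 2 x trials_per_class trials.

    Each subject gets a sub-seeded gain multiplier (lognormal, sigma =
    ``subject_gain_jitter``) and background spectral tilt (uniform in
    +/- ``subject_tilt_range``), emulating inter-subject variability.
    """
    if profiles[0].label == profiles[1].label:
        raise ValueError("class profiles must carry distinct labels")
    if trials_per_class < 1 or n_subjects < 1:
        raise ValueError("need at least one subject and one trial per class")
    master = np.random.default_rng(seed)
    trials: list[EEGTrial] = []
    for s in range(1, n_subjects + 1):
        gain_scale = float(np.exp(master.normal(0.0, subject_gain_jitter)))
        tilt = float(master.uniform(-subject_tilt_range, subject_tilt_range))
        for profile in profiles:
            for t in range(1, trials_per_class + 1):
                trial_seed = int(master.integers(0, 2**31))
                trials.append(
                    generate_trial(
                        profile,
                        channels,
                        rate,
                        duration_s,
                        seed=trial_seed,
                        noise_tilt=tilt,
                        gain_scale=gain_scale,
                        subject=f"S{s:02d}",
                        trial=f"{profile.label}-{t:02d}",
                    )
                )
    manifest = {
        "n_subjects": n_subjects,
        "trials_per_class": trials_per_class,
        "rate": rate,
        "duration_s": duration_s,
        "seed": seed,
        "subject_gain_jitter": subject_gain_jitter,
        "subject_tilt_range": subject_tilt_range,
        "profiles": [asdict(p) | {"channel_gains": dict(p.channel_gains)} for p in profiles],
    }
    return SyntheticDataset(trials=trials, manifest=manifest)


#: Channels that carry the planted class difference in the canonical fixtures.
PLANTED_CHANNELS = ("FT7", "FT8", "T7", "T8")


def gamma_discriminative_profiles(
    gap: float = 0.9,
    gain: float = 3.0,
    channels: Sequence[str] = PLANTED_CHANNELS,
) -> tuple[ClassProfile, ClassProfile]:
    """The canonical test pair: classes differing only in gamma-band complexity.

    The positive class is fully orderly (c = 0, a pure gamma tone) and the
    negative class mixes in band noise at c = ``gap`` on the planted channels;
    everything else is shared background. Anchoring one class at c = 0 keeps
    the planted separation a monotone function of ``gap``: the window-local
    amplitude-histogram entropy is steepest near the pure tone and folds back
    for mid-range mixtures, so a pair symmetric around c = 0.5 would not grow
    apart as the gap widens.
    """
    if not 0 <= gap <= 1:
        raise ValueError("gap must lie in [0, 1]")
    gains = {ch: gain for ch in channels}
    return (
        ClassProfile(label=POSITIVE, complexity=0.0, channel_gains=gains),
        ClassProfile(label=NEGATIVE, complexity=gap, channel_gains=gains),
    )


def null_profiles(gain: float = 3.0, channels: Sequence[str] = PLANTED_CHANNELS) -> tuple[ClassProfile, ClassProfile]:
    """Identical generation recipes under different labels: no signal by design."""
    gains = {ch: gain for ch in channels}
    common = dict(complexity=0.5, channel_gains=gains)
    return (
        ClassProfile(label=POSITIVE, **common),
        ClassProfile(label=NEGATIVE, **common),
    )


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write the dataset as delimited matrices plus a JSON manifest.

    One CSV per trial (rows = channels), one ``manifest.json`` naming every
    trial's file and metadata; the layout round-trips through
    :func:`tseeg.io.load_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(dataset.trials):
        fname = f"trial_{i:04d}.csv"
        np.savetxt(directory / fname, tr.data, delimiter=",")
        entries.append(
            {
                "file": fname,
                "subject": tr.subject,
                "session": tr.session,
                "trial": tr.trial,
                "label": tr.label,
                "rate": tr.rate,
                "channels": list(tr.channel_labels),
            }
        )
    manifest = {"generation": dataset.manifest, "trials": entries}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
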