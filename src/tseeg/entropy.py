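"""Sliding-window Tsallis entropy of amplitude distributions.

The feature under study is the nonextensive (Tsallis) entropy of a signal's
window-local amplitude distribution:

    E_ts(q) = (1 - sum_i P_i ** q) / (q - 1),        q > 0, q != 1,

which reduces to Shannon's  E_sh = -sum_i P_i ln P_i  as q -> 1 and obeys the
pseudo-additivity rule  E(X u Y) = E(X) + E(Y) + (1 - q) E(X) E(Y)  for
independent subsystems. For q > 1 the statistic is subextensive, the regime
usually argued for EEG given long-range neuronal correlations.

Probabilities are estimated per sliding window as an equal-width amplitude
histogram over the window's own [min, max] range, P_i = count_i / w. A window
of width ``w`` samples slides in steps of ``delta <= w``; the per-window
entropy series is summarised by its mean and sample variance, which form the
per-channel, per-rhythm feature pair fed to the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EEGTrial


@dataclass(frozen=True)
class ProbabilityDistribution:
    """Histogram probabilities P_i over N equal-width amplitude bins."""

    probabilities: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.size < 1:
            raise ValueError("distribution needs at least one bin")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to one")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_bins(self) -> int:
        return self.probabilities.size


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of the sliding-window entropy engine.

    q           nonextensive parameter (q = 1 selects the Shannon path)
    window_w    window width in samples (default 200 = 1 s at 200 Hz)
    step_delta  slide step in samples, must satisfy 1 <= delta <= w
                (default 100, i.e. 50% overlap)
    n_bins      histogram bin count, or "sqrt" for ceil(sqrt(w))
    """

    q: float = 3.0
    window_w: int = 200
    step_delta: int = 100
    n_bins: int | str = "sqrt"

    def __post_init__(self) -> None:
        if self.window_w < 2:
            raise ValueError("window width must be >= 2 samples")
        if not 1 <= self.step_delta <= self.window_w:
            raise ValueError("step must satisfy 1 <= delta <= window width")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if isinstance(self.n_bins, str):
            if self.n_bins != "sqrt":
                raise ValueError("bin rule must be an integer or 'sqrt'")
        elif self.n_bins < 1:
            raise ValueError("bin count must be >= 1")

    def resolve_bins(self) -> int:
        if self.n_bins == "sqrt":
            return math.ceil(math.sqrt(self.window_w))
        return int(self.n_bins)


@dataclass(frozen=True)
class EntropySeries:
    """Per-window entropy values and their 0-based window start indices."""

    values: np.ndarray
    starts: np.ndarray
    config: EntropyConfig

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EntropyFeatures:
    """Mean and sample variance of an entropy series: the classifier features."""

    mean: float
    variance: float


def amplitude_distribution(
    window_samples: np.ndarray, n_bins: int | str = "sqrt"
) -> ProbabilityDistribution:
    """Equal-width amplitude histogram of one window, as probabilities.

    Bins span the window's own [min, max]; a constant window collapses to a
    single degenerate bin with probability one.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be a 1-D vector of >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    if n_bins == "sqrt":
        bins = math.ceil(math.sqrt(x.size))
    else:
        bins = int(n_bins)
        if bins < 1:
            raise ValueError("bin count must be >= 1")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return ProbabilityDistribution(
            probabilities=np.array([1.0]), bin_edges=np.array([lo, hi])
        )
    # Left-closed equal-width bins over [lo, hi], the last bin closed at hi.
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(np.intp)
    np.clip(idx, 0, bins - 1, out=idx)
    counts = np.bincount(idx, minlength=bins)
    edges = lo + (hi - lo) * np.arange(bins + 1) / bins
    return ProbabilityDistribution(probabilities=counts / x.size, bin_edges=edges)


def tsallis_entropy(dist: ProbabilityDistribution, q: float) -> float:
    """Tsallis entropy (1 - sum P_i^q) / (q - 1); empty bins contribute zero."""
    if q <= 0:
        raise ValueError("q must be positive")
    if q == 1:
        raise ValueError("q = 1 is the Shannon limit; use shannon_entropy")
    p = dist.probabilities
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def shannon_entropy(dist: ProbabilityDistribution) -> float:
    """Shannon entropy -sum P_i ln P_i in nats, with 0 ln 0 = 0."""
    p = dist.probabilities
    # zero bins contribute exact 0.0 terms so the summation order (and hence
    # the floating-point result) matches the vectorised sliding-window path
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(-np.sum(plogp))


def max_tsallis_entropy(n_bins: int, q: float) -> float:
    """Upper bound (1 - N^(1-q)) / (q - 1), attained by the uniform distribution."""
    return (1.0 - n_bins ** (1.0 - q)) / (q - 1.0)


def _window_starts(n: int, w: int, delta: int) -> np.ndarray:
    return np.arange(0, n - w + 1, delta)


def sliding_entropy(sig: np.ndarray, config: EntropyConfig) -> EntropySeries:
    """Entropy of each sliding window of a single-channel signal.

    Windows start at 0, delta, 2*delta, ... while they fit entirely inside the
    signal; a trailing partial window is discarded rather than padded, since
    padding would distort the amplitude histogram. The per-window pipeline is
    histogram -> Tsallis entropy (Shannon when q = 1), vectorised across
    windows.
    """
    x = np.asarray(sig, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be a 1-D vector")
    w, delta = config.window_w, config.step_delta
    if x.size < w:
        raise ValueError(f"signal length {x.size} shorter than window {w}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    starts = _window_starts(x.size, w, delta)
    wins = np.lib.stride_tricks.sliding_window_view(x, w)[starts]
    n_bins = config.resolve_bins()

    lo = wins.min(axis=1, keepdims=True)
    hi = wins.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0  # constant windows: single bin, entropy 0
    safe = np.where(span == 0, 1.0, span)
    idx = np.floor((wins - lo) / safe * n_bins).astype(np.intp)
    np.clip(idx, 0, n_bins - 1, out=idx)  # x == max falls in the last bin
    offsets = np.arange(starts.size, dtype=np.intp)[:, None] * n_bins
    counts = np.bincount(
        (idx + offsets).ravel(), minlength=starts.size * n_bins
    ).reshape(starts.size, n_bins)
    p = counts / w

    if config.q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        values = -plogp.sum(axis=1)
    else:
        values = (1.0 - np.sum(p**config.q, axis=1)) / (config.q - 1.0)
    values = np.where(flat, 0.0, values)
    return EntropySeries(values=values, starts=starts, config=config)


def entropy_features(series: EntropySeries) -> EntropyFeatures:
    """Mean and sample (n-1) variance of the entropy series; variance is 0 for
    a single window."""
    v = series.values
    if v.size == 0:
        raise ValueError("empty entropy series")
    variance = float(v.var(ddof=1)) if v.size > 1 else 0.0
    return EntropyFeatures(mean=float(v.mean()), variance=variance)


META_COLUMNS = ("subject", "session", "trial", "label")


def feature_name(channel: str, band: str, statistic: str) -> str:
    return f"{channel}_{band}_{statistic}"


def build_feature_table(
    banded_trials: list[dict[str, EEGTrial]], config: EntropyConfig
) -> pd.DataFrame:
    """Assemble the feature matrix: one row per trial, one column per
    (channel, band, statistic).

    Each element of ``banded_trials`` maps band name -> preprocessed trial
    (all bands of one recording). Columns are named ``<channel>_<band>_<mean|var>``;
    metadata columns subject/session/trial/label lead the frame. All trials
    must share the channel set; offenders are reported.
    """
    if not banded_trials:
        bands: list[str] = []
        return pd.DataFrame(columns=list(META_COLUMNS))
    ref = next(iter(banded_trials[0].values()))
    ref_channels = ref.channel_labels
    rows = []
    for banded in banded_trials:
        any_band = next(iter(banded.values()))
        if any_band.channel_labels != ref_channels:
            raise ValueError(
                "inconsistent channel sets across trials: "
                f"trial {any_band.trial!r} has {list(any_band.channel_labels)[:5]}..."
            )
        row: dict[str, object] = {
            "subject": any_band.subject,
            "session": any_band.session,
            "trial": any_band.trial,
            "label": any_band.label,
        }
        for band_name, trial in sorted(banded.items()):
            for ci, ch in enumerate(trial.channel_labels):
                feats = entropy_features(sliding_entropy(trial.data[ci], config))
                row[feature_name(ch, band_name, "mean")] = feats.mean
                row[feature_name(ch, band_name, "var")] = feats.variance
        rows.append(row)
    return pd.DataFrame(rows)
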