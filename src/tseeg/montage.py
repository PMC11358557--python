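"""62-channel scalp montage, region partitions, and channel-selection utilities.

The bundled montage is the extended 10-20 layout used by the SEED recordings:
62 electrodes including the SEED-specific cerebellar leads CB1/CB2. Regions
follow the standard 10-20 naming convention: odd label suffixes lie over the
left hemisphere, even suffixes over the right, and a trailing ``Z`` marks the
midline. The anterior/posterior split runs along the central (T7..C..T8) row,
which is treated as a boundary belonging to neither half; the four quadrant
regions therefore exclude both midline and central-row electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

REGION_IDS = (
    "left_hemisphere",
    "right_hemisphere",
    "anterior",
    "posterior",
    "left_anterior",
    "right_anterior",
    "left_posterior",
    "right_posterior",
)


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout with optional 2-D scalp positions.

    Positions use the conventional topographic-map frame: head centre at the
    origin, nose toward +y, unit radius roughly at the head circumference.
    """

    channel_labels: tuple[str, ...]
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("montage channel labels must be unique")
        unknown = set(self.positions) - set(self.channel_labels)
        if unknown:
            raise ValueError(f"positions given for unknown labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.channel_labels)


@dataclass(frozen=True)
class RegionMap:
    """Named electrode groups covering hemispheres, halves, and quadrants."""

    regions: dict[str, frozenset[str]]

    def members(self, region: str) -> frozenset[str]:
        if region not in self.regions:
            raise KeyError(
                f"unknown region {region!r}; valid regions: {sorted(self.regions)}"
            )
        return self.regions[region]


def _bundled() -> dict:
    path = resources.files("tseeg").joinpath("data/montage.json")
    return json.loads(path.read_text())


def load_montage(path: str | Path | None = None) -> Montage:
    """Load the bundled 62-channel SEED montage, or a user file of the same schema."""
    doc = _bundled() if path is None else json.loads(Path(path).read_text())
    positions = {k: (float(v[0]), float(v[1])) for k, v in doc.get("positions", {}).items()}
    return Montage(channel_labels=tuple(doc["channels"]), positions=positions)


def load_region_map(path: str | Path | None = None) -> RegionMap:
    """Load the region partition bundled alongside the montage."""
    doc = _bundled() if path is None else json.loads(Path(path).read_text())
    return RegionMap(regions={k: frozenset(v) for k, v in doc["regions"].items()})


def boundary_channels() -> dict[str, frozenset[str]]:
    """Channels excluded from partitions: midline (hemispheres) and central row (halves)."""
    doc = _bundled()
    return {k: frozenset(v) for k, v in doc["boundary"].items()}


def region_members(montage: Montage, region_map: RegionMap, region: str) -> frozenset[str]:
    """Electrodes of one named region, checked against the montage."""
    members = region_map.members(region)
    stray = members - set(montage.channel_labels)
    if stray:
        raise ValueError(f"region {region!r} names channels outside the montage: {sorted(stray)}")
    return members


def top_quartile_channels(results: pd.DataFrame, fraction: float = 0.25) -> list[str]:
    """Select the best-performing channels from a per-channel result table.

    ``results`` needs one row per channel with columns ``unit`` (the channel
    label), ``mean_accuracy`` and ``mean_f_score``. Channels are ranked by
    mean accuracy, ties broken by mean F-score, then alphabetically; the top
    ``floor(n_channels * fraction)`` labels are returned in rank order.
    """
    if results.empty:
        raise ValueError("empty result table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    ranked = results.sort_values(
        ["mean_accuracy", "mean_f_score", "unit"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    n = int(len(results) * fraction)
    return ranked["unit"].head(n).tolist()
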