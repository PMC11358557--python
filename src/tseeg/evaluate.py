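"""Experiment orchestration: channel, rhythm, and region analyses across q.

An :class:`ExperimentPlan` names the Tsallis parameters (default q = 2, 3, 4),
the rhythms, and the analysis axes to run:

* ``channel`` — one classifier per electrode, using that electrode's
  {entropy mean, entropy variance} pair (2 features) in ``unit_band``;
* ``band`` — one classifier per rhythm, using every electrode's pair in that
  rhythm (124 features on the 62-channel montage);
* ``region`` — one classifier per scalp region, concatenating the member
  electrodes' feature pairs in ``unit_band``.

Channel and region axes are evaluated within a single rhythm (``unit_band``,
default gamma — the band analysed most closely here) so the result table keeps
one row per (q, band, unit). Every row records the mean/max accuracy and
F-score of a repeated stratified holdout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .classify import SplitSpec, feature_columns, repeated_holdout
from .entropy import EntropyConfig, META_COLUMNS, build_feature_table, feature_name
from .metrics import EvaluationSummary
from .montage import Montage, RegionMap, load_montage, load_region_map, top_quartile_channels
from .preprocess import EEGTrial

AXES = ("channel", "band", "region")

RESULT_COLUMNS = (
    "q",
    "band",
    "axis",
    "unit",
    "mean_accuracy",
    "max_accuracy",
    "mean_f_score",
    "max_f_score",
    "mean_sensitivity",
    "mean_specificity",
    "n_repetitions",
    "n_features",
    "flagged",
)


@dataclass(frozen=True)
class ExperimentPlan:
    """Full description of one evaluation campaign."""

    q_values: tuple[float, ...] = (2.0, 3.0, 4.0)
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma", "full")
    axes: tuple[str, ...] = AXES
    unit_band: str = "gamma"
    window_w: int = 200
    step_delta: int = 100
    n_bins: int | str = "sqrt"
    split: SplitSpec = field(default_factory=SplitSpec)
    k: int = 10
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if not (self.q_values and self.bands and self.axes):
            raise ValueError("plan needs at least one q value, band, and axis")
        bad = set(self.axes) - set(AXES)
        if bad:
            raise ValueError(f"unknown axes {sorted(bad)}; valid: {AXES}")
        if self.unit_band not in self.bands:
            raise ValueError(f"unit_band {self.unit_band!r} not in plan bands")

    def entropy_config(self, q: float) -> EntropyConfig:
        return EntropyConfig(
            q=q, window_w=self.window_w, step_delta=self.step_delta, n_bins=self.n_bins
        )


def _unit_columns(
    axis: str,
    unit: str,
    band: str,
    channels: Sequence[str],
    region_map: RegionMap | None,
) -> list[str]:
    if axis == "channel":
        members: Iterable[str] = [unit]
    elif axis == "band":
        members = channels
    else:
        members = sorted(region_map.members(unit))
    cols = []
    for ch in members:
        cols.append(feature_name(ch, band, "mean"))
        cols.append(feature_name(ch, band, "var"))
    return cols


def _row(
    q: float, band: str, axis: str, unit: str, summary: EvaluationSummary | None, n_features: int
) -> dict:
    row = {
        "q": q,
        "band": band,
        "axis": axis,
        "unit": unit,
        "n_features": n_features,
        "flagged": summary is None,
    }
    if summary is None:
        for col in RESULT_COLUMNS[4:10]:
            row[col] = math.nan
        row["n_repetitions"] = 0
    else:
        row.update(
            mean_accuracy=summary.mean_accuracy,
            max_accuracy=summary.max_accuracy,
            mean_f_score=summary.mean_f_score,
            max_f_score=summary.max_f_score,
            mean_sensitivity=summary.mean_sensitivity,
            mean_specificity=summary.mean_specificity,
            n_repetitions=summary.n_repetitions,
        )
    return row


def run_experiment(
    banded_trials: list[dict[str, EEGTrial]] | None,
    plan: ExperimentPlan,
    montage: Montage | None = None,
    region_map: RegionMap | None = None,
    feature_tables: Mapping[float, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Run every (q, axis, unit) cell of the plan and collect a result table.

    Features are extracted once per q value, then each unit's column subset is
    classified with a repeated stratified holdout. Pre-built feature tables
    (one per q, as from :func:`build_feature_table`) may be supplied to skip
    extraction. A unit with no feature columns (e.g. an empty region) yields a
    flagged row rather than disappearing.
    """
    montage = montage or load_montage()
    region_map = region_map or load_region_map()
    if feature_tables is None:
        if banded_trials is None:
            raise ValueError("either banded trials or feature tables are required")
        feature_tables = {
            q: build_feature_table(banded_trials, plan.entropy_config(q))
            for q in plan.q_values
        }
    rows = []
    for q in plan.q_values:
        table = feature_tables[q]
        channels = [
            ch for ch in montage.channel_labels
            if feature_name(ch, plan.unit_band, "mean") in table.columns
        ]
        for axis in plan.axes:
            if axis == "channel":
                cells = [(plan.unit_band, ch) for ch in channels]
            elif axis == "band":
                cells = [(b, b) for b in plan.bands]
            else:
                cells = [(plan.unit_band, r) for r in region_map.regions]
            for band, unit in cells:
                cols = _unit_columns(axis, unit, band, channels, region_map)
                cols = [c for c in cols if c in table.columns]
                if not cols:
                    rows.append(_row(q, band, axis, unit, None, 0))
                    continue
                sub = table[list(META_COLUMNS) + cols]
                summary = repeated_holdout(sub, plan.split, k=plan.k, metric=plan.metric)
                rows.append(_row(q, band, axis, unit, summary, len(cols)))
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def rank_units(results: pd.DataFrame, q: float, band: str, axis: str = "channel") -> list[str]:
    """Units of one (q, band, axis) stratum, best first.

    Descending mean accuracy, ties broken by mean F-score then unit label.
    """
    sub = results[(results["q"] == q) & (results["band"] == band) & (results["axis"] == axis)]
    if sub.empty:
        raise ValueError(f"no rows for q={q}, band={band!r}, axis={axis!r}")
    ranked = sub.sort_values(
        ["mean_accuracy", "mean_f_score", "unit"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return ranked["unit"].tolist()


def consensus_channels(
    tables: Sequence[pd.DataFrame], fraction: float = 0.25
) -> set[str]:
    """Channels in the top fraction for *every* supplied per-q result table.

    Each table must hold per-channel rows (columns ``unit``, ``mean_accuracy``,
    ``mean_f_score``) for one q value and a common band.
    """
    if not len(tables):
        raise ValueError("no result tables supplied")
    sets = []
    for tbl in tables:
        per_channel = tbl[tbl["axis"] == "channel"] if "axis" in tbl.columns else tbl
        sets.append(set(top_quartile_channels(per_channel, fraction)))
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def consensus_from_results(
    results: pd.DataFrame, band: str, fraction: float = 0.25
) -> set[str]:
    """Consensus top channels across every q present in one combined table."""
    qs = sorted(results.loc[results["axis"] == "channel", "q"].unique())
    tables = [
        results[(results["axis"] == "channel") & (results["q"] == q) & (results["band"] == band)]
        for q in qs
    ]
    return consensus_channels(tables, fraction)


def export_topology(selected: Iterable[str], montage: Montage | None = None) -> dict:
    """Topography document: every electrode with its 2-D position and a
    ``marked`` flag for the selected set; plottable downstream."""
    montage = montage or load_montage()
    selected = set(selected)
    unknown = selected - set(montage.channel_labels)
    if unknown:
        raise ValueError(f"labels not in montage: {sorted(unknown)}")
    channels = []
    for ch in montage.channel_labels:
        pos = montage.positions.get(ch)
        channels.append(
            {
                "label": ch,
                "x": None if pos is None else pos[0],
                "y": None if pos is None else pos[1],
                "marked": ch in selected,
            }
        )
    return {"n_channels": len(channels), "n_marked": len(selected), "channels": channels}


def save_results(
    results: pd.DataFrame, directory: str | Path, plan: ExperimentPlan
) -> None:
    """One CSV per axis plus a manifest JSON capturing the plan and seeds."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for axis in results["axis"].unique():
        results[results["axis"] == axis].to_csv(
            directory / f"results_{axis}.csv", index=False
        )
    plan_doc = asdict(plan)
    (directory / "plan.json").write_text(json.dumps(plan_doc, indent=1, default=str))
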