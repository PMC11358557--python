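"""Readers and writers for trial data: delimited matrices + manifest, and EDF.

The native on-disk layout is one delimited matrix per trial (rows = channels,
columns = samples) beside a ``manifest.json``:

    {"trials": [{"file": ..., "subject": ..., "session": ..., "trial": ...,
                 "label": ..., "rate": ..., "channels": [...]}, ...]}

EDF (European Data Format) files are read through MNE, one trial per file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import EEGTrial


def load_dataset(directory: str | Path) -> list[EEGTrial]:
    """Read every trial listed in a directory's manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    trials = []
    for entry in manifest["trials"]:
        data = np.loadtxt(directory / entry["file"], delimiter=",", ndmin=2)
        trials.append(
            EEGTrial(
                data=data,
                rate=float(entry["rate"]),
                channel_labels=tuple(entry["channels"]),
                subject=str(entry.get("subject", "")),
                session=str(entry.get("session", "")),
                trial=str(entry.get("trial", "")),
                label=entry.get("label"),
            )
        )
    return trials


def save_dataset(trials: list[EEGTrial], directory: str | Path) -> Path:
    """Write trials in the delimited + manifest layout; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, tr in enumerate(trials):
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
    path = directory / "manifest.json"
    path.write_text(json.dumps({"trials": entries}, indent=1))
    return path


def read_edf(
    path: str | Path,
    subject: str = "",
    session: str = "",
    trial: str = "",
    label: str | None = None,
) -> EEGTrial:
    """Read one EDF file as a single trial (data returned in microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGTrial(
        data=raw.get_data() * 1e6,  # MNE loads volts
        rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject=subject,
        session=session,
        trial=trial,
        label=label,
    )
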