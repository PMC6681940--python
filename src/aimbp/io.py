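"""CSV/JSON readers and writers for vitals, medication records and reports.

Dialects
--------
Vitals CSV: columns ``time_min, signal{SBP|DBP|HR}, modality{cuff|art|monitor},
value``; an empty value cell marks a missing measurement.  Irregular
timestamps are snapped to the nearest grid point (15 min by default); two
measurements snapping to the same cell are averaged.  No interpolation is
performed -- the DLM handles missingness natively.

Medication CSV: columns ``time_min, drug, event_type{bolus|rate}, value``
(mg for boluses, mg/hr for rate changes).

Reports and estimates are serialized as JSON with an embedded provenance
record (config hash + seed).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .dlm import Channel, VitalsSeries
from .pk import DoseEvent

__all__ = [
    "read_vitals",
    "write_vitals",
    "read_meds",
    "write_meds",
    "write_report",
    "load_config",
    "provenance",
]

_SIGNALS = ("SBP", "DBP", "HR")
_MODALITIES = ("cuff", "art", "monitor")
# canonical channel ordering in files
_CHANNEL_ORDER = [
    ("SBP", "cuff"), ("DBP", "cuff"), ("SBP", "art"), ("DBP", "art"),
    ("HR", "monitor"),
]


def read_vitals(path: str | Path, dt: float = 15.0) -> VitalsSeries:
    """Read a vitals CSV onto a uniform ``dt``-minute grid.

    Timestamps snap to the nearest grid point; collisions within a channel
    are averaged.  Unknown signals/modalities or unparseable rows raise
    with the offending line numbers.
    """
    df = pd.read_csv(path, dtype={"signal": str, "modality": str})
    required = {"time_min", "signal", "modality", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"vitals CSV must have columns {sorted(required)}")
    bad = df.index[~df["signal"].isin(_SIGNALS) | ~df["modality"].isin(_MODALITIES)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"unknown signal/modality at line(s) {lines}")
    bad_time = df.index[~np.isfinite(pd.to_numeric(df["time_min"], errors="coerce"))]
    if len(bad_time):
        lines = ", ".join(str(i + 2) for i in bad_time[:10])
        raise ValueError(f"unparseable time at line(s) {lines}")

    df = df.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["step"] = np.rint(df["time_min"].astype(float) / dt).astype(int)
    if (df["step"] < 0).any():
        raise ValueError("negative times are not allowed")
    n_steps = int(df["step"].max()) + 1

    present = {(s, m) for s, m in zip(df["signal"], df["modality"])}
    channels = tuple(
        Channel(s, m) for s, m in _CHANNEL_ORDER if (s, m) in present
    )
    y = np.full((n_steps, len(channels)), np.nan)
    for j, ch in enumerate(channels):
        sub = df[(df["signal"] == ch.signal) & (df["modality"] == ch.modality)]
        sub = sub.dropna(subset=["value"])
        means = sub.groupby("step")["value"].mean()
        y[means.index.to_numpy(), j] = means.to_numpy()
    return VitalsSeries(np.arange(n_steps) * dt, y, channels)


def write_vitals(vitals: VitalsSeries, path: str | Path) -> None:
    """Write a vitals series in the same dialect (lossless on grid-aligned data)."""
    rows = []
    for t in range(vitals.n_steps):
        for j, ch in enumerate(vitals.channels):
            if vitals.mask[t, j]:
                rows.append({
                    "time_min": vitals.time[t],
                    "signal": ch.signal,
                    "modality": ch.modality,
                    "value": vitals.y[t, j],
                })
    pd.DataFrame(rows, columns=["time_min", "signal", "modality", "value"]) \
        .to_csv(path, index=False)


def read_meds(path: str | Path) -> list[DoseEvent]:
    """Read a medication-administration CSV into time-ordered dose events."""
    df = pd.read_csv(path)
    required = {"time_min", "drug", "event_type", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"meds CSV must have columns {sorted(required)}")
    if len(df) == 0:
        return []
    bad = df.index[~df["event_type"].isin(("bolus", "rate"))]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"unknown event_type at line(s) {lines}")
    if not df["time_min"].is_monotonic_increasing:
        warnings.warn("medication events out of order; sorting by time")
        df = df.sort_values("time_min", kind="stable")
    events = []
    for _, row in df.iterrows():
        value = float(row["value"])
        if row["event_type"] == "bolus":
            events.append(DoseEvent(float(row["time_min"]), str(row["drug"]),
                                    amount=value))
        else:
            events.append(DoseEvent(float(row["time_min"]), str(row["drug"]),
                                    rate=value))
    return events


def write_meds(events: Iterable[DoseEvent], path: str | Path) -> None:
    rows = [{
        "time_min": e.time,
        "drug": e.drug,
        "event_type": "bolus" if e.is_bolus else "rate",
        "value": e.amount if e.is_bolus else e.rate,
    } for e in events]
    pd.DataFrame(rows, columns=["time_min", "drug", "event_type", "value"]) \
        .to_csv(path, index=False)


def provenance(config: dict, seed: int | None) -> dict:
    """Reproducibility record: a stable hash of the configuration plus the seed."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
    }


def write_report(report, path: str | Path, config: dict | None = None,
                 seed: int | None = None) -> None:
    """Serialize a report (or any dict-like result) as JSON with provenance."""
    if hasattr(report, "to_dict"):
        payload = report.to_dict()
    elif isinstance(report, dict):
        payload = dict(report)
    else:
        raise TypeError("report must be a dict or expose to_dict()")
    payload["provenance"] = provenance(config or {}, seed)
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    return yaml.safe_load(text) or {}
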