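"""Data structures, readers/writers, and epoch extraction for dyad recordings.

A *dyad recording* holds the multichannel concentration time series of two
interacting participants.  Every channel carries a role (``Model`` or
``Imitator``) and a region label (e.g. ``M1``, ``PMC``, ``PMC/M1``, ``SDC``);
the short-distance channels (SDC) see only scalp/systemic physiology and are
used downstream to calibrate the no-causality baseline.

File formats are deliberately plain: CSV time series with a header row of
channel labels (optional leading ``time`` column in seconds), a YAML/JSON
channel-map config (keys ``fs``, ``roles``, ``regions``, optional
``chromophore``), and a BIDS-events-like CSV table (onset, duration,
condition, trial_index).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "DyadRecording",
    "EventTable",
    "DyadEpoch",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "extract_epochs",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

ROLES = ("Model", "Imitator")
DEFAULT_EPOCH_LENGTH = 204   # 20 s task interval at fs = 10.17 Hz
DEFAULT_PRE_ONSET = 10       # epoch starts 1 s (10 samples) before video onset


class ConfigError(ValueError):
    """Channel-map configuration does not match the data file."""


@dataclass
class DyadRecording:
    """Full-session multichannel recording of one dyad."""

    samples: np.ndarray                 # (L_total, n_channels)
    fs: float
    channel_labels: list[str]
    role_map: dict[str, str]            # channel -> Model | Imitator
    region_map: dict[str, str]          # channel -> region name
    chromophore: str = "HbO"
    dyad_id: str = "dyad"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a non-empty (L x C) matrix")
        if self.samples.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels must match the number of columns")
        for ch in self.channel_labels:
            if self.role_map.get(ch) not in ROLES:
                raise ConfigError(f"channel {ch!r} lacks a valid role (Model/Imitator)")
            if ch not in self.region_map:
                raise ConfigError(f"channel {ch!r} lacks a region")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def channels(self, region: str, role: str) -> list[str]:
        """Channel labels of one region for one participant, in column order."""
        return [ch for ch in self.channel_labels
                if self.region_map[ch] == region and self.role_map[ch] == role]

    def regions(self, exclude_sdc: bool = True) -> list[str]:
        seen: list[str] = []
        for ch in self.channel_labels:
            r = self.region_map[ch]
            if r not in seen and not (exclude_sdc and r == "SDC"):
                seen.append(r)
        return seen

    def column_index(self, labels: list[str]) -> list[int]:
        return [self.channel_labels.index(ch) for ch in labels]


@dataclass
class EventTable:
    """Task/baseline intervals: onset and duration in seconds."""

    frame: pd.DataFrame    # columns: onset, duration, condition, trial_index

    def __post_init__(self) -> None:
        required = {"onset", "duration", "condition", "trial_index"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        onsets = self.frame["onset"].to_numpy(dtype=float)
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        if not np.all(self.frame["duration"].to_numpy(dtype=float) > 0):
            raise ValueError("event durations must be positive")

    def select(self, conditions: list[str] | None = None) -> pd.DataFrame:
        if conditions is None:
            return self.frame
        return self.frame[self.frame["condition"].isin(conditions)]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class DyadEpoch:
    """One analysis interval: Model channel block stacked before Imitator block."""

    data: np.ndarray          # (L, 2N), Model columns first
    n_per_participant: int    # N
    fs: float
    condition: str
    region: str
    dyad_id: str
    trial_index: int
    channel_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("epoch data must be 2-D")
        if data.shape[1] != 2 * self.n_per_participant:
            raise ValueError("epoch must have equal-width Model and Imitator blocks")
        if np.isnan(data).any():
            raise ValueError("epoch contains missing values; causal estimates "
                             "are lag-sensitive and imputation is not supported")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def swapped_roles(self) -> "DyadEpoch":
        """Relabel Model<->Imitator (Imitator block first); for antisymmetry checks."""
        n = self.n_per_participant
        data = np.concatenate([self.data[:, n:], self.data[:, :n]], axis=1)
        labels = tuple(self.channel_labels[n:] + self.channel_labels[:n]) \
            if self.channel_labels else ()
        return DyadEpoch(data=data, n_per_participant=n, fs=self.fs,
                         condition=self.condition, region=self.region,
                         dyad_id=self.dyad_id, trial_index=self.trial_index,
                         channel_labels=labels)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    else:
        cfg = dict(config)
    for key in ("fs", "roles", "regions"):
        if key not in cfg:
            raise ConfigError(f"channel-map config missing key {key!r}")
    return cfg


def read_recording(path, config, dyad_id: str | None = None) -> DyadRecording:
    """Read a CSV time series (header row of channel labels) with its channel map.

    The config maps every named channel to a role and a region; a config
    entry referencing a channel absent from the file is an error.  A leading
    ``time`` column (seconds) is allowed and dropped (sampling is uniform at
    ``fs``).
    """
    cfg = _load_config(config)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if "time" in frame.columns:
        frame = frame.drop(columns=["time"])
    labels = [str(c) for c in frame.columns]
    for ch in list(cfg["roles"]) + list(cfg["regions"]):
        if ch not in labels:
            raise ConfigError(f"config references absent channel {ch!r}")
    for ch in labels:
        if ch not in cfg["roles"] or ch not in cfg["regions"]:
            raise ConfigError(f"data channel {ch!r} missing from config")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = [c for c in frame.columns
               if not np.issubdtype(frame[c].dtype, np.number)]
        raise ValueError(f"non-numeric values in column(s) {bad}")
    return DyadRecording(
        samples=values.astype(float),
        fs=float(cfg["fs"]),
        channel_labels=labels,
        role_map=dict(cfg["roles"]),
        region_map=dict(cfg["regions"]),
        chromophore=str(cfg.get("chromophore", "HbO")),
        dyad_id=dyad_id or str(cfg.get("dyad_id", "dyad")),
    )


def write_recording(rec: DyadRecording, path) -> None:
    """Write the samples as CSV at full float precision (round-trip safe)."""
    frame = pd.DataFrame(rec.samples, columns=rec.channel_labels)
    frame.to_csv(path, index=False, float_format="%.17g")


def recording_config(rec: DyadRecording) -> dict:
    """Channel-map config dict matching :func:`read_recording`."""
    return {
        "fs": rec.fs,
        "roles": dict(rec.role_map),
        "regions": dict(rec.region_map),
        "chromophore": rec.chromophore,
        "dyad_id": rec.dyad_id,
        "sdc_channels": [ch for ch in rec.channel_labels
                         if rec.region_map[ch] == "SDC"],
    }


def read_events(path) -> EventTable:
    return EventTable(pd.read_csv(path))


def write_events(events: EventTable, path) -> None:
    events.frame.to_csv(path, index=False, float_format="%.17g")


def extract_epochs(rec: DyadRecording, events: EventTable, region: str,
                   epoch_length: int = DEFAULT_EPOCH_LENGTH,
                   pre_onset: int = DEFAULT_PRE_ONSET,
                   conditions: list[str] | None = None) -> list[DyadEpoch]:
    """Cut one epoch per event for one region's Model+Imitator channels.

    Epoch sample 0 sits at ``round(onset * fs) - pre_onset``; windows are
    half-open ``[start, start + epoch_length)`` in 0-based sample indices.
    Events whose window does not fit inside the recording are skipped with a
    warning, not raised.
    """
    m_labels = rec.channels(region, "Model")
    i_labels = rec.channels(region, "Imitator")
    if not m_labels or not i_labels:
        raise ValueError(f"region {region!r} has no channels for both roles")
    if len(m_labels) != len(i_labels):
        raise ValueError(
            f"region {region!r} has {len(m_labels)} Model but "
            f"{len(i_labels)} Imitator channels; blocks must match"
        )
    cols = rec.column_index(m_labels + i_labels)
    epochs: list[DyadEpoch] = []
    for row in events.select(conditions).itertuples(index=False):
        start = int(round(float(row.onset) * rec.fs)) - pre_onset
        stop = start + epoch_length
        if start < 0 or stop > rec.n_samples:
            msg = (f"epoch for trial {row.trial_index} ({row.condition}) at "
                   f"samples [{start}, {stop}) out of bounds; skipped")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        epochs.append(DyadEpoch(
            data=rec.samples[start:stop, cols].copy(),
            n_per_participant=len(m_labels),
            fs=rec.fs,
            condition=str(row.condition),
            region=region,
            dyad_id=rec.dyad_id,
            trial_index=int(row.trial_index),
            channel_labels=tuple(m_labels + i_labels),
        ))
    return epochs


def write_results(results: list, path) -> None:
    """Write causal results: a summary CSV plus a per-frequency companion CSV.

    The summary has one row per epoch (dyad, trial, region, condition,
    signed band value, intensity, baseline, decision, model order); the
    companion ``<stem>_spectra.csv`` holds the per-frequency directed
    spectra and masks in long format.  Floats are written with 17
    significant digits so a read-back reproduces them exactly.
    """
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    summary = pd.DataFrame([r.summary_row() for r in results])
    summary.to_csv(path, index=False, float_format="%.17g")
    spectra = pd.concat([r.spectrum_frame() for r in results], ignore_index=True)
    spectra.to_csv(path.with_name(path.stem + "_spectra" + path.suffix),
                   index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
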