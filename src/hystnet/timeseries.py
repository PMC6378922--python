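"""Multichannel, multi-trial source-level time series.

The container deliberately mirrors what a source-separation stage of an
EEG study hands to a connectivity analysis: a ``channels x samples x
trials`` array at a known sampling rate, with a per-sample condition
label recording the demand schedule, and the seed that produced it when
the data are synthetic.

I/O is plain text: a long-format CSV (``time_s, node, trial, value``)
plus a JSON sidecar carrying sampling rate, condition boundaries, the
generating network (if any) and the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SourceTimeSeries", "write_csv", "read_csv"]


@dataclass
class SourceTimeSeries:
    """Source-level signal block.

    Attributes
    ----------
    data
        Real array of shape ``(channels, samples, trials)``.
    fs
        Sampling rate in Hz.
    channel_names
        One name per channel.
    condition_labels
        Per-sample condition label (length ``samples``); ``None`` for
        unlabeled data.
    seed
        Seed used to generate the data, if synthetic.
    meta
        Free-form provenance (generating networks, segment boundaries).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    condition_labels: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError("data must have shape (channels, samples, trials)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite sample at (channel={bad[0]}, sample={bad[1]}, trial={bad[2]})"
            )
        if self.condition_labels is not None:
            self.condition_labels = np.asarray(self.condition_labels)
            if self.condition_labels.shape[0] != self.data.shape[1]:
                raise ValueError("condition_labels must have one entry per sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def segment(self, condition: str) -> "SourceTimeSeries":
        """Extract the samples labeled with one condition."""
        if self.condition_labels is None:
            raise ValueError("time series carries no condition labels")
        mask = self.condition_labels == condition
        if not mask.any():
            raise ValueError(f"no samples labeled {condition!r}")
        return SourceTimeSeries(
            data=self.data[:, mask, :],
            fs=self.fs,
            channel_names=list(self.channel_names),
            condition_labels=self.condition_labels[mask],
            seed=self.seed,
            meta=dict(self.meta),
        )

    def conditions(self) -> list[str]:
        if self.condition_labels is None:
            return []
        seen: list[str] = []
        for c in self.condition_labels:
            if c not in seen:
                seen.append(str(c))
        return seen


def write_csv(ts: SourceTimeSeries, path: str | Path) -> None:
    """Write a long-format CSV plus a ``<path>.json`` sidecar."""
    path = Path(path)
    k, n, r = ts.data.shape
    times = np.tile(np.repeat(ts.times, r), k)
    nodes = np.repeat(ts.channel_names, n * r)
    trials = np.tile(np.arange(r), k * n)
    values = ts.data.reshape(k * n * r)
    df = pd.DataFrame(
        {"time_s": times, "node": nodes, "trial": trials, "value": values}
    )
    df.to_csv(path, index=False)
    sidecar = {
        "fs": ts.fs,
        "channel_names": list(ts.channel_names),
        "seed": ts.seed,
        "condition_labels": None
        if ts.condition_labels is None
        else _run_length_encode(ts.condition_labels),
        "meta": ts.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_csv(path: str | Path) -> SourceTimeSeries:
    """Read a time series written by :func:`write_csv`.

    A sidecar JSON is used when present; otherwise ``fs`` is inferred
    from the time column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None

    if sidecar is not None:
        names = sidecar["channel_names"]
    else:
        names = list(dict.fromkeys(df["node"]))
    trials = sorted(df["trial"].unique())
    n = df["time_s"].nunique()
    k, r = len(names), len(trials)
    data = np.empty((k, n, r))
    df = df.sort_values(["node", "time_s", "trial"], kind="stable")
    for i, name in enumerate(names):
        sub = df[df["node"] == name]
        data[i] = sub["value"].to_numpy().reshape(n, r)
    if sidecar is not None:
        fs = sidecar["fs"]
        labels = (
            None
            if sidecar["condition_labels"] is None
            else _run_length_decode(sidecar["condition_labels"])
        )
        return SourceTimeSeries(
            data, fs, names, labels, seed=sidecar.get("seed"), meta=sidecar.get("meta", {})
        )
    t = np.sort(df["time_s"].unique())
    fs = 1.0 / float(np.median(np.diff(t))) if n > 1 else 1.0
    return SourceTimeSeries(data, fs, names)


def _run_length_encode(labels: np.ndarray) -> list[list]:
    runs: list[list] = []
    for lab in labels:
        lab = str(lab)
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return runs


def _run_length_decode(runs: list[list]) -> np.ndarray:
    return np.concatenate([np.full(cnt, lab, dtype=object) for lab, cnt in runs])
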