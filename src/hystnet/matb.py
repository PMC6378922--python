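"""Multi-Attribute Task Battery (MATB)-style event schedules.

The flight-deck multitasking battery exposes four concurrent subtasks:
system monitoring (warning lights and drifting gauges answered with
function keys), communications (own-callsign radio calls plus
distractor calls), compensatory tracking (continuous joystick control;
no discrete events), and resource management (pump failures and
shut-offs).  Task demand is manipulated through per-minute event rates;
each rate is drawn uniformly from its published low/high range and held
fixed for the block, and events then arrive as independent homogeneous
Poisson streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_RATE_RANGES",
    "EVENT_SUBTASK",
    "EVENT_ORDER",
    "EventSchedule",
    "draw_rates",
    "generate_events",
    "write_schedule",
    "read_schedule",
    "make_lhl_schedule",
]

#: Per-minute event-rate ranges by demand level.
EVENT_RATE_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "comm_target": {"low": (0.7, 1.0), "high": (3.0, 4.2)},
    "comm_distractor": {"low": (0.35, 0.5), "high": (1.0, 1.35)},
    "light": {"low": (4.0, 6.7), "high": (15.0, 17.7)},
    "gauge": {"low": (5.0, 7.0), "high": (16.0, 18.0)},
    "pump_failure": {"low": (0.7, 1.0), "high": (4.3, 5.0)},
    "pump_shutoff": {"low": (0.7, 1.0), "high": (2.0, 2.3)},
}

EVENT_SUBTASK: dict[str, str] = {
    "comm_target": "communications",
    "comm_distractor": "communications",
    "light": "system_monitoring",
    "gauge": "system_monitoring",
    "pump_failure": "resource_management",
    "pump_shutoff": "resource_management",
}

#: Deterministic tie-break order for simultaneous events.
EVENT_ORDER: list[str] = list(EVENT_RATE_RANGES)


@dataclass
class EventSchedule:
    """Timestamped subtask events for one (or several) demand blocks."""

    events: pd.DataFrame
    duration_s: float
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"time_s", "subtask", "event_type", "condition"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"schedule missing columns {sorted(missing)}")
        t = self.events["time_s"].to_numpy(dtype=float)
        if len(t) and (not np.all(np.isfinite(t))):
            raise ValueError("non-finite event time in schedule")
        if len(t) and (t.min() < 0 or t.max() >= self.duration_s):
            raise ValueError("event times must lie in [0, duration_s)")
        if not np.all(np.diff(t) >= 0):
            raise ValueError("events must be sorted by time")

    def __len__(self) -> int:
        return len(self.events)

    def condition_blocks(self) -> list[tuple[str, float, float]]:
        """(condition, start, end) blocks recorded in ``attrs``."""
        return list(self.events.attrs.get("blocks", []))


def draw_rates(
    condition: str, seed: int | np.random.Generator = 0
) -> dict[str, float]:
    """Draw one per-minute rate per event type, uniform in its range.

    ``condition`` is ``"low"`` or ``"high"``; the draw is fixed for the
    whole block.
    """
    condition = condition.lower()
    if condition not in ("low", "high"):
        raise ValueError(f"condition must be 'low' or 'high', got {condition!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {
        ev: float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        for ev, (lo, hi) in (
            (ev, EVENT_RATE_RANGES[ev][condition]) for ev in EVENT_ORDER
        )
    }


def generate_events(
    condition: str,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    rates: dict[str, float] | None = None,
    t_offset: float = 0.0,
    label: str | None = None,
) -> EventSchedule:
    """Homogeneous Poisson event streams for one demand block.

    One independent stream per event type at the (drawn or supplied)
    per-minute rate; streams are merged and time-sorted with the
    deterministic tie-break order ``EVENT_ORDER``.  Reproducible for a
    fixed integer seed.
    """
    if duration_s < 0:
        raise ValueError("duration must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rates is None:
        rates = draw_rates(condition, rng)
    rows = []
    for ev in EVENT_ORDER:
        rate_per_s = rates[ev] / 60.0
        n = rng.poisson(rate_per_s * duration_s)
        times = np.sort(rng.uniform(0.0, duration_s, size=n))
        for t in times:
            rows.append(
                (
                    t + t_offset,
                    EVENT_SUBTASK[ev],
                    ev,
                    label if label is not None else condition,
                )
            )
    df = pd.DataFrame(rows, columns=["time_s", "subtask", "event_type", "condition"])
    order = {ev: i for i, ev in enumerate(EVENT_ORDER)}
    df["_tie"] = df["event_type"].map(order)
    df = df.sort_values(["time_s", "_tie"], kind="stable").drop(columns="_tie")
    df = df.reset_index(drop=True)
    sched = EventSchedule(df, duration_s=t_offset + duration_s)
    sched.events.attrs["rates"] = dict(rates)
    return sched


def make_lhl_schedule(
    condition_minutes: float = 4.0,
    seed: int = 0,
) -> EventSchedule:
    """Full Low-High-Low session schedule (blocks L1, H2, L3).

    Each block draws its own rates (low/high/low demand) and its own
    Poisson streams from a seed-derived stream.
    """
    rng = np.random.default_rng(seed)
    dur = condition_minutes * 60.0
    frames = []
    blocks = []
    rates_by_block = {}
    for i, (label, level) in enumerate([("L1", "low"), ("H2", "high"), ("L3", "low")]):
        block = generate_events(
            level, dur, seed=np.random.default_rng(rng.integers(0, 2**31 - 1)),
            t_offset=i * dur, label=label,
        )
        frames.append(block.events)
        blocks.append((label, i * dur, (i + 1) * dur))
        rates_by_block[label] = block.events.attrs.get("rates", {})
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time_s", "subtask", "event_type", "condition"]
    )
    sched = EventSchedule(df, duration_s=3 * dur, seed=seed)
    sched.events.attrs["blocks"] = blocks
    sched.events.attrs["rates"] = rates_by_block
    return sched


def write_schedule(schedule: EventSchedule, path: str | Path) -> None:
    """Write the schedule as CSV (lossless round-trip)."""
    t = schedule.events["time_s"].to_numpy(dtype=float)
    if len(t) and not np.all(np.isfinite(t)):
        raise ValueError("refusing to write schedule with non-finite times")
    df = schedule.events.copy()
    df.attrs = {}
    header_meta = f"# duration_s={schedule.duration_s!r}\n"
    with open(path, "w") as fh:
        fh.write(header_meta)
        df.to_csv(fh, index=False)


def read_schedule(path: str | Path) -> EventSchedule:
    """Read a schedule written by :func:`write_schedule`."""
    with open(path) as fh:
        first = fh.readline()
        duration = None
        if first.startswith("# duration_s="):
            duration = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if duration is None:
        duration = float(df["time_s"].max()) + 1.0 if len(df) else 0.0
    df["time_s"] = df["time_s"].astype(float)
    return EventSchedule(df, duration_s=duration)
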