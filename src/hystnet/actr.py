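"""ACT-R-style multitasking agent.

The agent implements the *architectural* core of the ACT-R cognitive
architecture — the sub-symbolic declarative-memory equations plus the
timing and buffer constraints — with a minimal production set for the
system-monitoring and tracking subtasks of a MATB-like environment:

* **base-level learning** ``B(t) = ln sum_k (t - t_k)^-d + B0``: a
  chunk's activation grows with use and decays as a power law;
* **activation** ``A = B + sum_j W_j S_ij + eps`` with Gaussian
  transient noise;
* **retrieval probability** ``p = 1 / (1 + exp((tau - A)/s))``;
* **retrieval latency** ``T = F exp(-A)`` (a failed retrieval is
  signalled after ``F exp(-tau)``);
* productions are evaluated on a fixed 50 ms cycle, and the declarative
  buffer holds one chunk at a time, so concurrent retrieval requests
  queue.

Each system-monitoring event is answered by a serial pipeline — visual
encoding, declarative retrieval of the event->key mapping chunk, then a
manual keypress — while tracking error accumulates as a bounded
random-walk disturbance that is corrected only in cycles where
attention is free for tracking.  Because the base-level term carries a
chunk's whole presentation history, practice accumulated during a
high-demand block speeds retrieval in the following low-demand block;
the ``carryover`` switch controls whether histories persist across
blocks or are reset, which toggles this hysteresis on and off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matb import EVENT_ORDER, EventSchedule

__all__ = [
    "Chunk",
    "ActrParams",
    "BehavioralRecord",
    "base_level",
    "activation",
    "retrieval_probability",
    "retrieval_time",
    "run_session",
    "summarize_bins",
]


class RetrievalFailure(Exception):
    """Raised when a chunk has no presentation history ('no such chunk')."""


@dataclass
class Chunk:
    """A declarative-memory chunk with its presentation history."""

    id: str
    presentation_times: list[float] = field(default_factory=list)
    permanent_base: float = 0.0

    def __post_init__(self) -> None:
        t = self.presentation_times
        if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
            raise ValueError("presentation times must be strictly increasing")

    def add_presentation(self, t: float) -> None:
        if self.presentation_times and t <= self.presentation_times[-1]:
            raise ValueError("presentations must be added in increasing time order")
        self.presentation_times.append(t)


@dataclass
class ActrParams:
    """Sub-symbolic and timing parameters of the agent.

    Timing defaults (50 ms production cycle, 85 ms visual encoding,
    210 ms keypress) follow common cognitive-architecture conventions;
    ``d`` is the canonical 0.5 power-law decay.  ``dwell_s`` is how
    long a communications or resource-management event occupies
    attention (those subtasks are handled but not scored).
    """

    d: float = 0.5
    tau: float = -2.0
    s: float = 0.4
    F: float = 0.5
    W: dict[str, float] = field(default_factory=dict)
    Sji: dict[str, float] = field(default_factory=dict)
    epsilon_sd: float = 0.25
    cycle_ms: float = 50.0
    motor_ms: float = 210.0
    visual_ms: float = 85.0
    dwell_s: float = 1.5
    n_training: int = 5
    training_span_s: float = 300.0
    track_sigma: float = 30.0
    track_gain: float = 1.0
    track_bound: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("decay rate d must be positive")
        if self.s <= 0:
            raise ValueError("activation-noise scale s must be positive")
        if self.F <= 0:
            raise ValueError("latency factor F must be positive")
        if self.cycle_ms <= 0 or self.motor_ms < 0 or self.visual_ms < 0:
            raise ValueError("invalid timing parameters")


@dataclass
class BehavioralRecord:
    """Responses, tracking-error trace and production-cycle log."""

    responses: pd.DataFrame
    tracking_error: np.ndarray
    tick_times: np.ndarray
    duration_s: float
    misses: int
    retrieval_intervals: list[tuple[float, float]]
    blocks: list[tuple[str, float, float]] = field(default_factory=list)
    params: ActrParams | None = None


def base_level(chunk: Chunk, t: float, d: float = 0.5) -> float:
    """Base-level activation ``ln sum_k (t - t_k)^-d + B0``.

    Raises :class:`RetrievalFailure` for an empty history (no such
    chunk) rather than returning -inf.
    """
    if not chunk.presentation_times:
        raise RetrievalFailure(f"chunk {chunk.id!r} has no presentation history")
    if t <= chunk.presentation_times[-1]:
        raise ValueError("t must be strictly after every presentation")
    ages = np.asarray([t - tk for tk in chunk.presentation_times])
    return float(np.log(np.sum(ages ** (-d))) + chunk.permanent_base)


def activation(
    chunk: Chunk,
    t: float,
    params: ActrParams,
    context: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Total activation ``B(t) + sum_j W_j S_ij + eps``.

    ``context`` maps source elements ``j`` to attentional weights
    ``W_j``; association strengths ``S_ij`` come from ``params.Sji``.
    The transient noise ``eps ~ N(0, epsilon_sd)`` is drawn from the
    supplied generator (or the params seed).
    """
    b = base_level(chunk, t, params.d)
    assoc = 0.0
    weights = context if context is not None else params.W
    for j, wj in weights.items():
        assoc += wj * params.Sji.get(j, 0.0)
    eps = 0.0
    if params.epsilon_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        eps = float(rng.normal(0.0, params.epsilon_sd))
    return b + assoc + eps


def retrieval_probability(A: float, tau: float, s: float) -> float:
    """Logistic probability of successful retrieval, increasing in A."""
    if s <= 0:
        raise ValueError("noise scale s must be positive")
    return 1.0 / (1.0 + math.exp((tau - A) / s))


def retrieval_time(A: float, F: float) -> float:
    """Retrieval latency ``F exp(-A)`` seconds, decreasing in A."""
    if F <= 0:
        raise ValueError("latency factor F must be positive")
    return F * math.exp(-A)


def _training_history(block_start: float, params: ActrParams) -> list[float]:
    """Pre-block practice presentations, spread before the block start."""
    n = params.n_training
    span = params.training_span_s
    return [block_start - span + i * (span - 60.0) / max(n - 1, 1) for i in range(n)]


#: Monitoring event types that require a keyed response.
_MONITORED = ("light", "gauge")


def run_session(
    schedule: EventSchedule,
    params: ActrParams | None = None,
    carryover: bool = True,
) -> BehavioralRecord:
    """Run the agent over an event schedule.

    Productions are evaluated every ``cycle_ms``; system-monitoring
    events pass through visual encoding -> serialized declarative
    retrieval -> manual keypress, other events occupy attention for
    ``dwell_s``.  With ``carryover=True`` chunk histories persist
    across condition blocks (practice in the high-demand block raises
    activation afterwards); with ``carryover=False`` histories are
    reset to the pre-block training state at every block boundary.
    """
    if params is None:
        params = ActrParams()
    rng = np.random.default_rng(params.seed)
    dt = params.cycle_ms / 1000.0
    duration = schedule.duration_s
    n_ticks = int(math.ceil(duration / dt))
    tick_times = np.arange(n_ticks) * dt

    blocks = schedule.condition_blocks()
    if blocks:
        starts = [b[1] for b in blocks]
        ends = [b[2] for b in blocks]
        if any(e > s + 1e-9 for s, e in zip(starts[1:], ends[:-1])):
            raise ValueError("overlapping condition blocks in schedule")
    block_starts = sorted(b[1] for b in blocks) if blocks else [0.0]

    chunks: dict[str, Chunk] = {
        ev: Chunk(ev, _training_history(0.0, params)) for ev in _MONITORED
    }

    ev_df = schedule.events
    events = list(
        ev_df[["time_s", "subtask", "event_type", "condition"]].itertuples(index=False)
    )
    next_event = 0
    queue: list = []

    # serial cognitive pipeline state
    state = "idle"
    state_until = 0.0
    current = None
    retrieval_ok = False
    retrieval_intervals: list[tuple[float, float]] = []
    pending_reset = [s for s in block_starts if s > 0.0]

    track = np.empty(n_ticks)
    e = 0.0
    responses = []
    misses = 0

    for ti in range(n_ticks):
        t = tick_times[ti]

        # block boundary: reset declarative histories when not carrying over
        if not carryover and pending_reset and t >= pending_reset[0]:
            b0 = pending_reset.pop(0)
            for ev in _MONITORED:
                chunks[ev] = Chunk(ev, _training_history(b0, params))

        # enqueue events that have occurred (schedule order is the tie-break)
        while next_event < len(events) and events[next_event].time_s <= t:
            queue.append(events[next_event])
            next_event += 1

        # advance the pipeline on this production-evaluation cycle
        if state != "idle" and t >= state_until:
            if state == "encoding":
                chunk = chunks[current.event_type]
                try:
                    A = activation(chunk, t, params, rng=rng)
                    p_ok = retrieval_probability(A, params.tau, params.s)
                    retrieval_ok = bool(rng.uniform() < p_ok)
                    latency = (
                        retrieval_time(A, params.F)
                        if retrieval_ok
                        else retrieval_time(params.tau, params.F)
                    )
                except RetrievalFailure:
                    retrieval_ok = False
                    latency = retrieval_time(params.tau, params.F)
                state = "retrieving"
                state_until = t + latency
                retrieval_intervals.append((t, state_until))
            elif state == "retrieving":
                if retrieval_ok:
                    chunk = chunks[current.event_type]
                    if not chunk.presentation_times or t > chunk.presentation_times[-1]:
                        chunk.add_presentation(t)
                    state = "motor"
                    state_until = t + params.motor_ms / 1000.0
                else:
                    misses += 1
                    state = "idle"
                    current = None
            elif state == "motor":
                responses.append(
                    (
                        current.time_s,
                        state_until - current.time_s,
                        True,
                        current.subtask,
                        current.event_type,
                        current.condition,
                    )
                )
                state = "idle"
                current = None
            elif state == "dwell":
                state = "idle"
                current = None

        # start handling the next queued event if the pipeline is free
        if state == "idle" and queue:
            current = queue.pop(0)
            if current.event_type in _MONITORED:
                state = "encoding"
                state_until = t + params.visual_ms / 1000.0
            else:
                state = "dwell"
                state_until = t + params.dwell_s

        # tracking disturbance; corrected only when attention is free
        e += params.track_sigma * math.sqrt(dt) * rng.normal()
        if state == "idle":
            e -= params.track_gain * e * dt
        e = max(-params.track_bound, min(params.track_bound, e))
        track[ti] = abs(e)

    resp_df = pd.DataFrame(
        responses,
        columns=[
            "event_time",
            "response_time_s",
            "correct",
            "subtask",
            "event_type",
            "condition",
        ],
    )
    return BehavioralRecord(
        responses=resp_df,
        tracking_error=track,
        tick_times=tick_times,
        duration_s=duration,
        misses=misses,
        retrieval_intervals=retrieval_intervals,
        blocks=blocks,
        params=replace(params),
    )


def summarize_bins(record: BehavioralRecord, bin_minutes: float = 2.0) -> pd.DataFrame:
    """Per-bin mean correct reaction time and tracking RMS.

    One row per time bin (default 2 min), with the mean and SD of
    correct-response RTs and the root-mean-square tracking error.  Bins
    without a correct response carry NaN and are flagged.
    """
    if record.duration_s <= 0:
        raise ValueError("record has no duration to bin")
    bin_s = bin_minutes * 60.0
    n_bins = int(math.ceil(record.duration_s / bin_s - 1e-9))
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_s, (b + 1) * bin_s
        label = f"{int(lo // 60)}–{int(min(hi, record.duration_s) // 60)}"
        sel = record.responses[
            (record.responses["event_time"] >= lo)
            & (record.responses["event_time"] < hi)
            & record.responses["correct"]
        ]
        rt_mean = float(sel["response_time_s"].mean()) if len(sel) else float("nan")
        rt_sd = float(sel["response_time_s"].std()) if len(sel) > 1 else float("nan")
        mask = (record.tick_times >= lo) & (record.tick_times < hi)
        rms = float(np.sqrt(np.mean(record.tracking_error[mask] ** 2)))
        cond = None
        for name, s, e in record.blocks:
            if s <= lo < e:
                cond = name
                break
        rows.append(
            (label, cond, rt_mean, rt_sd, len(sel), rms, len(sel) == 0)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bin",
            "condition",
            "correct_rt_mean_s",
            "correct_rt_sd_s",
            "n_correct",
            "tracking_rms",
            "no_correct_responses",
        ],
    )
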