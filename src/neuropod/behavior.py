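"""Two-bottle choice behavior and optogenetic stimulation schedules.

Phenotyping cages report cumulative food and liquid intake every 5 s to the
nearest 0.01 g.  The raw streams occasionally dip (sensor noise reads as
negative intake); cleaning enforces a monotone non-decreasing stream by the
carry-forward rule: any reading lower than its predecessor is replaced by the
most recent value, left to right.

On cleaned streams the module computes 1-min binned intake curves, the
sucrose preference (100 x sucrose / total), the stable-preference criterion
used to admit animals to inhibition experiments (>66% in two consecutive
tests, differing by at most 15 percentage points), and the two laser
schedules: the periodic 1-min-on / 2-min-off TTL program and the
intake-triggered program (5 s of stimulation per 0.01 g consumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntakeStream",
    "ChoiceSession",
    "PreferenceResult",
    "StimulationSchedule",
    "clean_intake",
    "bin_intake",
    "compute_preference",
    "stable_preference",
    "periodic_schedule",
    "intake_triggered_schedule",
]

TICK_S = 5.0
QUANTUM_G = 0.01


@dataclass(frozen=True)
class IntakeStream:
    """Cumulative intake readings at uniform 5-s ticks."""

    timestamps: np.ndarray
    cumulative_g: np.ndarray
    channel: str = "bottle_a"

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        g = np.asarray(self.cumulative_g, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "cumulative_g", g)
        if t.size != g.size:
            raise ValueError("timestamps and readings must have equal length")
        if t.size > 1:
            dt = np.diff(t)
            if not np.all(dt > 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0]):
                raise ValueError("timestamps must be uniformly spaced")
        if g.size and g.min() < 0:
            raise ValueError("negative intake readings are invalid")

    @property
    def tick_s(self) -> float:
        return float(np.diff(self.timestamps)[0]) if self.timestamps.size > 1 else TICK_S


@dataclass(frozen=True)
class ChoiceSession:
    """A 1-h two-bottle session (sucrose vs sucralose)."""

    sucrose: IntakeStream
    sucralose: IntakeStream
    session_min: float = 60.0


@dataclass(frozen=True)
class PreferenceResult:
    sucrose_g: float
    sucralose_g: float
    total_g: float
    preference_pct: float | None  # None (flagged) when nothing was consumed

    @property
    def undefined(self) -> bool:
        return self.preference_pct is None


@dataclass(frozen=True)
class StimulationSchedule:
    """Laser on-intervals plus pulse parameters.

    ``intervals`` is an (n, 2) array of non-overlapping, sorted
    ``(start_s, end_s)`` on-periods; within each, the laser pulses at
    ``freq_hz`` with the stated duty fraction and amplitude.
    """

    intervals: np.ndarray
    freq_hz: float = 40.0
    duty: float = 0.2
    amplitude_v: float = 5.0
    provenance: str = "periodic"
    n_triggers: int | None = None

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        if not 0 < self.duty <= 1:
            raise ValueError("duty fraction must be in (0, 1]")
        if iv.size:
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("intervals must have positive length")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("intervals must be sorted and non-overlapping")

    @property
    def total_on_s(self) -> float:
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0])) if self.intervals.size else 0.0

    @property
    def pulse_width_s(self) -> float:
        return self.duty / self.freq_hz


def clean_intake(raw: IntakeStream) -> tuple[IntakeStream, int]:
    """Enforce a monotone non-decreasing stream by carry-forward.

    Left to right, any reading lower than its (already corrected) predecessor
    is replaced by that most recent value.  Returns the cleaned stream and
    the number of replaced readings.  Idempotent, and never decreases a
    reading.
    """
    g = raw.cumulative_g.copy()
    corrections = 0
    for i in range(1, g.size):
        if g[i] < g[i - 1]:
            g[i] = g[i - 1]
            corrections += 1
    return IntakeStream(raw.timestamps, g, raw.channel), corrections


def bin_intake(stream: IntakeStream, bin_s: float = 60.0) -> pd.DataFrame:
    """Cumulative intake sampled at the end of each bin (default 1 min)."""
    t = stream.timestamps
    g = stream.cumulative_g
    start = t[0]
    edges = np.arange(start + bin_s, t[-1] + bin_s / 2, bin_s)
    idx = np.searchsorted(t, edges, side="right") - 1
    return pd.DataFrame(
        {"time_s": edges, "cumulative_g": g[idx] - g[0]}
    )


def compute_preference(session: ChoiceSession) -> tuple[PreferenceResult, pd.DataFrame]:
    """Preference at the end of the session, plus per-minute cumulative curves.

    Intakes are referenced to the session-start reading of each (cleaned)
    stream; preference = 100 x sucrose / (sucrose + sucralose).  A session in
    which nothing was consumed has an undefined preference, flagged as None.
    """
    curves = []
    intakes = {}
    for name, stream in (("sucrose", session.sucrose), ("sucralose", session.sucralose)):
        if np.any(np.diff(stream.cumulative_g) < 0):
            raise ValueError(f"{name} stream is not cleaned (negative increments present)")
        end = stream.timestamps[0] + session.session_min * 60.0
        mask = stream.timestamps <= end
        intakes[name] = float(stream.cumulative_g[mask][-1] - stream.cumulative_g[0])
        curve = bin_intake(stream)
        curve = curve[curve["time_s"] <= end].assign(channel=name)
        curves.append(curve)
    total = intakes["sucrose"] + intakes["sucralose"]
    pref = 100.0 * intakes["sucrose"] / total if total > 0 else None
    result = PreferenceResult(
        sucrose_g=intakes["sucrose"],
        sucralose_g=intakes["sucralose"],
        total_g=total,
        preference_pct=pref,
    )
    return result, pd.concat(curves, ignore_index=True)


def stable_preference(
    test_prefs, threshold_pct: float = 66.0, max_delta_pct: float = 15.0
) -> tuple[bool, tuple | None]:
    """Stable-preference rule for admission to inhibition experiments.

    True iff some pair of consecutive tests are both strictly above
    ``threshold_pct`` and differ by at most ``max_delta_pct`` percentage
    points.  Returns the first qualifying pair of indices (i, i+1), or None.
    """
    prefs = list(test_prefs)
    if len(prefs) < 2:
        raise ValueError("need at least two tests")
    for i in range(len(prefs) - 1):
        a, b = prefs[i], prefs[i + 1]
        if a > threshold_pct and b > threshold_pct and abs(a - b) <= max_delta_pct:
            return True, (i, i + 1)
    return False, None


def periodic_schedule(
    duration_min: float = 60.0,
    on_min: float = 1.0,
    off_min: float = 2.0,
    freq_hz: float = 40.0,
    duty: float = 0.2,
    amplitude_v: float = 5.0,
    start_on: bool = True,
) -> StimulationSchedule:
    """The cage TTL program: cycles of 1 min on / 2 min off for the session.

    Sessions begin with the laser on (``start_on``); the cycle period is
    ``on_min + off_min`` and tiles the session exactly, truncating a final
    partial interval at the session end.
    """
    if on_min + off_min <= 0:
        raise ValueError("cycle length must be positive")
    duration_s = duration_min * 60.0
    on_s, off_s = on_min * 60.0, off_min * 60.0
    period = on_s + off_s
    intervals = []
    t = 0.0 if start_on else off_s
    while t < duration_s:
        intervals.append((t, min(t + on_s, duration_s)))
        t += period
    return StimulationSchedule(
        np.asarray(intervals, dtype=float),
        freq_hz=freq_hz,
        duty=duty,
        amplitude_v=amplitude_v,
        provenance="periodic",
    )


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    if intervals.size == 0:
        return intervals.reshape(0, 2)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def intake_triggered_schedule(
    stream: IntakeStream,
    trigger_g: float = QUANTUM_G,
    stim_s: float = 5.0,
    freq_hz: float = 40.0,
    duty: float = 0.2,
    amplitude_v: float = 5.0,
) -> StimulationSchedule:
    """Intake-triggered program: each 0.01 g consumed fires 5 s of laser.

    Triggers are derived from the cleaned cumulative stream: each new
    ``trigger_g`` quantum emits an on-interval of ``stim_s`` seconds starting
    at its tick.  Overlapping or simultaneous intervals are merged (the
    hardware cannot double-fire), so the number of *triggers* (floor of total
    intake / ``trigger_g``) can exceed the number of merged intervals.
    """
    if trigger_g <= 0:
        raise ValueError("trigger_g must be positive")
    g = stream.cumulative_g
    if np.any(np.diff(g) < 0):
        raise ValueError("stream must be cleaned before scheduling")
    quanta = np.floor((g - g[0]) / trigger_g + 1e-9).astype(int)
    new = np.diff(quanta, prepend=quanta[0])
    tick_idx = np.flatnonzero(new > 0)
    starts = stream.timestamps[tick_idx] - stream.timestamps[0]
    intervals = _merge_intervals(np.column_stack([starts, starts + stim_s]))
    return StimulationSchedule(
        intervals,
        freq_hz=freq_hz,
        duty=duty,
        amplitude_v=amplitude_v,
        provenance="intake-triggered",
        n_triggers=int(quanta[-1]),
    )
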