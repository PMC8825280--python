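"""Calcium-imaging response classification.

Two acquisition modes are supported:

* ratiometric in vitro imaging of dissociated cells loaded with Fluo-4 and
  Fura Red: responses are called on the ratio R = Fluo-4 / Fura Red, a
  positive response being an increase of more than 10% over a five-frame
  pre-stimulus baseline, with a terminal 50 mM KCl depolarization serving as
  a viability gate (same 10% rule);
* single-channel in vivo GCaMP imaging of vagal nodose neurons: the trace is
  expressed as dF/F relative to the run mean and a response is an increase of
  more than 20% over the pre-stimulus dF/F level.

Responder overlap between two stimuli (e.g. d-glucose vs sucralose) is
summarized as a Venn-style partition with percentages reported both over
responders and over all viable units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RatiometricTrace",
    "DffTrace",
    "StimulusCall",
    "ResponseCall",
    "VennSummary",
    "compute_ratio",
    "call_response",
    "viability_gate",
    "normalize_to_kcl",
    "classify_trace",
    "compute_dff",
    "call_dff_response",
    "classify_dff_trace",
    "venn_summary",
]

RATIO_THRESHOLD = 0.10  #: in vitro call threshold (fractional increase, strict)
DFF_THRESHOLD = 0.20  #: in vivo call threshold (dF/F increase over pre-stimulus level)


@dataclass(frozen=True)
class RatiometricTrace:
    """Two-channel fluorescence time series for one cell.

    ``stimulus_windows`` is a list of ``(name, onset_s, duration_s)`` in time
    order; ``kcl_window`` is ``(onset_s, duration_s)`` of the terminal KCl
    depolarization.
    """

    times: np.ndarray
    fluo4: np.ndarray
    furared: np.ndarray
    cell_id: str
    stimulus_windows: list
    kcl_window: tuple

    def __post_init__(self):
        for name in ("times", "fluo4", "furared"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.times.size == self.fluo4.size == self.furared.size):
            raise ValueError("channel and time arrays must have equal length")


@dataclass(frozen=True)
class DffTrace:
    """Single-channel fluorescence time series for one neuron."""

    times: np.ndarray
    f: np.ndarray
    neuron_id: str
    stimulus_windows: list

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "f", np.asarray(self.f, dtype=float))
        if self.times.size != self.f.size:
            raise ValueError("times and f must have equal length")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("fluorescence contains non-finite values")


@dataclass(frozen=True)
class StimulusCall:
    responded: bool
    peak_fractional_increase: float
    baseline_used: float


@dataclass(frozen=True)
class ResponseCall:
    """Per-unit classification: viability plus per-stimulus calls."""

    unit_id: str
    viable: bool
    calls: dict = field(default_factory=dict)  # stimulus name -> StimulusCall
    kcl_peak: float | None = None

    def responded_to(self, stimulus: str) -> bool:
        call = self.calls.get(stimulus)
        return bool(call is not None and call.responded)


@dataclass(frozen=True)
class VennSummary:
    """Responder-overlap partition of a viable population."""

    n_viable: int
    n_responders: int
    n_a_only: int
    n_b_only: int
    n_both: int
    n_nonresponders_viable: int
    pct_of_responders: dict
    pct_of_viable: dict
    no_responders: bool = False


def compute_ratio(trace: RatiometricTrace) -> np.ndarray:
    """R(t) = Fluo-4(t) / Fura Red(t); Fura Red must be strictly positive."""
    bad = np.flatnonzero(trace.furared <= 0)
    if bad.size:
        raise ValueError(
            f"Fura Red channel non-positive at frame {int(bad[0])} "
            f"(cell {trace.cell_id}); ratio undefined"
        )
    return trace.fluo4 / trace.furared


def _window_mask(times: np.ndarray, onset: float, duration: float) -> np.ndarray:
    return (times >= onset) & (times < onset + duration)


def _pre_window_baseline(
    times: np.ndarray, values: np.ndarray, onset: float, n_frames: int
) -> float:
    pre = np.flatnonzero(times < onset)
    if pre.size < n_frames:
        raise ValueError(
            f"need {n_frames} frames before the window at t={onset} s, have {pre.size}"
        )
    return float(values[pre[-n_frames:]].mean())


def call_response(
    times: np.ndarray,
    ratio: np.ndarray,
    window: tuple,
    baseline_frames: int = 5,
    threshold_frac: float = RATIO_THRESHOLD,
    baseline: float | None = None,
) -> StimulusCall:
    """Call one stimulus window on a ratio series.

    The baseline is the mean of the ``baseline_frames`` frames immediately
    preceding the window onset (or the supplied ``baseline``).  The call is
    positive iff the maximum fractional increase over the window strictly
    exceeds ``threshold_frac``.
    """
    onset, duration = window
    if baseline is None:
        baseline = _pre_window_baseline(times, ratio, onset, baseline_frames)
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    mask = _window_mask(times, onset, duration)
    if not mask.any():
        raise ValueError("stimulus window contains no frames")
    peak = float(np.max((ratio[mask] - baseline) / baseline))
    return StimulusCall(responded=peak > threshold_frac, peak_fractional_increase=peak,
                        baseline_used=baseline)


def viability_gate(
    times: np.ndarray,
    ratio: np.ndarray,
    kcl_window: tuple,
    baseline_frames: int = 5,
    threshold_frac: float = RATIO_THRESHOLD,
) -> tuple[bool, float]:
    """KCl viability gate: viable iff the KCl ratio increase exceeds 10%.

    Returns ``(viable, kcl_peak_fractional_increase)``.
    """
    call = call_response(times, ratio, kcl_window, baseline_frames, threshold_frac)
    return call.responded, call.peak_fractional_increase


def normalize_to_kcl(peaks: dict, kcl_peak: float) -> dict:
    """Express per-stimulus peak increases as fractions of the KCl peak."""
    if kcl_peak <= 0:
        raise ValueError("KCl peak must be positive for normalization")
    return {name: p / kcl_peak for name, p in peaks.items()}


def classify_trace(
    trace: RatiometricTrace,
    baseline_frames: int = 5,
    threshold_frac: float = RATIO_THRESHOLD,
    rebaseline: bool = True,
) -> ResponseCall:
    """Ratio -> viability gate -> per-stimulus calls for one cell.

    Non-viable cells (KCl increase <= 10%) carry no stimulus calls.  With
    ``rebaseline`` (the default) each stimulus uses a fresh five-frame
    baseline taken immediately before its own window; otherwise all windows
    share the baseline preceding the first window.
    """
    ratio = compute_ratio(trace)
    viable, kcl_peak = viability_gate(
        trace.times, ratio, trace.kcl_window, baseline_frames, threshold_frac
    )
    if not viable:
        return ResponseCall(trace.cell_id, viable=False, calls={}, kcl_peak=kcl_peak)
    windows = sorted(trace.stimulus_windows, key=lambda w: w[1])
    initial_baseline = _pre_window_baseline(
        trace.times, ratio, windows[0][1], baseline_frames
    )
    calls = {}
    for name, onset, duration in windows:
        baseline = None if rebaseline else initial_baseline
        calls[name] = call_response(
            trace.times, ratio, (onset, duration), baseline_frames, threshold_frac,
            baseline=baseline,
        )
    return ResponseCall(trace.cell_id, viable=True, calls=calls, kcl_peak=kcl_peak)


def compute_dff(trace: DffTrace) -> np.ndarray:
    """dF/F = (F - mean F of the entire run) / mean F; mean is exactly zero."""
    mean = float(trace.f.mean()) if trace.f.size else 0.0
    if mean <= 0:
        raise ValueError("mean fluorescence must be positive for dF/F")
    return (trace.f - mean) / mean


def call_dff_response(
    times: np.ndarray,
    dff: np.ndarray,
    window: tuple,
    threshold_frac: float = DFF_THRESHOLD,
    pre_window: tuple | None = None,
) -> StimulusCall:
    """Call one stimulus on a dF/F series.

    Because dF/F is defined against the run mean, "baseline" is taken as the
    mean dF/F over the pre-stimulus frames (all frames before onset, or the
    frames inside ``pre_window`` if given).  The call is positive iff the
    maximum in-window dF/F exceeds that level by more than
    ``threshold_frac``.
    """
    onset, duration = window
    if pre_window is None:
        pre_mask = times < onset
    else:
        pre_mask = _window_mask(times, *pre_window)
    if not pre_mask.any():
        raise ValueError("no pre-stimulus frames available")
    level = float(dff[pre_mask].mean())
    mask = _window_mask(times, onset, duration)
    if not mask.any():
        raise ValueError("stimulus window contains no frames")
    peak = float(np.max(dff[mask]) - level)
    return StimulusCall(responded=peak > threshold_frac,
                        peak_fractional_increase=peak, baseline_used=level)


def classify_dff_trace(
    trace: DffTrace, threshold_frac: float = DFF_THRESHOLD
) -> ResponseCall:
    """dF/F -> per-stimulus calls for one in vivo neuron (no KCl gate)."""
    dff = compute_dff(trace)
    calls = {
        name: call_dff_response(trace.times, dff, (onset, duration), threshold_frac)
        for name, onset, duration in sorted(trace.stimulus_windows, key=lambda w: w[1])
    }
    return ResponseCall(trace.neuron_id, viable=True, calls=calls)


def venn_summary(calls: list, stim_a: str, stim_b: str) -> VennSummary:
    """Partition viable units into a-only / b-only / both / neither.

    Percentages are reported over responders (as in dissociated-cell and
    coculture summaries) and over all viable units (as in the in vivo
    summaries).  Non-viable units must be excluded before calling.
    """
    viable = [c for c in calls if c.viable]
    if not viable:
        raise ValueError("no viable units to summarize")
    if any(not c.viable for c in calls):
        raise ValueError("venn_summary expects only viable units")
    a = np.array([c.responded_to(stim_a) for c in viable])
    b = np.array([c.responded_to(stim_b) for c in viable])
    n_both = int((a & b).sum())
    n_a_only = int((a & ~b).sum())
    n_b_only = int((~a & b).sum())
    n_resp = n_a_only + n_b_only + n_both
    n_viable = len(viable)
    n_neither = n_viable - n_resp
    classes = {"a_only": n_a_only, "b_only": n_b_only, "both": n_both}
    if n_resp:
        pct_resp = {k: 100.0 * v / n_resp for k, v in classes.items()}
    else:
        pct_resp = {k: float("nan") for k in classes}
    pct_viable = {k: 100.0 * v / n_viable for k, v in classes.items()}
    pct_viable["neither"] = 100.0 * n_neither / n_viable
    return VennSummary(
        n_viable=n_viable,
        n_responders=n_resp,
        n_a_only=n_a_only,
        n_b_only=n_b_only,
        n_both=n_both,
        n_nonresponders_viable=n_neither,
        pct_of_responders=pct_resp,
        pct_of_viable=pct_viable,
        no_responders=n_resp == 0,
    )
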