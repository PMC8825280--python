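"""Whole-nerve extracellular electrophysiology.

Converts a raw multiunit voltage trace recorded from the cervical vagus nerve
into a spike train (RMS-threshold detection), a smoothed firing-rate series
(Gaussian kernel evaluated on a regular bin grid) and baseline-normalized
response metrics for intraduodenal infusion epochs.

No spike sorting is attempted: the recording is compound afferent activity and
all supra-threshold events are pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VoltageTrace",
    "SpikeTrain",
    "FiringRateSeries",
    "InfusionEvent",
    "ResponseMetrics",
    "detect_spikes",
    "estimate_firing_rate",
    "normalize_to_baseline",
    "quantify_response",
    "analyze_recording",
]


@dataclass(frozen=True)
class VoltageTrace:
    """A raw extracellular recording.

    Parameters
    ----------
    samples : ndarray
        Voltage in microvolts.
    sampling_rate : float
        Samples per second (Hz); must be positive.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("voltage trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times (s), strictly increasing."""

    spike_times: np.ndarray
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.spike_times.size


@dataclass(frozen=True)
class FiringRateSeries:
    """Smoothed firing rate (Hz) evaluated at regular bin centers."""

    bin_centers: np.ndarray
    rate: np.ndarray
    bin_width: float
    kernel_sigma: float

    def __post_init__(self):
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, dtype=float))
        object.__setattr__(self, "rate", np.asarray(self.rate, dtype=float))
        if self.bin_centers.shape != self.rate.shape:
            raise ValueError("bin_centers and rate must have the same shape")

    def mean_rate(self, t_start: float | None = None, t_end: float | None = None) -> float:
        """Mean rate over [t_start, t_end] (whole series by default)."""
        mask = np.ones(self.bin_centers.size, dtype=bool)
        if t_start is not None:
            mask &= self.bin_centers >= t_start
        if t_end is not None:
            mask &= self.bin_centers <= t_end
        if not mask.any():
            raise ValueError("requested window contains no bins")
        return float(self.rate[mask].mean())


@dataclass(frozen=True)
class InfusionEvent:
    """A 1-min intraluminal infusion and its analysis window.

    ``window_end`` defaults to ``onset + 360`` s: successive infusions were
    separated by at least six minutes, so the response window runs to the
    earliest possible next stimulus.
    """

    stimulus: str
    onset: float
    duration: float = 60.0
    window_end: float | None = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")
        if self.onset < 0:
            raise ValueError("infusion onset must be >= 0")
        if self.window_end is None:
            object.__setattr__(self, "window_end", self.onset + 360.0)
        if self.window_end <= self.onset:
            raise ValueError("window_end must be after onset")


@dataclass(frozen=True)
class ResponseMetrics:
    """Baseline-normalized response metrics for one infusion."""

    stimulus: str
    baseline_rate: float
    peak_norm: float
    time_to_peak: float
    auc: float
    raw_peak_rate: float | None = None


def _rms(trace: VoltageTrace, rms_window_s: float | None) -> float:
    v = trace.samples
    if rms_window_s is not None:
        n = int(round(rms_window_s * trace.sampling_rate))
        if n <= 0:
            raise ValueError("rms_window_s too short for the sampling rate")
        v = v[:n]
    return float(np.sqrt(np.mean(v**2))) if v.size else 0.0


def detect_spikes(
    trace: VoltageTrace,
    k: float = 4.0,
    rms_window_s: float | None = None,
    refractory_s: float = 1e-3,
) -> SpikeTrain:
    """Detect multiunit spikes by RMS-threshold crossing.

    The threshold is ``k`` times the RMS of the trace (computed over the first
    ``rms_window_s`` seconds if given, else the whole trace).  Each contiguous
    excursion of ``|v|`` above threshold yields one spike at the time of its
    absolute-amplitude extremum; excursions starting within ``refractory_s``
    of the previous spike are merged into it.

    An all-zero trace yields an empty train (RMS is zero, nothing crosses).
    """
    if trace.samples.size == 0:
        raise ValueError("empty voltage trace")
    if k <= 0:
        raise ValueError("threshold multiplier k must be positive")
    rms = _rms(trace, rms_window_s)
    params = {"k": k, "rms": rms, "rms_window_s": rms_window_s, "refractory_s": refractory_s}
    if rms == 0.0:
        return SpikeTrain(np.empty(0), params)
    threshold = k * rms
    above = np.abs(trace.samples) > threshold
    if not above.any():
        return SpikeTrain(np.empty(0), params)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    abs_v = np.abs(trace.samples)
    times = []
    last = -math.inf
    fs = trace.sampling_rate
    for s, e in zip(starts, ends):
        peak_idx = s + int(np.argmax(abs_v[s:e]))
        t_start = trace.start_time + s / fs
        if t_start - last < refractory_s:
            continue  # merged into the previous spike
        t = trace.start_time + peak_idx / fs
        times.append(t)
        last = t
    return SpikeTrain(np.asarray(times), params)


def estimate_firing_rate(
    train: SpikeTrain,
    t_start: float,
    t_end: float,
    bin_width_s: float = 0.2,
    kernel_sigma_s: float = 0.2,
) -> FiringRateSeries:
    """Gaussian-kernel firing-rate estimate on a regular 200-ms bin grid.

    rate(t) = sum_i N(t - t_i; sigma), so the integral of the rate equals the
    spike count for spikes well inside [t_start, t_end] (edge mass is lost for
    spikes within a few sigma of the boundaries; no padding is applied).
    """
    if t_end <= t_start:
        raise ValueError("t_end must be after t_start")
    if kernel_sigma_s <= 0:
        raise ValueError("kernel sigma must be positive")
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(round((t_end - t_start) / bin_width_s))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    centers = t_start + bin_width_s * (np.arange(n_bins) + 0.5)
    spikes = train.spike_times
    rate = np.zeros(n_bins)
    if spikes.size:
        norm = 1.0 / (kernel_sigma_s * math.sqrt(2.0 * math.pi))
        # chunk the spike axis to bound peak memory on long recordings
        chunk = max(1, int(5e6 // max(n_bins, 1)))
        for i in range(0, spikes.size, chunk):
            d = centers[:, None] - spikes[None, i : i + chunk]
            rate += norm * np.exp(-0.5 * (d / kernel_sigma_s) ** 2).sum(axis=1)
    return FiringRateSeries(centers, rate, bin_width_s, kernel_sigma_s)


def normalize_to_baseline(
    series: FiringRateSeries,
    baseline_start: float = 0.0,
    baseline_dur_s: float = 120.0,
    mode: str = "ratio",
) -> tuple[FiringRateSeries, float]:
    """Normalize a rate series to its prestimulus baseline (first 2 min).

    ``mode='ratio'`` (default) returns rate / baseline-mean (fold of
    baseline); ``mode='subtract'`` returns rate - baseline-mean (Hz).
    A zero baseline mean cannot be used as a ratio denominator and raises.
    """
    mask = (series.bin_centers >= baseline_start) & (
        series.bin_centers <= baseline_start + baseline_dur_s
    )
    if not mask.any():
        raise ValueError("series does not cover the baseline window")
    baseline = float(series.rate[mask].mean())
    if mode == "ratio":
        if baseline == 0.0:
            raise ValueError(
                "baseline mean rate is zero; ratio normalization is undefined - "
                "analyze raw rates or use mode='subtract'"
            )
        normalized = series.rate / baseline
    elif mode == "subtract":
        normalized = series.rate - baseline
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return (
        FiringRateSeries(series.bin_centers, normalized, series.bin_width, series.kernel_sigma),
        baseline,
    )


def quantify_response(
    series: FiringRateSeries,
    event: InfusionEvent,
    baseline_rate: float | None = None,
    positive_part_auc: bool = False,
) -> ResponseMetrics:
    """Quantify a stimulation response on a baseline-normalized series.

    * ``peak_norm``: maximum normalized rate in [onset, window_end];
    * ``time_to_peak``: time from infusion onset to that maximum;
    * ``auc``: trapezoidal integral of (normalized - 1) over the window
      (signed by default; ``positive_part_auc`` floors each bin at zero).
    """
    mask = (series.bin_centers >= event.onset) & (series.bin_centers <= event.window_end)
    if not mask.any():
        raise ValueError("event window not covered by the series")
    t = series.bin_centers[mask]
    r = series.rate[mask]
    peak_idx = int(np.argmax(r))
    peak = float(r[peak_idx])
    ttp = float(t[peak_idx] - event.onset)
    excess = r - 1.0
    if positive_part_auc:
        excess = np.maximum(excess, 0.0)
    auc = float(np.trapezoid(excess, t))
    raw_peak = peak * baseline_rate if baseline_rate is not None else None
    return ResponseMetrics(
        stimulus=event.stimulus,
        baseline_rate=baseline_rate if baseline_rate is not None else math.nan,
        peak_norm=peak,
        time_to_peak=ttp,
        auc=auc,
        raw_peak_rate=raw_peak,
    )


def analyze_recording(
    trace: VoltageTrace,
    events: Sequence[InfusionEvent],
    k: float = 4.0,
    rms_window_s: float | None = None,
    refractory_s: float = 1e-3,
    bin_width_s: float = 0.2,
    kernel_sigma_s: float = 0.2,
    baseline_dur_s: float = 120.0,
) -> tuple[SpikeTrain, FiringRateSeries, float, list[ResponseMetrics]]:
    """Full pipeline: detect -> rate -> normalize -> per-event metrics.

    Returns the spike train, the *normalized* rate series, the baseline rate
    in Hz and one :class:`ResponseMetrics` per infusion event.
    """
    train = detect_spikes(trace, k=k, rms_window_s=rms_window_s, refractory_s=refractory_s)
    series = estimate_firing_rate(
        train,
        trace.start_time,
        trace.start_time + trace.duration,
        bin_width_s=bin_width_s,
        kernel_sigma_s=kernel_sigma_s,
    )
    normalized, baseline = normalize_to_baseline(
        series, baseline_start=trace.start_time, baseline_dur_s=baseline_dur_s
    )
    metrics = [quantify_response(normalized, ev, baseline_rate=baseline) for ev in events]
    return train, normalized, baseline, metrics
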