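"""Seeded synthetic-data generators with ground-truth labels.

Each generator emulates one raw-data modality of the study at its stated
acquisition conditions and returns both the data object consumed by the
corresponding analysis module and a :class:`GroundTruth` record of the design
(exact spike times, designed responder classes, planted effects, true
preference, true attenuation).  Identical parameters and seed reproduce
byte-identical output.

Design conventions (the data, not the biology, is simulated):

* voltage noise is additive Gaussian; spikes are a stereotyped biphasic 1-ms
  template scaled to the requested amplitude, at times drawn from an
  inhomogeneous Poisson process with a piecewise-constant rate;
* calcium responses are triangular transients whose designed peak fractional
  increases sit safely on either side of the 10% call threshold (ambiguous
  designs within +-1% of the threshold are rejected);
* detected Cq values are Normal, truncated below the detection cutoff, with
  undetected wells drawn as Bernoulli dropout;
* intake streams are 0.01-g-quantized cumulative counts with optional
  one-tick negative sensor dips;
* cut-back optics follow the exponential (dB-linear) attenuation law with
  multiplicative lognormal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import IntakeStream, QUANTUM_G
from .biophys import CutbackSeries
from .calcium import DffTrace, RatiometricTrace
from .ephys import VoltageTrace
from .qpcr import HOUSEKEEPING_GENES, CqMatrix

__all__ = [
    "GroundTruth",
    "gen_vagal_recording",
    "gen_calcium_population",
    "gen_dff_population",
    "gen_cq_matrix",
    "gen_receptor_cells",
    "gen_intake_session",
    "gen_cutback",
]


@dataclass(frozen=True)
class GroundTruth:
    """What a generator designed, for recovery checks downstream."""

    kind: str
    params: dict
    labels: dict
    seed: int


# ---------------------------------------------------------------------------
# vagal electrophysiology
# ---------------------------------------------------------------------------

def _spike_template(sampling_rate_hz: float, amplitude_uv: float,
                    width_s: float = 1e-3) -> np.ndarray:
    """Biphasic extracellular waveform: one full sine cycle over ~1 ms.

    The negative lobe leads (classic extracellular polarity); peak absolute
    amplitude equals ``amplitude_uv``.
    """
    n = max(3, int(round(width_s * sampling_rate_hz)))
    t = np.arange(n) / (n - 1)
    return -amplitude_uv * np.sin(2.0 * math.pi * t)


def _piecewise_rate_segments(duration_s, baseline_rate_hz, response_profile):
    """Break [0, duration] into constant-rate segments from the profile."""
    edges = {0.0, float(duration_s)}
    for onset, dur, _ in response_profile:
        if onset < 0 or onset + dur > duration_s:
            raise ValueError(
                f"response window ({onset}, {onset + dur}) falls outside the recording"
            )
        edges.update((float(onset), float(onset + dur)))
    edges = sorted(edges)
    segments = []
    for a, b in zip(edges[:-1], edges[1:]):
        mult = 1.0
        for onset, dur, m in response_profile:
            if m < 0:
                raise ValueError("rate multipliers must be >= 0")
            if onset <= a and b <= onset + dur:
                mult *= m
        segments.append((a, b, baseline_rate_hz * mult))
    return segments


def draw_poisson_spike_times(duration_s, baseline_rate_hz, response_profile,
                             rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous (piecewise-constant) Poisson spike times, sorted."""
    times = []
    for a, b, rate in _piecewise_rate_segments(duration_s, baseline_rate_hz,
                                               response_profile):
        if rate <= 0:
            continue
        n = rng.poisson(rate * (b - a))
        times.append(np.sort(rng.uniform(a, b, n)))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def gen_vagal_recording(
    duration_s: float = 300.0,
    sampling_rate_hz: float = 20_000.0,
    baseline_rate_hz: float = 10.0,
    response_profile: list | None = None,
    spike_amplitude_uv: float = 60.0,
    noise_sd_uv: float = 3.0,
    seed: int = 0,
) -> tuple[VoltageTrace, GroundTruth]:
    """Simulate a whole-nerve recording with stimulus-locked rate increases.

    ``response_profile`` is a list of ``(onset_s, duration_s, rate_multiplier)``
    epochs; the multiunit rate is ``baseline_rate_hz`` outside them and
    baseline x multiplier inside.  The trace is Gaussian noise plus a
    stereotyped biphasic 1-ms template at each true spike time; the truth
    labels carry the exact spike times.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    response_profile = list(response_profile or [])
    rng = np.random.default_rng(seed)
    spike_times = draw_poisson_spike_times(
        duration_s, baseline_rate_hz, response_profile, rng
    )
    n_samples = int(round(duration_s * sampling_rate_hz))
    v = rng.normal(0.0, noise_sd_uv, n_samples)
    template = _spike_template(sampling_rate_hz, spike_amplitude_uv)
    for t in spike_times:
        i = int(round(t * sampling_rate_hz))
        j = min(i + template.size, n_samples)
        v[i:j] += template[: j - i]
    trace = VoltageTrace(v, sampling_rate_hz)
    truth = GroundTruth(
        kind="vagal_recording",
        params={
            "duration_s": duration_s,
            "sampling_rate_hz": sampling_rate_hz,
            "baseline_rate_hz": baseline_rate_hz,
            "response_profile": response_profile,
            "spike_amplitude_uv": spike_amplitude_uv,
            "noise_sd_uv": noise_sd_uv,
        },
        labels={"spike_times": spike_times},
        seed=seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# calcium imaging
# ---------------------------------------------------------------------------

#: in vitro protocol layout (s): two 15-s stimuli with 30-s buffer between,
#: a terminal KCl depolarization, 210-s total run
INVITRO_LAYOUT = {
    "total_s": 210.0,
    "stim_a": (45.0, 15.0),
    "stim_b": (90.0, 15.0),
    "kcl": (165.0, 30.0),
}


def _triangular_bump(times, onset, duration):
    """Unit-peak triangular transient spanning the window."""
    mid = onset + duration / 2.0
    half = duration / 2.0
    return np.clip(1.0 - np.abs(times - mid) / half, 0.0, None)


def _check_margin(name, frac, threshold=0.10, margin=0.01):
    if abs(frac - threshold) <= margin:
        raise ValueError(
            f"{name}={frac} is within +-{margin} of the {threshold} call threshold; "
            "the designed population would be ambiguous - choose a value with margin"
        )


def gen_calcium_population(
    n_neither: int = 21,
    n_a_only: int = 14,
    n_b_only: int = 4,
    n_both: int = 8,
    n_nonviable: int = 0,
    frame_interval_s: float = 1.5,
    responder_peak_frac: float = 0.25,
    nonresponder_peak_frac: float = 0.05,
    kcl_peak_frac: float = 0.15,
    noise_sd_frac: float = 0.002,
    stim_names: tuple = ("glucose", "sucralose"),
    seed: int = 0,
) -> tuple[list[RatiometricTrace], GroundTruth]:
    """Simulate a dissociated-cell ratiometric imaging session.

    Cells are designed into five classes: responders to stimulus A only, B
    only, both, viable non-responders ("neither", i.e. KCl-only) and
    non-viable cells whose KCl transient stays below the gate.  Peak
    fractional increases are placed with safe margins around the 10% call
    threshold so the downstream classifier recovers the design exactly;
    designs within +-1% of the threshold are rejected.
    """
    counts = dict(neither=n_neither, a_only=n_a_only, b_only=n_b_only,
                  both=n_both, nonviable=n_nonviable)
    if any(c < 0 for c in counts.values()):
        raise ValueError("class counts must be >= 0")
    if not responder_peak_frac > 0.10 > nonresponder_peak_frac:
        raise ValueError(
            "need responder_peak_frac > 0.10 > nonresponder_peak_frac for an "
            "unambiguous design"
        )
    for name, frac in (
        ("responder_peak_frac", responder_peak_frac),
        ("nonresponder_peak_frac", nonresponder_peak_frac),
        ("kcl_peak_frac", kcl_peak_frac),
    ):
        _check_margin(name, frac)
    rng = np.random.default_rng(seed)
    layout = INVITRO_LAYOUT
    times = np.arange(0.0, layout["total_s"], frame_interval_s)
    windows = [
        (stim_names[0], *layout["stim_a"]),
        (stim_names[1], *layout["stim_b"]),
    ]
    classes = [c for c, n in counts.items() for _ in range(n)]
    rng.shuffle(classes)
    traces, labels = [], []
    for i, cls in enumerate(classes):
        cell_id = f"cell{i:03d}"
        r0 = 1.0 + 0.05 * rng.standard_normal()
        ratio = np.full_like(times, r0)
        peak_a = responder_peak_frac if cls in ("a_only", "both") else nonresponder_peak_frac
        peak_b = responder_peak_frac if cls in ("b_only", "both") else nonresponder_peak_frac
        peak_k = nonresponder_peak_frac if cls == "nonviable" else kcl_peak_frac
        ratio += r0 * peak_a * _triangular_bump(times, *layout["stim_a"])
        ratio += r0 * peak_b * _triangular_bump(times, *layout["stim_b"])
        ratio += r0 * peak_k * _triangular_bump(times, *layout["kcl"])
        ratio += r0 * noise_sd_frac * rng.standard_normal(times.size)
        furared = 1000.0 * (1.0 + 0.1 * rng.random()) * np.ones_like(times)
        traces.append(
            RatiometricTrace(
                times=times,
                fluo4=ratio * furared,
                furared=furared,
                cell_id=cell_id,
                stimulus_windows=windows,
                kcl_window=layout["kcl"],
            )
        )
        labels.append({"cell_id": cell_id, "class": cls})
    truth = GroundTruth(
        kind="calcium_population",
        params={
            "counts": counts,
            "frame_interval_s": frame_interval_s,
            "responder_peak_frac": responder_peak_frac,
            "nonresponder_peak_frac": nonresponder_peak_frac,
            "kcl_peak_frac": kcl_peak_frac,
            "stim_names": stim_names,
        },
        labels={"cells": labels},
        seed=seed,
    )
    return traces, truth


#: in vivo protocol layout (s): 2-min baseline, two 60-s stimuli separated by
#: 2 min of buffer, 2-min tail; 683-ms frames
INVIVO_LAYOUT = {
    "total_s": 480.0,
    "stim_a": (120.0, 60.0),
    "stim_b": (300.0, 60.0),
}


def gen_dff_population(
    n_neither: int = 20,
    n_a_only: int = 22,
    n_b_only: int = 12,
    n_both: int = 0,
    frame_interval_s: float = 0.683,
    responder_peak_frac: float = 0.6,
    nonresponder_peak_frac: float = 0.05,
    noise_sd_frac: float = 0.005,
    stim_names: tuple = ("sucrose", "sucralose"),
    seed: int = 0,
) -> tuple[list[DffTrace], GroundTruth]:
    """Simulate an in vivo single-channel (GCaMP) imaging session.

    Same class-design idea as :func:`gen_calcium_population`, but traces are
    single-channel fluorescence analyzed as dF/F with the 20% call threshold;
    there is no KCl gate (all imaged neurons count).  Designed responder
    transients are large (default 60% of baseline fluorescence) so calls stay
    unambiguous after the run-mean dF/F re-referencing.
    """
    counts = dict(neither=n_neither, a_only=n_a_only, b_only=n_b_only, both=n_both)
    if any(c < 0 for c in counts.values()):
        raise ValueError("class counts must be >= 0")
    if not responder_peak_frac > 0.25 > nonresponder_peak_frac:
        raise ValueError(
            "need responder_peak_frac comfortably above the 0.20 dF/F threshold "
            "and nonresponder_peak_frac below it"
        )
    rng = np.random.default_rng(seed)
    layout = INVIVO_LAYOUT
    times = np.arange(0.0, layout["total_s"], frame_interval_s)
    windows = [
        (stim_names[0], *layout["stim_a"]),
        (stim_names[1], *layout["stim_b"]),
    ]
    classes = [c for c, n in counts.items() for _ in range(n)]
    rng.shuffle(classes)
    traces, labels = [], []
    for i, cls in enumerate(classes):
        neuron_id = f"neuron{i:03d}"
        f0 = 1000.0 * (1.0 + 0.2 * rng.random())
        f = np.full_like(times, f0)
        peak_a = responder_peak_frac if cls in ("a_only", "both") else nonresponder_peak_frac
        peak_b = responder_peak_frac if cls in ("b_only", "both") else nonresponder_peak_frac
        f += f0 * peak_a * _triangular_bump(times, *layout["stim_a"])
        f += f0 * peak_b * _triangular_bump(times, *layout["stim_b"])
        f += f0 * noise_sd_frac * rng.standard_normal(times.size)
        traces.append(
            DffTrace(times=times, f=f, neuron_id=neuron_id, stimulus_windows=windows)
        )
        labels.append({"neuron_id": neuron_id, "class": cls})
    truth = GroundTruth(
        kind="dff_population",
        params={
            "counts": counts,
            "frame_interval_s": frame_interval_s,
            "responder_peak_frac": responder_peak_frac,
            "nonresponder_peak_frac": nonresponder_peak_frac,
            "stim_names": stim_names,
        },
        labels={"neurons": labels},
        seed=seed,
    )
    return traces, truth


# ---------------------------------------------------------------------------
# single-cell RT-qPCR
# ---------------------------------------------------------------------------

def _truncated_normal_cq(rng, mean, sd, cutoff, size):
    """Normal(mean, sd) truncated above at the detection cutoff (Cq < cutoff)."""
    out = rng.normal(mean, sd, size)
    bad = out >= cutoff
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out >= cutoff
    return out


def gen_cq_matrix(
    n_cells_per_group: tuple = (60, 30),
    genes: tuple = ("Slc5a1", "Tas1r3", "Syn1", "Snap25") + HOUSEKEEPING_GENES,
    de_genes: dict | None = None,
    dropout_prob: float = 0.0,
    cq_mean: float = 26.0,
    cq_sd: float = 0.5,
    cq_cutoff: float = 34.0,
    group_labels: tuple = ("GFP+", "GFP-"),
    n_mice: int = 3,
    n_hk_missing: int = 0,
    housekeeping: tuple = HOUSEKEEPING_GENES,
    seed: int = 0,
) -> tuple[CqMatrix, GroundTruth]:
    """Simulate a Biomark-style single-cell Cq export with planted effects.

    ``de_genes`` maps gene -> log2 effect: cells of the *first* group have
    their Cq lowered by the effect (one cycle per log2 unit), so the expected
    linear RQ ratio group1/group2 is 2^effect.  Detected values are Normal
    with s.d. ``cq_sd``, truncated below the detection cutoff; non-housekeeping
    wells drop out with probability ``dropout_prob``; housekeeping genes are
    always detected except in ``n_hk_missing`` designed QC casualties that
    lack both.  Cells are assigned round-robin to ``n_mice`` animals.
    """
    de_genes = dict(de_genes or {})
    genes = tuple(genes)
    unknown = set(de_genes) - set(genes)
    if unknown:
        raise ValueError(f"effects listed for genes not in the panel: {sorted(unknown)}")
    if not cq_mean < cq_cutoff:
        raise ValueError("cq_mean must lie below the detection cutoff")
    if not 0 <= dropout_prob < 1:
        raise ValueError("dropout_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows, quality_rows, meta_rows, index = [], [], [], []
    cell_no = 0
    for g_idx, (label, n_cells) in enumerate(zip(group_labels, n_cells_per_group)):
        for c in range(n_cells):
            cell = f"{label}_c{c:03d}"
            index.append(cell)
            cq_row = {}
            for gene in genes:
                effect = de_genes.get(gene, 0.0) if g_idx == 0 else 0.0
                val = _truncated_normal_cq(rng, cq_mean - effect, cq_sd, cq_cutoff, 1)[0]
                if gene not in housekeeping and rng.random() < dropout_prob:
                    val = np.nan
                cq_row[gene] = val
            rows.append(cq_row)
            quality_rows.append({g: rng.uniform(0.75, 1.0) for g in genes})
            meta_rows.append({"group": label, "mouse_id": f"m{cell_no % n_mice + 1}"})
            cell_no += 1
    cq = pd.DataFrame(rows, index=index)[list(genes)]
    quality = pd.DataFrame(quality_rows, index=index)[list(genes)]
    metadata = pd.DataFrame(meta_rows, index=index)
    casualties = []
    if n_hk_missing:
        casualties = list(rng.choice(cq.index, size=n_hk_missing, replace=False))
        cq.loc[casualties, list(housekeeping)] = np.nan
    truth = GroundTruth(
        kind="cq_matrix",
        params={
            "n_cells_per_group": tuple(n_cells_per_group),
            "genes": genes,
            "de_genes": de_genes,
            "dropout_prob": dropout_prob,
            "cq_mean": cq_mean,
            "cq_sd": cq_sd,
            "cq_cutoff": cq_cutoff,
            "group_labels": tuple(group_labels),
        },
        labels={"de_genes": de_genes, "qc_casualties": casualties},
        seed=seed,
    )
    return CqMatrix(cq=cq, quality=quality, metadata=metadata), truth


def gen_receptor_cells(
    class_fracs: tuple = (0.20, 0.60, 0.01, 0.19),
    n_cells_per_mouse: int = 50,
    n_mice: int = 3,
    gene_a: str = "Slc5a1",
    gene_b: str = "Tas1r3",
    cq_mean: float = 26.0,
    cq_sd: float = 0.5,
    cq_cutoff: float = 34.0,
    seed: int = 0,
) -> tuple[CqMatrix, GroundTruth]:
    """Simulate cells with designed receptor-coexpression class fractions.

    ``class_fracs`` orders (neither, a_only, b_only, both) and must sum to 1;
    each mouse's cells are a multinomial draw from those fractions.  The truth
    labels carry the per-mouse designed counts.
    """
    fracs = np.asarray(class_fracs, dtype=float)
    if fracs.size != 4 or not math.isclose(fracs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("class_fracs must be four fractions summing to 1")
    rng = np.random.default_rng(seed)
    order = ["neither", "a_only", "b_only", "both"]
    genes = (gene_a, gene_b) + HOUSEKEEPING_GENES
    rows, quality_rows, meta_rows, index = [], [], [], []
    per_mouse_counts = {}
    for m in range(n_mice):
        mouse = f"m{m + 1}"
        counts = rng.multinomial(n_cells_per_mouse, fracs)
        per_mouse_counts[mouse] = dict(zip(order, (int(c) for c in counts)))
        cell_classes = [cls for cls, n in zip(order, counts) for _ in range(n)]
        rng.shuffle(cell_classes)
        for c, cls in enumerate(cell_classes):
            index.append(f"{mouse}_c{c:03d}")
            detect_a = cls in ("a_only", "both")
            detect_b = cls in ("b_only", "both")
            row = {}
            for gene, det in ((gene_a, detect_a), (gene_b, detect_b)):
                row[gene] = (
                    _truncated_normal_cq(rng, cq_mean, cq_sd, cq_cutoff, 1)[0]
                    if det else np.nan
                )
            for hk in HOUSEKEEPING_GENES:
                row[hk] = _truncated_normal_cq(rng, cq_mean, cq_sd, cq_cutoff, 1)[0]
            rows.append(row)
            quality_rows.append({g: rng.uniform(0.75, 1.0) for g in genes})
            meta_rows.append({"group": "GFP+", "mouse_id": mouse})
    cq = pd.DataFrame(rows, index=index)[list(genes)]
    quality = pd.DataFrame(quality_rows, index=index)[list(genes)]
    metadata = pd.DataFrame(meta_rows, index=index)
    truth = GroundTruth(
        kind="receptor_cells",
        params={
            "class_fracs": tuple(float(f) for f in fracs),
            "n_cells_per_mouse": n_cells_per_mouse,
            "n_mice": n_mice,
            "gene_a": gene_a,
            "gene_b": gene_b,
        },
        labels={"per_mouse_counts": per_mouse_counts},
        seed=seed,
    )
    return CqMatrix(cq=cq, quality=quality, metadata=metadata), truth


# ---------------------------------------------------------------------------
# intake behavior
# ---------------------------------------------------------------------------

def gen_intake_session(
    true_pref_frac: float = 0.9,
    total_g: float = 2.0,
    tick_s: float = 5.0,
    duration_min: float = 60.0,
    dip_prob: float = 0.0,
    dip_mag_g: float = 0.05,
    seed: int = 0,
) -> tuple[IntakeStream, IntakeStream, GroundTruth]:
    """Simulate a two-bottle session as two cumulative cage-sensor streams.

    Total intake ``total_g`` is split by ``true_pref_frac`` between the
    sucrose and sucralose bottles, quantized to 0.01 g, and spread over the
    session as random per-tick quanta.  With probability ``dip_prob`` a tick's
    reading dips by ``dip_mag_g`` (a transient sensor artifact) and reverts at
    the next tick; the cleaned stream recovers the designed finals exactly.
    """
    if not 0 <= true_pref_frac <= 1:
        raise ValueError("true_pref_frac must lie in [0, 1]")
    if total_g < 0:
        raise ValueError("total_g must be >= 0")
    if dip_mag_g <= 0:
        raise ValueError("dip_mag_g must be positive")
    rng = np.random.default_rng(seed)
    n_ticks = int(round(duration_min * 60.0 / tick_s))
    timestamps = np.arange(n_ticks + 1) * tick_s
    finals = {
        "sucrose": round(round(total_g * true_pref_frac / QUANTUM_G) * QUANTUM_G, 2),
        "sucralose": round(round(total_g * (1 - true_pref_frac) / QUANTUM_G) * QUANTUM_G, 2),
    }
    streams = []
    for channel in ("sucrose", "sucralose"):
        n_quanta = int(round(finals[channel] / QUANTUM_G))
        per_tick = np.zeros(n_ticks + 1)
        if n_quanta:
            ticks = rng.integers(1, n_ticks + 1, size=n_quanta)
            np.add.at(per_tick, ticks, QUANTUM_G)
        clean = np.round(np.cumsum(per_tick), 2)
        raw = clean.copy()
        dip_ticks = np.flatnonzero(rng.random(n_ticks + 1) < dip_prob)
        dip_ticks = dip_ticks[(dip_ticks > 0) & (dip_ticks < n_ticks)]
        for i in dip_ticks:
            raw[i] = max(0.0, round(clean[i] - dip_mag_g, 2))
        streams.append(IntakeStream(timestamps, raw, channel))
    truth = GroundTruth(
        kind="intake_session",
        params={
            "true_pref_frac": true_pref_frac,
            "total_g": total_g,
            "tick_s": tick_s,
            "duration_min": duration_min,
            "dip_prob": dip_prob,
            "dip_mag_g": dip_mag_g,
        },
        labels={
            "final_sucrose_g": finals["sucrose"],
            "final_sucralose_g": finals["sucralose"],
            "true_preference_pct": (
                100.0 * finals["sucrose"] / (finals["sucrose"] + finals["sucralose"])
                if finals["sucrose"] + finals["sucralose"] > 0 else None
            ),
        },
        seed=seed,
    )
    return streams[0], streams[1], truth


# ---------------------------------------------------------------------------
# fiber optics
# ---------------------------------------------------------------------------

def gen_cutback(
    alpha_db_per_cm: float = 0.93,
    lengths_cm=None,
    p0_mw: float = 1.0,
    noise_cv: float = 0.0,
    geometry: str = "straight",
    seed: int = 0,
) -> tuple[CutbackSeries, GroundTruth]:
    """Simulate a cut-back measurement with multiplicative lognormal noise.

    power(L) = p0 * 10^(-alpha (L - Lmin) / 10) * lognormal noise whose
    coefficient of variation is ``noise_cv`` (mean 1, so the noise is
    unbiased on the linear scale).
    """
    if alpha_db_per_cm < 0:
        raise ValueError("attenuation coefficient must be >= 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    lengths = np.asarray(
        lengths_cm if lengths_cm is not None else np.arange(1.0, 10.5, 0.5), dtype=float
    )
    if lengths.size < 2 or not np.all(np.diff(lengths) > 0):
        raise ValueError("need >= 2 strictly increasing lengths")
    rng = np.random.default_rng(seed)
    power = p0_mw * np.power(10.0, -alpha_db_per_cm * (lengths - lengths[0]) / 10.0)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        power = power * rng.lognormal(-0.5 * sigma**2, sigma, lengths.size)
    series = CutbackSeries(lengths, power, geometry=geometry)
    truth = GroundTruth(
        kind="cutback",
        params={
            "alpha_db_per_cm": alpha_db_per_cm,
            "lengths_cm": lengths,
            "p0_mw": p0_mw,
            "noise_cv": noise_cv,
            "geometry": geometry,
        },
        labels={"alpha_db_per_cm": alpha_db_per_cm},
        seed=seed,
    )
    return series, truth
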