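"""Delimited-text readers and writers with provenance headers.

All outputs are plain tab-separated text.  Files written by this module
begin with comment lines of the form ``# key: value`` recording the package
version, the seed and the parameters of the run, so a result can always be
reproduced from its own header.  Readers skip ``#`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import IntakeStream
from .biophys import CutbackSeries
from .calcium import DffTrace, RatiometricTrace
from .ephys import VoltageTrace
from .qpcr import CqMatrix

SEP = "\t"


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_table(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False):
    """Write a DataFrame as TSV preceded by ``# key: value`` provenance lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"version": __version__, **(meta or {})}
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {json.dumps(_jsonable(value))}\n")
        df.to_csv(fh, sep=SEP, index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, comment="#", index_col=index_col)


def read_header(path) -> dict:
    """Parse the ``# key: value`` provenance lines of a written table."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            try:
                meta[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = value.strip()
    return meta


# -- ground truth sidecars ---------------------------------------------------

def write_ground_truth(truth, path):
    """Write a GroundTruth record as a YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "kind": truth.kind,
        "seed": truth.seed,
        "params": _jsonable(truth.params),
        "labels": _jsonable(truth.labels),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_ground_truth(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# -- electrophysiology -------------------------------------------------------

def write_voltage_trace(trace: VoltageTrace, path, meta: dict | None = None):
    """Single-column voltage file; the sampling rate lives in the header."""
    df = pd.DataFrame({"voltage_uv": trace.samples})
    write_table(df, path, meta={
        "sampling_rate_hz": trace.sampling_rate,
        "start_time_s": trace.start_time,
        **(meta or {}),
    })


def read_voltage_trace(path) -> VoltageTrace:
    """Read either (time_s, voltage_uv) columns or a single voltage column
    with ``sampling_rate_hz`` declared in the header."""
    df = read_table(path)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy()
        if t.size < 2:
            raise ValueError("need at least two samples to infer the sampling rate")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0]):
            raise ValueError("time column must be uniformly sampled")
        return VoltageTrace(df["voltage_uv"].to_numpy(), 1.0 / dt[0], start_time=t[0])
    meta = read_header(path)
    if "sampling_rate_hz" not in meta:
        raise ValueError("single-column voltage file must declare sampling_rate_hz")
    return VoltageTrace(
        df["voltage_uv"].to_numpy(),
        float(meta["sampling_rate_hz"]),
        start_time=float(meta.get("start_time_s", 0.0)),
    )


def write_spike_train(train, path, meta: dict | None = None):
    write_table(
        pd.DataFrame({"spike_time_s": train.spike_times}),
        path,
        meta={**train.detection_params, **(meta or {})},
    )


# -- calcium -----------------------------------------------------------------

def write_calcium_traces(traces, path, windows_path=None, meta: dict | None = None):
    """Long-format per-cell traces plus a window-definition sidecar."""
    frames = []
    for tr in traces:
        if isinstance(tr, RatiometricTrace):
            frames.append(pd.DataFrame({
                "cell_id": tr.cell_id, "time_s": tr.times,
                "fluo4": tr.fluo4, "furared": tr.furared,
            }))
        else:
            frames.append(pd.DataFrame({
                "cell_id": tr.neuron_id, "time_s": tr.times, "f": tr.f,
            }))
    write_table(pd.concat(frames, ignore_index=True), path, meta=meta)
    if windows_path is not None:
        first = traces[0]
        doc = {"stimulus_windows": [
            {"name": n, "onset_s": float(o), "duration_s": float(d)}
            for n, o, d in first.stimulus_windows
        ]}
        if isinstance(first, RatiometricTrace):
            doc["kcl_window"] = {
                "onset_s": float(first.kcl_window[0]),
                "duration_s": float(first.kcl_window[1]),
            }
        Path(windows_path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_calcium_traces(path, windows_path):
    """Read long-format traces back into trace objects (mode inferred from
    columns: fluo4/furared -> ratiometric, f -> dF/F)."""
    df = read_table(path)
    doc = yaml.safe_load(Path(windows_path).read_text())
    windows = [
        (w["name"], w["onset_s"], w["duration_s"]) for w in doc["stimulus_windows"]
    ]
    kcl = doc.get("kcl_window")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        if "fluo4" in df.columns:
            traces.append(RatiometricTrace(
                times=sub["time_s"].to_numpy(),
                fluo4=sub["fluo4"].to_numpy(),
                furared=sub["furared"].to_numpy(),
                cell_id=str(cell_id),
                stimulus_windows=windows,
                kcl_window=(kcl["onset_s"], kcl["duration_s"]),
            ))
        else:
            traces.append(DffTrace(
                times=sub["time_s"].to_numpy(),
                f=sub["f"].to_numpy(),
                neuron_id=str(cell_id),
                stimulus_windows=windows,
            ))
    return traces


# -- qPCR --------------------------------------------------------------------

def write_cq_matrix(m: CqMatrix, path, meta_path, meta: dict | None = None):
    """Biomark-style export: per-gene Cq columns paired with quality columns
    (``<gene>_quality``); undetected wells are empty fields.  Cell metadata
    goes to a second table."""
    wide = m.cq.copy()
    for gene in m.cq.columns:
        wide[f"{gene}_quality"] = m.quality[gene]
    write_table(wide, path, meta=meta, index=True)
    write_table(m.metadata, meta_path, meta=meta, index=True)


def read_cq_matrix(path, meta_path) -> CqMatrix:
    wide = read_table(path, index_col=0)
    genes = [c for c in wide.columns if not c.endswith("_quality")]
    cq = wide[genes]
    quality = wide[[f"{g}_quality" for g in genes]]
    quality.columns = genes
    metadata = read_table(meta_path, index_col=0)
    return CqMatrix(cq=cq, quality=quality, metadata=metadata)


# -- behavior ----------------------------------------------------------------

def write_intake_streams(streams, path, meta: dict | None = None):
    frames = [
        pd.DataFrame({
            "timestamp_s": s.timestamps,
            "channel": s.channel,
            "cumulative_g": s.cumulative_g,
        })
        for s in streams
    ]
    write_table(pd.concat(frames, ignore_index=True), path, meta=meta)


def read_intake_streams(path) -> dict:
    df = read_table(path)
    return {
        str(channel): IntakeStream(
            sub["timestamp_s"].to_numpy(), sub["cumulative_g"].to_numpy(), str(channel)
        )
        for channel, sub in df.groupby("channel", sort=False)
    }


def write_schedule(schedule, path, meta: dict | None = None):
    df = pd.DataFrame(schedule.intervals, columns=["on_start_s", "on_end_s"])
    write_table(df, path, meta={
        "freq_hz": schedule.freq_hz,
        "duty": schedule.duty,
        "amplitude_v": schedule.amplitude_v,
        "provenance": schedule.provenance,
        "n_triggers": schedule.n_triggers,
        **(meta or {}),
    })


# -- fiber optics ------------------------------------------------------------

def write_cutback(series: CutbackSeries, path, meta: dict | None = None):
    df = pd.DataFrame({"length_cm": series.lengths_cm, "power_mw": series.power_mw})
    write_table(df, path, meta={"geometry": series.geometry, **(meta or {})})


def read_cutback(path) -> CutbackSeries:
    df = read_table(path)
    meta = read_header(path)
    return CutbackSeries(
        df["length_cm"].to_numpy(),
        df["power_mw"].to_numpy(),
        geometry=str(meta.get("geometry", "straight")),
    )
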