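"""Reading and writing recordings and analysis artifacts.

Recordings travel as delimited text (CSV/TSV) with a header row naming the
channels; a schema maps channel roles to column names and the sampling rate
comes from the schema or is inferred from a time column.  Derived grids
(TFRs, coherence/phase maps) are stored as ``.npz`` archives with their axes
and configuration, summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coherence import CoherenceMap
from .preprocess import BeatSeries, RawRecording

__all__ = [
    "DEFAULT_SCHEMA",
    "read_recording",
    "write_recording",
    "save_beat_series",
    "load_beat_series",
    "save_coherence",
    "load_coherence",
    "save_json",
]

DEFAULT_SCHEMA = {
    "time": "time",
    "abp": "ABP",
    "cbfv": "CBFV",
    "ecg": "ECG",
    "etco2": "EtCO2",
}


def read_recording(
    path: str | Path,
    schema: dict[str, str] | None = None,
    fs: float | None = None,
    sep: str = ",",
) -> RawRecording:
    """Load a delimited-text recording.

    ``schema`` maps the roles time/abp/cbfv/ecg/etco2 to column names; the
    sampling rate is taken from ``fs`` or inferred from the time column.
    Missing channels and NaN gaps raise descriptive errors.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=sep)
    for role in ("abp", "cbfv", "ecg", "etco2"):
        col = schema[role]
        if col not in df.columns:
            raise ValueError(f"recording {path} is missing channel column '{col}' ({role})")
    if fs is None:
        tcol = schema["time"]
        if tcol not in df.columns:
            raise ValueError("no sampling rate given and no time column to infer it from")
        dt = np.diff(df[tcol].to_numpy())
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-3):
            raise ValueError("time column is not uniformly sampled")
        fs = 1.0 / dt[0]
    return RawRecording(
        fs=float(fs),
        abp=df[schema["abp"]].to_numpy(dtype=float),
        cbfv=df[schema["cbfv"]].to_numpy(dtype=float),
        ecg=df[schema["ecg"]].to_numpy(dtype=float),
        etco2=df[schema["etco2"]].to_numpy(dtype=float),
    )


def write_recording(rec: RawRecording, path: str | Path, schema: dict[str, str] | None = None) -> None:
    """Write a recording as CSV (round-trips through :func:`read_recording`)."""
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.DataFrame(
        {
            schema["time"]: rec.time,
            schema["abp"]: rec.abp,
            schema["cbfv"]: rec.cbfv,
            schema["ecg"]: rec.ecg,
            schema["etco2"]: rec.etco2,
        }
    )
    df.to_csv(path, index=False)


def save_beat_series(path: str | Path, **segments: BeatSeries) -> None:
    """Store named beat-averaged segments in one ``.npz`` archive."""
    arrays = {}
    for name, seg in segments.items():
        arrays[f"{name}_abp"] = seg.abp
        arrays[f"{name}_cbfv"] = seg.cbfv
        arrays[f"{name}_meta"] = np.array([seg.fs, seg.t0])
        arrays[f"{name}_label"] = np.array(seg.state_label)
    np.savez(path, **arrays)


def load_beat_series(path: str | Path) -> dict[str, BeatSeries]:
    data = np.load(path, allow_pickle=False)
    names = {k[: -len("_abp")] for k in data.files if k.endswith("_abp")}
    out = {}
    for name in sorted(names):
        fs, t0 = data[f"{name}_meta"]
        out[name] = BeatSeries(
            fs=float(fs),
            abp=data[f"{name}_abp"],
            cbfv=data[f"{name}_cbfv"],
            state_label=str(data[f"{name}_label"]),
            t0=float(t0),
        )
    return out


def save_coherence(path: str | Path, coh: CoherenceMap) -> None:
    np.savez_compressed(
        path,
        values=coh.values.astype(np.float32),
        defined_mask=coh.defined_mask,
        t_axis=coh.t_axis,
        f_axis=coh.f_axis,
        smoothed_cross=coh.smoothed_cross,
        overflow_fraction=np.array(coh.overflow_fraction),
    )


def load_coherence(path: str | Path) -> CoherenceMap:
    data = np.load(path, allow_pickle=False)
    return CoherenceMap(
        values=data["values"].astype(float),
        defined_mask=data["defined_mask"],
        t_axis=data["t_axis"],
        f_axis=data["f_axis"],
        smoothed_cross=data["smoothed_cross"],
        overflow_fraction=float(data["overflow_fraction"]),
    )


def save_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if not isinstance(v, np.ndarray)}
        raise TypeError(f"cannot serialise {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default))
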