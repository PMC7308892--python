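"""CSV / JSON readers and writers for recordings, references and windows.

Plain CSV (one file per subject, header mandatory) keeps fixtures diffable;
values round-trip losslessly because floats are written in shortest-repr
form. The reader interface is format-agnostic, so a dedicated biosignal
container format could be added behind the same functions later.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dsp import WindowEstimate
from .simulate import GroundTruth, PpgRecording, ReferenceSeries

__all__ = [
    "read_recording",
    "write_recording",
    "read_reference",
    "write_reference",
    "write_truth",
    "windows_to_frame",
    "frame_to_windows",
    "write_windows",
    "read_windows",
    "load_config",
    "save_config",
]

RECORDING_COLUMNS = ["time_s", "ppg_red", "ppg_ir", "ambient", "activity"]


def write_recording(rec: PpgRecording, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": rec.time_s,
            "ppg_red": rec.ppg_red,
            "ppg_ir": rec.ppg_ir,
            "ambient": rec.ambient,
            "activity": rec.activity,
        }
    ).to_csv(path, index=False)
    return path


def read_recording(path: str | Path, subject_id: str | None = None) -> PpgRecording:
    """Read a recording CSV; the subject id defaults to the file stem."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty recording file: {path}") from None
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"recording {path} is missing required column(s): "
            f"{', '.join(missing)}"
        )
    if df.empty:
        raise ValueError(f"recording {path} contains no samples")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if t.size > 1:
        if not np.all(dt > 0):
            raise ValueError(f"recording {path}: time not strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"recording {path}: non-uniform time grid")
        fs = 1.0 / float(np.median(dt))
    else:
        fs = float("nan")
    return PpgRecording(
        subject_id=subject_id or path.stem,
        sampling_rate_hz=fs,
        time_s=t,
        ppg_red=df["ppg_red"].to_numpy(float),
        ppg_ir=df["ppg_ir"].to_numpy(float),
        ambient=df["ambient"].to_numpy(float),
        activity=df["activity"].to_numpy(str),
    )


def write_reference(
    ref: ReferenceSeries, path: str | Path, abga_path: str | Path | None = None
) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": ref.time_s,
            "spo2_ref": ref.spo2_ref,
            "heart_rate_ref": ref.heart_rate_ref,
        }
    ).to_csv(path, index=False)
    if abga_path is not None:
        pd.DataFrame(
            {"time_s": ref.abga_times_s, "sao2": ref.sao2_abga}
        ).to_csv(abga_path, index=False)
    return path


def read_reference(
    path: str | Path, abga_path: str | Path | None = None
) -> ReferenceSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "spo2_ref", "heart_rate_ref"):
        if col not in df.columns:
            raise ValueError(f"reference {path} missing column: {col}")
    abga_t = np.array([])
    sao2 = np.array([])
    if abga_path is not None and Path(abga_path).exists():
        abga = pd.read_csv(abga_path)
        abga_t = abga["time_s"].to_numpy(float)
        sao2 = abga["sao2"].to_numpy(float)
    return ReferenceSeries(
        time_s=df["time_s"].to_numpy(float),
        spo2_ref=df["spo2_ref"].to_numpy(float),
        heart_rate_ref=df["heart_rate_ref"].to_numpy(float),
        abga_times_s=abga_t,
        sao2_abga=sao2,
    )


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": truth.time_s,
            "spo2_true": truth.spo2_true,
            "heart_rate_true": truth.heart_rate_true,
            "activity": truth.activity,
            "artefact_mask": truth.artefact_mask.astype(int),
        }
    ).to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# windows


def windows_to_frame(windows: list[WindowEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(w) for w in windows])


def frame_to_windows(df: pd.DataFrame) -> list[WindowEstimate]:
    fields = {f.name for f in dataclasses.fields(WindowEstimate)}
    out = []
    for rec in df.to_dict(orient="records"):
        kwargs = {k: v for k, v in rec.items() if k in fields}
        for opt in ("spo2_est", "spo2_est_unclamped", "ref_spo2_mean"):
            v = kwargs.get(opt)
            if v is not None and isinstance(v, float) and np.isnan(v):
                kwargs[opt] = None
        kwargs["rejected"] = bool(kwargs["rejected"])
        out.append(WindowEstimate(**kwargs))
    return out


def write_windows(windows: list[WindowEstimate], path: str | Path) -> Path:
    path = Path(path)
    windows_to_frame(windows).to_csv(path, index=False)
    return path


def read_windows(path: str | Path) -> list[WindowEstimate]:
    return frame_to_windows(pd.read_csv(path))


# --------------------------------------------------------------------------
# configuration


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(config.model_dump_json(indent=2))
    return path


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.model_validate_json(Path(path).read_text())
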