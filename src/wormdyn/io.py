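"""File I/O: recordings (CSV / HDF5), latents, parameters, fits, sweeps.

CSV dialect for recordings: neurons as rows, frames as columns, header
row of frame times, first column the neuron id.  Labels are a one-column
CSV named ``state`` with integers 1-7.  HDF5 recordings hold datasets
``traces`` (neurons x time), ``time``, ``neuron_ids`` and optionally
``labels``.  Every artifact written by the CLI carries provenance: a
config hash, the seed and the package version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .control import InvalidLabelError, validate_labels
from .dynamics import ModelParams, SimTrajectory
from .fitting import FitResult
from .preprocessing import LatentSeries, NeuralRecording

__all__ = [
    "IngestionError",
    "load_recording",
    "save_recording",
    "load_labels",
    "save_latents",
    "load_latents",
    "save_params",
    "load_params",
    "save_fit_result",
    "save_trajectory",
    "load_trajectory",
    "save_sweep",
    "provenance",
]


class IngestionError(ValueError):
    """Malformed input file; message names the offending axis/cell."""


def provenance(config: dict, seed: int | None = None) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "package_version": __version__,
    }


def save_recording(path, recording: NeuralRecording, labels=None, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        times = np.arange(recording.n_frames) * recording.frame_interval
        df = pd.DataFrame(recording.traces, index=recording.neuron_ids, columns=times)
        df.index.name = "neuron"
        df.to_csv(path)
        if labels is not None:
            pd.DataFrame({"state": validate_labels(labels)}).to_csv(
                path.with_suffix(".labels.csv"), index=False
            )
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=recording.traces)
            f.create_dataset("time", data=np.arange(recording.n_frames) * recording.frame_interval)
            f.create_dataset("neuron_ids", data=np.asarray(recording.neuron_ids, dtype="S"))
            if labels is not None:
                f.create_dataset("labels", data=validate_labels(labels))
    else:
        raise ValueError(f"format must be csv or hdf5, got {format!r}")


def load_labels(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "state" not in df.columns:
        raise IngestionError("labels CSV must have a 'state' column")
    try:
        return validate_labels(df["state"].to_numpy())
    except InvalidLabelError as e:
        raise InvalidLabelError(f"{path}: {e}") from e


def load_recording(path, format: str = "csv", labels_path=None):
    """-> (NeuralRecording, labels or None).  Validates shapes and labels."""
    path = Path(path)
    labels = None
    if format == "csv":
        try:
            df = pd.read_csv(path, index_col=0)
        except Exception as e:  # noqa: BLE001
            raise IngestionError(f"{path}: cannot parse CSV ({e})") from e
        mat = df.to_numpy()
        if not np.issubdtype(mat.dtype, np.number):
            for j, col in enumerate(df.columns):
                bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
                if bad.any():
                    i = int(np.argmax(bad.to_numpy()))
                    raise IngestionError(
                        f"{path}: non-numeric cell at row {df.index[i]!r}, column {col!r}"
                    )
            raise IngestionError(f"{path}: non-numeric data")
        try:
            times = np.asarray([float(c) for c in df.columns])
        except ValueError as e:
            raise IngestionError(f"{path}: header row must hold frame times") from e
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        rec = NeuralRecording(traces=mat, frame_interval=dt,
                              neuron_ids=[str(i) for i in df.index])
        lp = labels_path or path.with_suffix(".labels.csv")
        if Path(lp).exists():
            labels = load_labels(lp)
    elif format == "hdf5":
        with h5py.File(path, "r") as f:
            traces = np.asarray(f["traces"])
            times = np.asarray(f["time"])
            ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["neuron_ids"][()]]
            dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
            rec = NeuralRecording(traces=traces, frame_interval=dt, neuron_ids=ids)
            if "labels" in f:
                labels = validate_labels(np.asarray(f["labels"]))
    else:
        raise ValueError(f"format must be csv or hdf5, got {format!r}")

    if labels is not None and len(labels) != rec.n_frames:
        raise IngestionError(
            f"labels axis ({len(labels)}) does not match the recording's "
            f"frame axis ({rec.n_frames})"
        )
    return rec, labels


def save_latents(path, series: LatentSeries) -> None:
    path = Path(path)
    times = np.arange(len(series)) * series.frame_interval
    pd.DataFrame({"time": times, "v1": series.v1, "v2": series.v2}).to_csv(path, index=False)
    sidecar = {
        "variance_fractions": np.asarray(series.variance_fractions).tolist(),
        "scale_factor": series.scale_factor,
        "orientation_sign": series.orientation_sign,
        "center_offset": series.center_offset,
        "frame_interval": series.frame_interval,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_latents(path) -> LatentSeries:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return LatentSeries(
        v1=df["v1"].to_numpy(),
        v2=df["v2"].to_numpy(),
        variance_fractions=np.asarray(meta.get("variance_fractions", [])),
        frame_interval=float(meta.get("frame_interval", 1.0)),
        scale_factor=float(meta.get("scale_factor", 1.0)),
        orientation_sign=int(meta.get("orientation_sign", 1)),
        center_offset=float(meta.get("center_offset", 0.0)),
    )


def save_params(path, params: ModelParams, extra: dict | None = None) -> None:
    d = json.loads(params.to_json())
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def load_params(path) -> ModelParams:
    return ModelParams.from_json(Path(path).read_text())


def save_fit_result(path, result: FitResult, latents=None, extra: dict | None = None) -> None:
    """JSON summary plus a CSV of (time, v1, x, E) when latents are given."""
    path = Path(path)
    d = result.summary()
    if extra:
        d.update(extra)
    path.write_text(json.dumps(d, indent=2))
    if latents is not None and result.error_series is not None:
        v1 = latents.v1
        times = np.arange(len(v1)) * latents.frame_interval
        x = v1 - result.error_series
        pd.DataFrame({"time": times, "v1": v1, "x": x, "E": result.error_series}).to_csv(
            path.with_suffix(".csv"), index=False
        )


def save_trajectory(path, traj: SimTrajectory) -> None:
    traj.to_frame().to_csv(path, index=False)


def load_trajectory(path) -> SimTrajectory:
    df = pd.read_csv(path)
    return SimTrajectory(
        times=df["time"].to_numpy(), x=df["x"].to_numpy(),
        y=df["y"].to_numpy(), u=df["u"].to_numpy(),
    )


def save_sweep(path, sweep) -> None:
    """Long-format CSV (value, bin_center, density) plus a JSON summary."""
    path = Path(path)
    rows = []
    for v, dist in zip(sweep.values, sweep.distributions):
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        for c, d in zip(centers, dist.densities):
            rows.append({"parameter": sweep.parameter_name, "value": v,
                         "bin_center": c, "density": d})
    pd.DataFrame(rows).to_csv(path, index=False)
    path.with_suffix(".json").write_text(json.dumps({
        "parameter": sweep.parameter_name,
        "summary": sweep.summary,
    }, indent=2))
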