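"""Readers and writers for the pipeline's file formats.

Localization tables are CSV (``frame,x_nm,y_nm[,intensity]``;
ThunderSTORM-style headers ``x [nm]`` / ``y [nm]`` are accepted on read),
trajectories are CSV (``traj_id,frame,x_um,y_um``), images are TIFF, and
MEA recordings are HDF5 (``/traces`` int16 with scale attributes) or flat
int16 binary with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import LocalizationTable, TrajectorySet
from .synthetic import MEARecording

__all__ = [
    "write_localizations_csv",
    "read_localizations_csv",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_tiff",
    "read_tiff",
    "write_mea_h5",
    "read_mea_h5",
    "write_mea_raw",
    "read_mea_raw",
    "write_json",
]

_LOC_ALIASES = {
    "frame": "frame",
    "x_nm": "x_nm",
    "y_nm": "y_nm",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "x": "x_nm",
    "y": "y_nm",
    "intensity": "intensity",
    "intensity [photon]": "intensity",
}


def write_localizations_csv(locs: LocalizationTable, path) -> None:
    df = locs.to_dataframe()
    header = [
        f"# field_width_nm={locs.field_width_nm}",
        f"# field_height_nm={locs.field_height_nm}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False)


def read_localizations_csv(
    path, field_width_nm: float | None = None, field_height_nm: float | None = None
) -> LocalizationTable:
    """Read a localization CSV (ThunderSTORM-like column aliases accepted).

    Field extent is taken from ``# field_*`` comment lines when present,
    from the arguments otherwise, and falls back to the data's bounding box.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if line.startswith("#"):
                pos += len(line)
                if "=" in line:
                    key, val = line.lstrip("# ").split("=", 1)
                    meta[key.strip()] = float(val)
            else:
                break
    df = pd.read_csv(path, comment="#")
    df = df.rename(columns={c: _LOC_ALIASES.get(c.strip(), c.strip()) for c in df.columns})
    for col in ("frame", "x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    w = field_width_nm or meta.get("field_width_nm") or float(df["x_nm"].max() or 1.0)
    h = field_height_nm or meta.get("field_height_nm") or float(df["y_nm"].max() or 1.0)
    return LocalizationTable(
        frame=df["frame"].to_numpy(),
        x_nm=df["x_nm"].to_numpy(),
        y_nm=df["y_nm"].to_numpy(),
        field_width_nm=w,
        field_height_nm=h,
        intensity=df["intensity"].to_numpy() if "intensity" in df.columns else None,
    )


def write_trajectories_csv(traj: TrajectorySet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dt_s={traj.dt_s}\n")
        traj.to_dataframe().to_csv(fh, index=False)


def read_trajectories_csv(path, dt_s: float | None = None) -> TrajectorySet:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, val = line.lstrip("# ").split("=", 1)
                meta[key.strip()] = float(val)
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    return TrajectorySet(
        trajectory_id=df["traj_id"].to_numpy(),
        frame=df["frame"].to_numpy(),
        x_um=df["x_um"].to_numpy(),
        y_um=df["y_um"].to_numpy(),
        dt_s=dt_s or meta.get("dt_s", 0.020),
    )


def write_tiff(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, image)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mea_h5(rec: MEARecording, path, lsb_per_sd: float = 0.01) -> None:
    """Write traces as int16 HDF5 (`/traces`), quantized at ``lsb_per_sd`` sd."""
    scale = lsb_per_sd * rec.noise_sd
    quant = np.clip(np.round(rec.traces / scale), -32768, 32767).astype(np.int16)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("traces", data=quant)
        d.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        d.attrs["scale"] = scale
        d.attrs["noise_sd"] = rec.noise_sd


def read_mea_h5(path) -> MEARecording:
    with h5py.File(path, "r") as f:
        d = f["traces"]
        traces = d[()].astype(np.float32) * d.attrs["scale"]
        fs = float(d.attrs["sampling_rate_hz"])
        noise_sd = float(d.attrs.get("noise_sd", 1.0))
    return MEARecording(
        traces=traces,
        sampling_rate_hz=fs,
        duration_s=traces.shape[1] / fs,
        noise_sd=noise_sd,
    )


def write_mea_raw(rec: MEARecording, bin_path, json_path, lsb_per_sd: float = 0.01) -> None:
    """Write traces as flat int16 binary (C order) plus a JSON header."""
    scale = lsb_per_sd * rec.noise_sd
    quant = np.clip(np.round(rec.traces / scale), -32768, 32767).astype(np.int16)
    quant.tofile(bin_path)
    header = {
        "n_channels": int(rec.n_channels),
        "n_samples": int(rec.traces.shape[1]),
        "sampling_rate_hz": rec.sampling_rate_hz,
        "scale": scale,
        "dtype": "int16",
        "order": "C",
    }
    Path(json_path).write_text(json.dumps(header, indent=2, sort_keys=True))


def read_mea_raw(bin_path, json_path) -> MEARecording:
    header = json.loads(Path(json_path).read_text())
    raw = np.fromfile(bin_path, dtype=np.int16).reshape(
        header["n_channels"], header["n_samples"]
    )
    traces = raw.astype(np.float32) * header["scale"]
    fs = float(header["sampling_rate_hz"])
    return MEARecording(
        traces=traces, sampling_rate_hz=fs, duration_s=traces.shape[1] / fs
    )


def write_json(obj, path) -> None:
    """Deterministic JSON writer (sorted keys, numpy-safe)."""

    def _default(o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
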