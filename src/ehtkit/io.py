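"""File I/O: two-column trace CSVs with JSON parameter sidecars,
multi-page channel TIFFs, label maps and ground-truth/feature tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import FluorescenceTrace, VoltageTrace
from .force_trace import ForceTrace

__all__ = [
    "read_force_trace",
    "write_force_trace",
    "read_two_column_trace",
    "write_trace_csv",
    "write_tissue_image",
    "read_tissue_image",
]


def _params_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _params_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_params_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _params_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _write_sidecar(path: Path, meta: dict):
    if meta:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(_params_to_jsonable(meta), indent=2, default=str)
        )


def write_force_trace(trace: ForceTrace, path):
    """Write a force trace as CSV (time_s, force_mN [, stim]) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time, "force_mN": trace.force})
    if trace.stim_times is not None:
        stim = np.zeros(trace.time.size, dtype=int)
        stim[np.searchsorted(trace.time, trace.stim_times).clip(0, stim.size - 1)] = 1
        df["stim"] = stim
    if trace.post_distance is not None:
        df["post_mm"] = trace.post_distance
    df.to_csv(path, index=False)
    _write_sidecar(path, trace.meta)


def read_force_trace(path) -> ForceTrace:
    """Read a force-log CSV (columns time_s, force_mN, optional stim, post_mm)."""
    df = pd.read_csv(path)
    for col in ("time_s", "force_mN"):
        if col not in df.columns:
            raise ValueError(f"force log is missing the {col!r} column")
    stim = None
    if "stim" in df.columns:
        stim = df.loc[df["stim"] > 0, "time_s"].to_numpy()
    post = df["post_mm"].to_numpy() if "post_mm" in df.columns else None
    return ForceTrace(
        df["time_s"].to_numpy(), df["force_mN"].to_numpy(), stim_times=stim, post_distance=post
    )


def write_trace_csv(trace, path, value_name="value"):
    """Write any two-column trace (time_s, value) + JSON params sidecar."""
    path = Path(path)
    y = trace.intensity if hasattr(trace, "intensity") else trace.voltage
    pd.DataFrame({"time_s": trace.time, value_name: y}).to_csv(path, index=False)
    _write_sidecar(path, getattr(trace, "meta", {}))


def read_two_column_trace(path, kind="ca"):
    """Read a two-column CSV as a fluorescence ('ca') or voltage ('ap') trace."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy()
    y = df.iloc[:, 1].to_numpy()
    if kind == "ap":
        return VoltageTrace(t, y)
    return FluorescenceTrace(t, y)


def write_tissue_image(channels, labels, ground_truth, stem):
    """Write a synthetic scan: channel TIFF (one page per channel), label
    TIFF and ground-truth CSV under a common file stem."""
    stem = Path(stem)
    tifffile.imwrite(
        stem.with_suffix(".tif"),
        np.asarray(channels, dtype=np.float32),
        photometric="minisblack",
        planarconfig="separate",
    )
    tifffile.imwrite(
        stem.with_name(stem.name + "_labels.tif"), np.asarray(labels, dtype=np.int32)
    )
    ground_truth.to_csv(stem.with_name(stem.name + "_truth.csv"), index=False)


def read_tissue_image(path):
    """Read a multi-page channel TIFF as a (n_channels, H, W) float array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)
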