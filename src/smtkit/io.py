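"""File I/O: TIFF stacks, track-table CSV with config sidecar, ROI JSON."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import TRACK_COLUMNS, AcquisitionParams, LinkingParams, ROIMask, TrackTable


def read_tiff_stack(path) -> np.ndarray:
    """Multi-page TIFF as a (frames, height, width) float array.

    A single-page file becomes a 1-frame stack; for multi-series files the
    first series is used.
    """
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D time series, got shape {arr.shape}")
    return arr


def write_tiff_stack(path, movie: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(movie), photometric="minisblack")


def write_track_csv(table: TrackTable, path, linking: LinkingParams | None = None) -> None:
    """Write the track table plus a YAML sidecar with acquisition/linking params.

    Column order follows the canonical schema; extra columns are appended.
    The sidecar lands next to the CSV as ``<stem>.config.yaml``.
    """
    path = Path(path)
    df = table.df.copy()
    cols = [c for c in TRACK_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)
    sidecar = {"acquisition": asdict(table.acq)}
    if linking is not None:
        sidecar["linking"] = asdict(linking)
    path.with_suffix(".config.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_track_csv(path, acq: AcquisitionParams | None = None) -> TrackTable:
    """Read a track CSV; acquisition params come from the sidecar unless given."""
    path = Path(path)
    df = pd.read_csv(path)
    if acq is None:
        sidecar = path.with_suffix(".config.yaml")
        if sidecar.exists():
            cfg = yaml.safe_load(sidecar.read_text())
            acq = AcquisitionParams(**cfg["acquisition"])
        else:
            acq = AcquisitionParams()
    if "interpolated" in df.columns:
        df["interpolated"] = df["interpolated"].astype(bool)
    return TrackTable(df, acq)


def read_linking_sidecar(path) -> LinkingParams | None:
    sidecar = Path(path).with_suffix(".config.yaml")
    if not sidecar.exists():
        return None
    cfg = yaml.safe_load(sidecar.read_text())
    return LinkingParams(**cfg["linking"]) if "linking" in cfg else None


def read_roi_json(path) -> ROIMask:
    """ROI polygon from JSON: {"vertices": [[x, y], ...]}."""
    data = json.loads(Path(path).read_text())
    return ROIMask(np.asarray(data["vertices"], dtype=float))


def write_roi_json(path, roi: ROIMask) -> None:
    Path(path).write_text(json.dumps({"vertices": roi.vertices.tolist()}))


def read_acq_config(path) -> AcquisitionParams:
    """Acquisition params from a YAML key-value file."""
    cfg = yaml.safe_load(Path(path).read_text())
    if "acquisition" in cfg:
        cfg = cfg["acquisition"]
    return AcquisitionParams(**cfg)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
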