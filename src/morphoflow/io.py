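"""Format readers and writers: TIFF volumes, trajectory CSV dialects,
velocity-field/similarity CSV, and JSON sidecars."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from morphoflow.dispersal import TrajectorySet
from morphoflow.velocimetry import SimilarityMap, VelocityField

__all__ = [
    "VolumeSeries",
    "read_volume",
    "write_volume",
    "read_tracks",
    "write_tracks",
    "field_to_frame",
    "write_field_csv",
    "write_json",
]


@dataclass
class VolumeSeries:
    """Ordered 3D intensity frames with physical calibration.

    ``data`` is a (T, Z, Y, X) array; ``spacing`` the voxel size in um
    as (z, y, x); ``dt`` the frame interval in minutes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("volume series must be (T, Z, Y, X)")

    def __len__(self) -> int:
        return self.data.shape[0]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def read_volume(path, spacing=None, dt=None, axes: str | None = None) -> VolumeSeries:
    """Read a multi-page TIFF as a TZYX series.

    Axis metadata is resolved from the TIFF tags when present; the
    ``axes`` override (a permutation string like ``"TZYX"``) rearranges
    the on-disk layout.  A JSON sidecar ``<path>.json`` written by
    :func:`write_volume` supplies spacing and dt unless overridden.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        file_axes = tf.series[0].axes if tf.series else None
    axes = axes or file_axes
    if axes and len(axes) == arr.ndim and set(axes) <= set("TZYXQI"):
        axes = axes.replace("Q", "Z").replace("I", "T")
        want = [a for a in "TZYX" if a in axes]
        arr = np.transpose(arr, [axes.index(a) for a in want])
        for pos, a in enumerate("TZYX"):
            if a not in axes:
                arr = np.expand_dims(arr, pos)
    elif arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        warnings.warn(
            f"no axis metadata in {path.name}; assuming (Z, Y, X) single frame",
            stacklevel=2,
        )
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"cannot resolve {path} to a TZYX series (shape {arr.shape})")

    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    spacing = tuple(spacing or meta.get("spacing", (1.0, 1.0, 1.0)))
    dt = dt if dt is not None else meta.get("dt", 1.0)
    return VolumeSeries(data=arr, spacing=spacing, dt=float(dt))


def write_volume(path, series: VolumeSeries, ground_truth: dict | None = None) -> None:
    """Write a TZYX TIFF plus a JSON sidecar with calibration/ground truth."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(series.data, dtype=np.float32),
                     photometric="minisblack", metadata={"axes": "TZYX"})
    sidecar = {"spacing": list(series.spacing), "dt": series.dt}
    if ground_truth:
        sidecar["ground_truth"] = ground_truth
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, default=_jsonify))


_TRACKMATE_COLS = {"TRACK_ID": "track_id", "FRAME": "frame",
                   "POSITION_X": "x", "POSITION_Y": "y", "POSITION_Z": "z"}


def read_tracks(path, dialect: str = "auto", dt: float = 1.0) -> TrajectorySet:
    """Read a trajectory CSV in the plain or tracking-table dialect.

    The tracking dialect uses columns ``TRACK_ID, FRAME, POSITION_X/Y[/Z]``
    and may carry extra non-numeric header rows, which are dropped and
    counted; the plain dialect uses ``track_id, frame, x, y[, z]``.
    """
    df = pd.read_csv(path)
    if dialect == "auto":
        dialect = "trackmate" if "TRACK_ID" in df.columns else "plain"
    if dialect == "trackmate":
        missing = [c for c in ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y")
                   if c not in df.columns]
        if missing:
            raise ValueError(f"tracking table missing columns {missing}")
        df = df.rename(columns=_TRACKMATE_COLS)
    elif dialect == "plain":
        missing = [c for c in ("track_id", "frame", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    keep = [c for c in ("track_id", "cluster_id", "frame", "x", "y", "z")
            if c in df.columns]
    df = df[keep]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric[["track_id", "frame", "x", "y"]].isna().any(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} malformed/header row(s)", stacklevel=2)
    df = numeric[~bad]
    df = df.astype({"track_id": int, "frame": int})
    return TrajectorySet(data=df.reset_index(drop=True), dt=dt)


def write_tracks(path, tracks: TrajectorySet) -> None:
    tracks.data.to_csv(path, index=False)


def field_to_frame(fld: VelocityField, sim: SimilarityMap | None = None) -> pd.DataFrame:
    """Tidy per-node table: z, y, x, u, v, w, valid[, similarity]."""
    c = fld.centers.reshape(-1, 3)
    v = fld.vectors.reshape(-1, 3)
    df = pd.DataFrame({
        "z": c[:, 0], "y": c[:, 1], "x": c[:, 2],
        "u": v[:, 0], "v": v[:, 1], "w": v[:, 2],
        "valid": fld.valid.ravel().astype(int),
    })
    if sim is not None:
        df["similarity"] = sim.values.ravel()
        df["similarity_valid"] = sim.valid.ravel().astype(int)
    return df


def write_field_csv(path, fld: VelocityField, sim: SimilarityMap | None = None) -> None:
    field_to_frame(fld, sim).to_csv(path, index=False, float_format="%.9g")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2,
                                     default=_jsonify) + "\n")
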