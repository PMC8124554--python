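"""Tab-separated readers and writers for recordings, annotations and series.

Kinematic TSV layout: a ``time`` column followed, for every joint ``J`` in
canonical order, by ``J_x J_y J_z J_qw J_qx J_qy J_qz`` (meters / unit
quaternion components, scalar-first).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import (
    AngleSeries,
    KinematicRecording,
    SegmentAnnotation,
    validate_annotations,
)
from .errors import FormatError, IntegrityError
from .skeleton import JOINT_ORDER

_SUFFIXES = ("x", "y", "z", "qw", "qx", "qy", "qz")


def _columns() -> list[str]:
    cols = ["time"]
    for j in JOINT_ORDER:
        cols.extend(f"{j.value}_{s}" for s in _SUFFIXES)
    return cols


def read_recording(
    path: str | os.PathLike,
    system: str,
    nominal_rate: float | None = None,
    tracker_config: int | None = None,
) -> KinematicRecording:
    """Read a kinematic TSV file into a :class:`KinematicRecording`.

    Quaternions are normalized on read.  Raises :class:`FormatError` naming
    the first missing column, and :class:`IntegrityError` for non-monotone
    timestamps.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _columns():
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    times = df["time"].to_numpy(dtype=float)
    n = len(times)
    positions = np.empty((n, len(JOINT_ORDER), 3))
    quaternions = np.empty((n, len(JOINT_ORDER), 4))
    for k, j in enumerate(JOINT_ORDER):
        for a, s in enumerate(("x", "y", "z")):
            positions[:, k, a] = df[f"{j.value}_{s}"].to_numpy(dtype=float)
        for a, s in enumerate(("qw", "qx", "qy", "qz")):
            quaternions[:, k, a] = df[f"{j.value}_{s}"].to_numpy(dtype=float)
    if n > 1 and np.any(np.diff(times) <= 0):
        raise IntegrityError(f"non-monotone timestamps in {path}")
    if nominal_rate is None:
        nominal_rate = 1.0 / float(np.median(np.diff(times))) if n > 1 else 100.0
    return KinematicRecording(
        system=system,
        nominal_rate=nominal_rate,
        times=times,
        positions=positions,
        quaternions=quaternions,
        tracker_config=tracker_config,
    )


def write_recording(recording: KinematicRecording, path: str | os.PathLike) -> None:
    """Write a recording to TSV (quaternions are stored normalized)."""
    n = len(recording)
    data: dict[str, np.ndarray] = {"time": recording.times}
    for k, j in enumerate(JOINT_ORDER):
        for a, s in enumerate(("x", "y", "z")):
            data[f"{j.value}_{s}"] = recording.positions[:, k, a] if n else np.empty(0)
        for a, s in enumerate(("qw", "qx", "qy", "qz")):
            data[f"{j.value}_{s}"] = recording.quaternions[:, k, a] if n else np.empty(0)
    pd.DataFrame(data, columns=_columns()).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_annotations(path: str | os.PathLike) -> list[SegmentAnnotation]:
    """Read a segment-annotation TSV (movement_id, t_start, t_end, linked_angles)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"movement_id": str}, keep_default_na=False
    )
    for col in ("movement_id", "t_start", "t_end", "linked_angles"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    anns = []
    for _, row in df.iterrows():
        linked = tuple(a for a in str(row["linked_angles"]).split(",") if a)
        anns.append(
            SegmentAnnotation(
                movement_id=str(row["movement_id"]).zfill(2),
                t_start=float(row["t_start"]),
                t_end=float(row["t_end"]),
                linked_angles=linked,
            )
        )
    return validate_annotations(anns)


def write_annotations(
    annotations: list[SegmentAnnotation], path: str | os.PathLike
) -> None:
    anns = validate_annotations(list(annotations))
    df = pd.DataFrame(
        {
            "movement_id": [a.movement_id for a in anns],
            "t_start": [a.t_start for a in anns],
            "t_end": [a.t_end for a in anns],
            "linked_angles": [",".join(a.linked_angles) for a in anns],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_angle_series(
    series: dict[str, AngleSeries], path: str | os.PathLike
) -> None:
    """Write sample-aligned angle series as one TSV (`time` + one column each)."""
    names = list(series)
    times = series[names[0]].times
    data = {"time": times}
    for name in names:
        s = series[name]
        if len(s) != len(times) or np.max(np.abs(s.times - times), initial=0) > 1e-9:
            raise IntegrityError("angle series are not sample-aligned")
        vals = s.values.copy()
        vals[~s.valid] = np.nan
        data[name] = vals
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_angle_series(path: str | os.PathLike) -> dict[str, AngleSeries]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "time" not in df.columns:
        raise FormatError(f"missing column 'time' in {path}")
    times = df["time"].to_numpy(dtype=float)
    return {
        c: AngleSeries(c, times, df[c].to_numpy(dtype=float))
        for c in df.columns
        if c != "time"
    }
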