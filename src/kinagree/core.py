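"""Core containers: frames, recordings, angle series, segment annotations.

Recordings are stored array-backed (times ``(N,)``, positions ``(N, 20, 3)``,
quaternions ``(N, 20, 4)`` scalar-first) for vectorized processing; a
:class:`SkeletonFrame` view of any index is available for per-frame work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, IntegrityError, UsageError
from .skeleton import JOINT_ORDER, JointId

# ---------------------------------------------------------------------------
# quaternion helpers (Hamilton convention, scalar-first: w, x, y, z)


def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Normalize quaternion(s) to unit norm; raises on zero norm."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        from .errors import GeometryError

        raise GeometryError("zero quaternion cannot be normalized")
    return q / n


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def quat_mul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (scalar-first, broadcastable)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v by unit quaternion(s) q."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = q[..., 1:]
    qw = q[..., :1]
    t = 2.0 * np.cross(qv, v)
    return v + qw * t + np.cross(qv, t)


# ---------------------------------------------------------------------------


@dataclass
class SkeletonFrame:
    """One timestamped snapshot of all 20 joints (positions + orientations)."""

    t: float
    positions: dict[JointId, np.ndarray]
    orientations: dict[JointId, np.ndarray]

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise IntegrityError(f"frame timestamp {self.t} not finite/non-negative")
        missing = [j for j in JOINT_ORDER if j not in self.positions]
        if missing:
            raise IntegrityError(f"frame missing joints: {missing}")


@dataclass
class KinematicRecording:
    """Time-ordered skeleton stream from one system.

    Parameters
    ----------
    system : {"reference", "vr"}
    nominal_rate : nominal sample rate in Hz.
    tracker_config : number of tracked points (3/4/6/8/9) or None for the
        marker-based reference system.
    times, positions, quaternions : arrays of shape (N,), (N, 20, 3),
        (N, 20, 4); quaternions scalar-first, normalized on construction.
    """

    system: str
    nominal_rate: float
    times: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray
    tracker_config: int | None = None

    def __post_init__(self) -> None:
        if self.system not in ("reference", "vr"):
            raise IntegrityError(f"unknown system label {self.system!r}")
        if self.tracker_config is not None and self.tracker_config not in (3, 4, 6, 8, 9):
            raise IntegrityError(f"tracker_config {self.tracker_config} not in {{3,4,6,8,9}}")
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        n = len(self.times)
        if self.positions.shape != (n, len(JOINT_ORDER), 3):
            raise IntegrityError("positions array has wrong shape")
        if self.quaternions.shape != (n, len(JOINT_ORDER), 4):
            raise IntegrityError("quaternions array has wrong shape")
        if n:
            if np.any(np.diff(self.times) <= 0):
                raise IntegrityError("timestamps must be strictly increasing")
            if self.system == "reference" and n > 2:
                dt = np.diff(self.times)
                if np.ptp(dt) > 1e-9:
                    raise IntegrityError(
                        "reference recording must have constant frame spacing"
                    )
            self.quaternions = quat_normalize(self.quaternions)

    def __len__(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            t=float(self.times[i]),
            positions={j: self.positions[i, k] for k, j in enumerate(JOINT_ORDER)},
            orientations={j: self.quaternions[i, k] for k, j in enumerate(JOINT_ORDER)},
        )

    @property
    def frames(self) -> list[SkeletonFrame]:
        return [self.frame(i) for i in range(len(self))]

    def joint_positions(self, joint: JointId) -> np.ndarray:
        return self.positions[:, JOINT_ORDER.index(joint), :]

    def joint_quaternions(self, joint: JointId) -> np.ndarray:
        return self.quaternions[:, JOINT_ORDER.index(joint), :]

    def copy(self) -> "KinematicRecording":
        return replace(
            self,
            times=self.times.copy(),
            positions=self.positions.copy(),
            quaternions=self.quaternions.copy(),
        )


@dataclass
class AngleSeries:
    """A single joint-angle time series in degrees.

    ``valid`` flags samples; invalid samples carry NaN values and are
    skipped by downstream statistics.
    """

    name: str
    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.valid)):
            raise IntegrityError("times/values/valid length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise IntegrityError("angle series timestamps must be strictly increasing")
        if np.any(~np.isfinite(self.values[self.valid])):
            raise IntegrityError("non-finite value marked valid")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, t0: float, t1: float) -> "AngleSeries":
        m = (self.times >= t0) & (self.times <= t1)
        return AngleSeries(self.name, self.times[m], self.values[m], self.valid[m])

    def copy(self) -> "AngleSeries":
        return AngleSeries(
            self.name, self.times.copy(), self.values.copy(), self.valid.copy()
        )


# movement catalogue: id -> default linked angle names (empty cells stay empty)
PREAMBLE_ID = "00"  # synchronization preamble; not one of the 20 movements

MOVEMENT_TABLE: dict[str, tuple[str, ...]] = {
    "01": ("head_inc", "neck_flex"),
    "02": ("head_latinc", "neck_latflex"),
    "03": (),
    "04": ("chest_flex", "pelvis_flex"),
    "05": ("chest_flex", "pelvis_flex"),
    "06": (),
    "07": (),
    "08": ("shoulder_left_elev",),
    "09": ("shoulder_right_elev",),
    "10": ("shoulder_left_elev", "shoulder_right_elev"),
    "11": ("shoulder_left_elev",),
    "12": ("shoulder_right_elev",),
    "13": ("shoulder_left_elev", "shoulder_right_elev"),
    "14": (),
    "15": (
        "elbow_left_flex",
        "elbow_right_flex",
        "elbow_left_azim",
        "elbow_right_azim",
    ),
    "16": ("knee_left_flex",),
    "17": ("knee_right_flex",),
    "18": (),
    "19": ("hip_right_flex",),
    "20": ("hip_left_flex",),
}

ANGLE_NAMES: tuple[str, ...] = (
    "head_inc",
    "head_latinc",
    "neck_flex",
    "neck_latflex",
    "chest_flex",
    "pelvis_flex",
    "shoulder_left_elev",
    "shoulder_right_elev",
    "elbow_left_flex",
    "elbow_right_flex",
    "elbow_left_azim",
    "elbow_right_azim",
    "hip_left_flex",
    "hip_right_flex",
    "knee_left_flex",
    "knee_right_flex",
)


@dataclass
class SegmentAnnotation:
    """Labeled time window for one scripted movement."""

    movement_id: str
    t_start: float
    t_end: float
    linked_angles: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.movement_id != PREAMBLE_ID and self.movement_id not in MOVEMENT_TABLE:
            raise IntegrityError(f"unknown movement id {self.movement_id!r}")
        if not self.t_start < self.t_end:
            raise IntegrityError(
                f"segment {self.movement_id}: t_start {self.t_start} >= t_end {self.t_end}"
            )
        bad = [a for a in self.linked_angles if a not in ANGLE_NAMES]
        if bad:
            raise IntegrityError(f"segment {self.movement_id}: unknown angles {bad}")
        self.linked_angles = tuple(self.linked_angles)


def validate_annotations(annotations: list[SegmentAnnotation]) -> list[SegmentAnnotation]:
    """Sort by t_start and reject overlapping segments."""
    anns = sorted(annotations, key=lambda a: a.t_start)
    for a, b in zip(anns, anns[1:]):
        if b.t_start < a.t_end:
            raise IntegrityError(
                f"segments {a.movement_id} and {b.movement_id} overlap in time"
            )
    return anns


def select_linked_segments(
    annotations: list[SegmentAnnotation], angle_name: str
) -> list[tuple[float, float]]:
    """Time windows of all segments linked to `angle_name`, in time order."""
    if angle_name not in ANGLE_NAMES:
        raise UsageError(f"unknown angle name {angle_name!r}")
    hits = [a for a in annotations if angle_name in a.linked_angles]
    hits.sort(key=lambda a: a.t_start)
    return [(a.t_start, a.t_end) for a in hits]


def concatenate_segments(
    series: AngleSeries, windows: list[tuple[float, float]]
) -> AngleSeries:
    """Samples of `series` falling inside any window, timestamps preserved.

    The output keeps the original timestamps; because windows are
    non-overlapping and processed in time order, timestamps remain strictly
    increasing.
    """
    if not windows:
        return AngleSeries(series.name, np.empty(0), np.empty(0), np.empty(0, bool))
    mask = np.zeros(len(series), dtype=bool)
    for t0, t1 in windows:
        mask |= (series.times >= t0) & (series.times <= t1)
    return AngleSeries(
        series.name, series.times[mask], series.values[mask], series.valid[mask]
    )


def aligned_pair(ref: AngleSeries, vr: AngleSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common-valid (times, ref values, vr values) from two aligned series."""
    if len(ref) != len(vr):
        raise AlignmentError(f"length mismatch: {len(ref)} vs {len(vr)}")
    m = ref.valid & vr.valid
    return ref.times[m], ref.values[m], vr.values[m]
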