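"""Derivation of the 16 joint angles from skeleton kinematics.

Three methods are used, mirroring standard biomechanical practice:

* **plane-referenced** angles: anatomical reference planes (frontal,
  sagittal, transversal) are attached locally to a joint and oriented by a
  torso axis and the shoulder (or hip) line; the signed angle of a limb
  vector is measured inside one plane, from a neutral direction.  A
  straight-forward pointing arm has a shoulder elevation of +90 deg, a
  straight-backward one -90 deg, and a hanging arm 0 deg.
* **three-point flexion**: the interior angle at the middle of three joint
  positions by the law of cosines, reported as ``180 deg - alpha`` so a
  straight limb reads 0 deg (elbows and knees).
* **quaternion relative rotation**: for end joints (here the head) the
  relative rotation ``q12 = q1^-1 (x) q2`` between the joint and its
  predecessor is decomposed into intrinsic y-x-z Euler angles, yielding
  sagittal inclination and lateral inclination.

All angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    ANGLE_NAMES,
    AngleSeries,
    KinematicRecording,
    SkeletonFrame,
    quat_conjugate,
    quat_mul,
    quat_normalize,
)
from .errors import GeometryError, UsageError
from .skeleton import JointId

_EPS_SEP = 1e-6  # m, minimum joint separation
_EPS_PROJ = 1e-9  # m, minimum in-plane projection norm
GIMBAL_MARGIN = 0.5  # deg around +-90 pitch flagged for the Euler decomposition

_LOWER_BODY = {
    JointId.hip_center,
    JointId.hip_left,
    JointId.hip_right,
    JointId.knee_left,
    JointId.knee_right,
}


@dataclass
class BodyPlane:
    """One anatomical reference plane attached at ``origin``."""

    kind: str  # frontal | sagittal | transversal
    origin: np.ndarray
    unit_normal: np.ndarray


@dataclass
class AngleDefinition:
    """Declarative definition of one joint angle.

    For ``plane_referenced``: the local triad is attached at
    ``plane_origin_joint`` and oriented by the torso axis running from the
    second to the first of ``orienting_joints`` and by the shoulder/hip
    line; the vector to ``target_joint`` is projected into
    ``containing_plane`` and measured from ``zero_direction``
    (up/down/anterior), positive toward ``positive_direction``.
    ``axis_from_calibration`` holds the torso axis from a calibration
    (neutral) frame instead of the current one.

    For ``three_point_flexion``: ``triple`` is (outer, middle, outer).
    For ``quaternion_relative``: ``predecessor_joint`` and ``component``
    (inclination | lateral) select the extracted Euler component.
    """

    name: str
    method: str
    target_joint: JointId | None = None
    plane_origin_joint: JointId | None = None
    orienting_joints: tuple[JointId, JointId] | None = None
    measured_plane: str | None = None
    containing_plane: str | None = None
    zero_direction: str | None = None
    positive_direction: str | None = None
    axis_from_calibration: bool = False
    triple: tuple[JointId, JointId, JointId] | None = None
    predecessor_joint: JointId | None = None
    component: str | None = None
    #: m; below this in-plane projection the direction is unreliable (a few
    #: degrees of limb deviation) and the sample is flagged missing
    min_projection: float = 0.02

    def __post_init__(self) -> None:
        if self.method not in (
            "plane_referenced",
            "three_point_flexion",
            "quaternion_relative",
        ):
            raise UsageError(f"unknown angle method {self.method!r}")
        if self.method == "plane_referenced" and None in (
            self.target_joint,
            self.plane_origin_joint,
            self.orienting_joints,
            self.containing_plane,
            self.zero_direction,
            self.positive_direction,
        ):
            raise UsageError(f"{self.name}: incomplete plane-referenced definition")
        if self.method == "three_point_flexion" and self.triple is None:
            raise UsageError(f"{self.name}: three-point definition needs a joint triple")
        if self.method == "quaternion_relative" and None in (
            self.target_joint,
            self.predecessor_joint,
            self.component,
        ):
            raise UsageError(f"{self.name}: incomplete quaternion definition")


# ---------------------------------------------------------------------------
# triads


def _unit(v: np.ndarray, what: str, eps: float = _EPS_SEP) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < eps):
        raise GeometryError(f"degenerate geometry: {what}")
    return v / n


def _triad_vectors(
    axis_first: np.ndarray,
    axis_second: np.ndarray,
    lateral_left: np.ndarray,
    lateral_right: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(up, left, anterior) unit vectors; inputs broadcast over leading axes."""
    u = _unit(axis_first - axis_second, "coincident orienting joints")
    l_raw = lateral_left - lateral_right
    l_orth = l_raw - np.sum(l_raw * u, axis=-1, keepdims=True) * u
    left = _unit(l_orth, "lateral line parallel to torso axis")
    anterior = np.cross(left, u)
    return u, left, anterior


def _lateral_joints(origin: JointId) -> tuple[JointId, JointId]:
    if origin in _LOWER_BODY:
        return JointId.hip_left, JointId.hip_right
    return JointId.shoulder_left, JointId.shoulder_right


def build_local_triad(
    frame: SkeletonFrame,
    origin_joint: JointId,
    orienting_joints: tuple[JointId, JointId],
) -> tuple[BodyPlane, BodyPlane, BodyPlane]:
    """Build the (frontal, sagittal, transversal) planes at ``origin_joint``.

    The torso axis (transversal normal) runs from the second to the first
    orienting joint; the shoulder line (hip line for lower-body origins)
    supplies the sagittal normal after Gram-Schmidt orthogonalization; the
    frontal normal (anterior) completes the right-handed triad.
    """
    a_first = frame.positions[orienting_joints[0]]
    a_second = frame.positions[orienting_joints[1]]
    lj, rj = _lateral_joints(origin_joint)
    u, left, anterior = _triad_vectors(
        np.asarray(a_first, float),
        np.asarray(a_second, float),
        np.asarray(frame.positions[lj], float),
        np.asarray(frame.positions[rj], float),
    )
    origin = np.asarray(frame.positions[origin_joint], float)
    return (
        BodyPlane("frontal", origin, anterior),
        BodyPlane("sagittal", origin, left),
        BodyPlane("transversal", origin, u),
    )


# ---------------------------------------------------------------------------
# plane-referenced angles


def _plane_angle_arrays(
    v: np.ndarray,
    up: np.ndarray,
    left: np.ndarray,
    anterior: np.ndarray,
    definition: AngleDefinition,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed angle (degrees) and validity for target vectors ``v``."""
    if definition.containing_plane == "sagittal":
        e1, e2 = anterior, up
    elif definition.containing_plane == "frontal":
        e1, e2 = left, up
    elif definition.containing_plane == "transversal":
        e1, e2 = anterior, left
    else:
        raise UsageError(f"unknown plane kind {definition.containing_plane!r}")

    basis = {"up": up, "down": -up, "anterior": anterior}
    zero = basis[definition.zero_direction]
    pos = {
        "anterior": anterior,
        "left": left,
        "lateral_left": left,
        "lateral_right": -left,
    }[definition.positive_direction]

    c1 = np.sum(v * e1, axis=-1)
    c2 = np.sum(v * e2, axis=-1)
    valid = np.hypot(c1, c2) >= max(_EPS_PROJ, definition.min_projection)
    cz = np.sum(v * zero, axis=-1)
    cp = np.sum(v * pos, axis=-1)
    angle = np.degrees(np.arctan2(cp, cz))
    return angle, valid


def plane_referenced_angle(
    frame: SkeletonFrame,
    definition: AngleDefinition,
    calibration_frame: SkeletonFrame | None = None,
) -> float:
    """Signed plane-referenced angle for one frame (degrees, NaN if undefined).

    ``calibration_frame`` supplies the held torso axis for definitions with
    ``axis_from_calibration``; it defaults to ``frame`` itself.
    """
    if definition.method != "plane_referenced":
        raise UsageError(f"{definition.name} is not plane-referenced")
    cal = calibration_frame if definition.axis_from_calibration and calibration_frame else frame
    oj = definition.orienting_joints
    axis_frame = cal
    lj, rj = _lateral_joints(definition.plane_origin_joint)
    u, left, anterior = _triad_vectors(
        np.asarray(axis_frame.positions[oj[0]], float),
        np.asarray(axis_frame.positions[oj[1]], float),
        np.asarray(frame.positions[lj], float),
        np.asarray(frame.positions[rj], float),
    )
    v = np.asarray(frame.positions[definition.target_joint], float) - np.asarray(
        frame.positions[definition.plane_origin_joint], float
    )
    angle, valid = _plane_angle_arrays(v, u, left, anterior, definition)
    return float(angle) if bool(valid) else float("nan")


# ---------------------------------------------------------------------------
# three-point flexion


def three_point_flexion(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Flexion at the middle joint ``p2`` from three positions (degrees).

    Segment lengths a=|p1-p3|, b=|p2-p3|, c=|p1-p2| enter the law of
    cosines; the interior angle alpha at p2 is complemented to
    ``180 - alpha`` so a straight limb reads zero.
    """
    vals = _three_point_arrays(
        np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float)
    )
    return float(vals)


def _three_point_arrays(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    a = np.linalg.norm(p1 - p3, axis=-1)
    b = np.linalg.norm(p2 - p3, axis=-1)
    c = np.linalg.norm(p1 - p2, axis=-1)
    if np.any(b < _EPS_SEP) or np.any(c < _EPS_SEP):
        raise GeometryError("zero-length segment in three-point flexion")
    cos_alpha = (b**2 + c**2 - a**2) / (2.0 * b * c)
    if np.any(np.abs(cos_alpha) > 1.0 + 1e-9):
        import warnings

        warnings.warn("degenerate triangle in three-point flexion; cosine clamped")
    alpha = np.degrees(np.arccos(np.clip(cos_alpha, -1.0, 1.0)))
    return 180.0 - alpha


# ---------------------------------------------------------------------------
# quaternion relative rotation


def relative_rotation(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Relative rotation ``q12 = q1^-1 (x) q2`` (Hamilton, scalar-first).

    The result is normalized and hemisphere-fixed so its scalar part is
    non-negative.
    """
    q1 = quat_normalize(q1)
    q2 = quat_normalize(q2)
    q12 = quat_normalize(quat_mul(quat_conjugate(q1), q2))
    sign = np.where(q12[..., :1] < 0.0, -1.0, 1.0)
    return q12 * sign


def quaternion_angle_pair(
    q_target: np.ndarray, q_predecessor: np.ndarray
) -> tuple[float, float]:
    """(inclination, lateral inclination) in degrees from two orientations.

    The relative rotation of the target with respect to its predecessor is
    decomposed into intrinsic y-x-z Euler angles in the local frame; the
    pitch term is the sagittal inclination (forward positive) and the roll
    term the lateral inclination (left positive).
    """
    inc, lat, _ = _quaternion_angles_arrays(
        np.asarray(q_target, float)[None, :], np.asarray(q_predecessor, float)[None, :]
    )
    return float(inc[0]), float(lat[0])


def _quaternion_angles_arrays(
    q_target: np.ndarray, q_predecessor: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q12 = relative_rotation(q_target, q_predecessor)
    # q12 maps the predecessor frame into the target frame; the local
    # rotation of the target relative to its predecessor is the conjugate.
    local = quat_conjugate(q12)
    eul = Rotation.from_quat(local, scalar_first=True).as_euler("YXZ", degrees=True)
    pitch = eul[..., 0]
    roll = eul[..., 1]
    valid = np.abs(np.abs(pitch) - 90.0) >= GIMBAL_MARGIN
    return pitch, -roll, valid


# ---------------------------------------------------------------------------
# default catalogue of the 16 angles


def _plane(name: str, target: JointId, origin: JointId, axis, containing, zero, pos,
           measured, cal: bool = False) -> AngleDefinition:
    return AngleDefinition(
        name=name,
        method="plane_referenced",
        target_joint=target,
        plane_origin_joint=origin,
        orienting_joints=axis,
        measured_plane=measured,
        containing_plane=containing,
        zero_direction=zero,
        positive_direction=pos,
        axis_from_calibration=cal,
    )


def default_definitions() -> dict[str, AngleDefinition]:
    J = JointId
    defs = [
        AngleDefinition("head_inc", "quaternion_relative", target_joint=J.head,
                        predecessor_joint=J.neck, component="inclination"),
        AngleDefinition("head_latinc", "quaternion_relative", target_joint=J.head,
                        predecessor_joint=J.neck, component="lateral"),
        _plane("neck_flex", J.head, J.neck, (J.neck, J.shoulder_center),
               "sagittal", "up", "anterior", "frontal"),
        _plane("neck_latflex", J.head, J.neck, (J.neck, J.shoulder_center),
               "frontal", "up", "left", "sagittal"),
        _plane("chest_flex", J.shoulder_center, J.chest, (J.chest, J.spine_mid),
               "sagittal", "up", "anterior", "frontal"),
        _plane("pelvis_flex", J.spine_mid, J.hip_center, (J.spine_mid, J.hip_center),
               "sagittal", "up", "anterior", "frontal", cal=True),
        _plane("shoulder_left_elev", J.elbow_left, J.shoulder_left,
               (J.shoulder_center, J.chest), "sagittal", "down", "anterior", "frontal"),
        _plane("shoulder_right_elev", J.elbow_right, J.shoulder_right,
               (J.shoulder_center, J.chest), "sagittal", "down", "anterior", "frontal"),
        AngleDefinition("elbow_left_flex", "three_point_flexion",
                        triple=(J.shoulder_left, J.elbow_left, J.hand_left)),
        AngleDefinition("elbow_right_flex", "three_point_flexion",
                        triple=(J.shoulder_right, J.elbow_right, J.hand_right)),
        _plane("elbow_left_azim", J.elbow_left, J.shoulder_left,
               (J.shoulder_center, J.chest), "transversal", "anterior",
               "lateral_left", "sagittal"),
        _plane("elbow_right_azim", J.elbow_right, J.shoulder_right,
               (J.shoulder_center, J.chest), "transversal", "anterior",
               "lateral_right", "sagittal"),
        _plane("hip_left_flex", J.knee_left, J.hip_left, (J.spine_mid, J.hip_center),
               "sagittal", "down", "anterior", "frontal"),
        _plane("hip_right_flex", J.knee_right, J.hip_right, (J.spine_mid, J.hip_center),
               "sagittal", "down", "anterior", "frontal"),
        AngleDefinition("knee_left_flex", "three_point_flexion",
                        triple=(J.hip_left, J.knee_left, J.ankle_left)),
        AngleDefinition("knee_right_flex", "three_point_flexion",
                        triple=(J.hip_right, J.knee_right, J.ankle_right)),
    ]
    out = {d.name: d for d in defs}
    assert tuple(out) == ANGLE_NAMES
    return out


# ---------------------------------------------------------------------------
# whole-recording evaluation


def compute_angle_series(
    recording: KinematicRecording,
    definitions: dict[str, AngleDefinition] | None = None,
    calibration_index: int = 0,
) -> dict[str, AngleSeries]:
    """Evaluate angle definitions over a whole recording (vectorized).

    Returns one :class:`AngleSeries` per definition, sample-aligned with the
    recording timestamps; samples with degenerate geometry or gimbal
    proximity are flagged invalid (NaN).
    """
    if definitions is None:
        definitions = default_definitions()
    n = len(recording)
    out: dict[str, AngleSeries] = {}
    pos = {j: recording.joint_positions(j) for j in JointId}
    qua = {j: recording.joint_quaternions(j) for j in JointId}

    for name, d in definitions.items():
        if n == 0:
            out[name] = AngleSeries(name, np.empty(0), np.empty(0), np.empty(0, bool))
            continue
        if d.method == "three_point_flexion":
            p1, p2, p3 = (pos[j] for j in d.triple)
            values = _three_point_arrays(p1, p2, p3)
            valid = np.isfinite(values)
        elif d.method == "quaternion_relative":
            inc, lat, valid = _quaternion_angles_arrays(
                qua[d.target_joint], qua[d.predecessor_joint]
            )
            values = inc if d.component == "inclination" else lat
        else:
            oj = d.orienting_joints
            if d.axis_from_calibration:
                af = pos[oj[0]][calibration_index][None, :]
                as_ = pos[oj[1]][calibration_index][None, :]
            else:
                af, as_ = pos[oj[0]], pos[oj[1]]
            lj, rj = _lateral_joints(d.plane_origin_joint)
            u, left, anterior = _triad_vectors(af, as_, pos[lj], pos[rj])
            v = pos[d.target_joint] - pos[d.plane_origin_joint]
            values, valid = _plane_angle_arrays(
                v, np.broadcast_to(u, v.shape), np.broadcast_to(left, v.shape),
                np.broadcast_to(anterior, v.shape), d
            )
        values = np.where(valid, values, np.nan)
        out[name] = AngleSeries(name, recording.times.copy(), values, valid)
    return out
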