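"""Joint-angle derivation: anchors, oracles, and geometric invariances.

Each of the three angle methods is checked against an independently coded
oracle (explicit rotation matrices / dot products) on random inputs, and
the canonical-pose anchors of the shoulder elevation convention are pinned
exactly.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import kinagree as kg
from kinagree.angles import (
    build_local_triad,
    default_definitions,
    plane_referenced_angle,
    quaternion_angle_pair,
    relative_rotation,
    three_point_flexion,
)
from kinagree.core import quat_mul, quat_normalize
from kinagree.errors import GeometryError
from kinagree.skeleton import JOINT_ORDER, JointId

from conftest import canonical_pose


def _rot_apply(frame, R, t=None):
    """A frame with every joint rigidly rotated (and translated)."""
    t = np.zeros(3) if t is None else t
    pos = {j: R @ p + t for j, p in frame.positions.items()}
    qR = Rotation.from_matrix(R).as_quat(scalar_first=True)
    quat = {j: quat_normalize(quat_mul(qR, q)) for j, q in frame.orientations.items()}
    return kg.SkeletonFrame(frame.t, pos, quat)


class TestTriads:
    def test_neutral_pose_aligns_with_global_axes(self, neutral_frame):
        frontal, sagittal, transversal = build_local_triad(
            neutral_frame, JointId.shoulder_left, (JointId.shoulder_center, JointId.chest)
        )
        assert np.allclose(frontal.unit_normal, [1, 0, 0], atol=1e-6)
        assert np.allclose(sagittal.unit_normal, [0, 1, 0], atol=1e-6)
        assert np.allclose(transversal.unit_normal, [0, 0, 1], atol=1e-6)
        assert np.allclose(
            frontal.origin, neutral_frame.positions[JointId.shoulder_left]
        )

    def test_pitched_torso_tilts_transversal_normal(self, neutral_frame):
        R = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        frame = _rot_apply(neutral_frame, R)
        _, _, transversal = build_local_triad(
            frame, JointId.shoulder_left, (JointId.shoulder_center, JointId.chest)
        )
        assert np.allclose(transversal.unit_normal, [1, 0, 0], atol=1e-6)

    def test_triad_is_orthonormal(self, neutral_frame):
        planes = build_local_triad(
            neutral_frame, JointId.neck, (JointId.neck, JointId.shoulder_center)
        )
        normals = np.array([p.unit_normal for p in planes])
        assert np.allclose(normals @ normals.T, np.eye(3), atol=1e-6)

    def test_coincident_orienting_joints_rejected(self, neutral_frame):
        pos = {j: p.copy() for j, p in neutral_frame.positions.items()}
        pos[JointId.shoulder_center] = pos[JointId.chest]
        frame = kg.SkeletonFrame(0.0, pos, neutral_frame.orientations)
        with pytest.raises(GeometryError):
            build_local_triad(
                frame, JointId.shoulder_left, (JointId.shoulder_center, JointId.chest)
            )


class TestShoulderElevationAnchors:
    """The sign convention of the plane-referenced elevation."""

    @pytest.mark.parametrize(
        "arm, expected",
        [("forward", 90.0), ("backward", -90.0), ("down", 0.0)],
    )
    def test_canonical_arm_poses(self, arm, expected):
        frame = canonical_pose(arm)
        d = default_definitions()["shoulder_left_elev"]
        assert plane_referenced_angle(frame, d) == pytest.approx(expected, abs=1e-9)


class TestPlaneReferencedOracle:
    def _oracle(self, frame, d):
        """Independent computation from explicitly built rotation matrices."""
        first = frame.positions[d.orienting_joints[0]]
        second = frame.positions[d.orienting_joints[1]]
        u = first - second
        u = u / np.linalg.norm(u)
        lj, rj = (
            (JointId.hip_left, JointId.hip_right)
            if d.plane_origin_joint
            in (JointId.hip_center, JointId.hip_left, JointId.hip_right)
            else (JointId.shoulder_left, JointId.shoulder_right)
        )
        lraw = frame.positions[lj] - frame.positions[rj]
        left = lraw - (lraw @ u) * u
        left = left / np.linalg.norm(left)
        ant = np.cross(left, u)
        B = np.column_stack([ant, left, u])  # world <- body rotation matrix
        v = B.T @ (
            frame.positions[d.target_joint] - frame.positions[d.plane_origin_joint]
        )  # v in body coordinates (anterior, left, up)
        zero = {"up": np.array([0.0, 0, 1]), "down": np.array([0.0, 0, -1]),
                "anterior": np.array([1.0, 0, 0])}[d.zero_direction]
        pos = {"anterior": np.array([1.0, 0, 0]), "left": np.array([0.0, 1, 0]),
               "lateral_left": np.array([0.0, 1, 0]),
               "lateral_right": np.array([0.0, -1, 0])}[d.positive_direction]
        return np.degrees(np.arctan2(v @ pos, v @ zero))

    def test_matches_matrix_oracle_on_random_poses(self, neutral_frame, rng):
        defs = [
            d for d in default_definitions().values()
            if d.method == "plane_referenced" and not d.axis_from_calibration
        ]
        base = neutral_frame
        for _ in range(1000 // len(defs) + 1):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3)
            jitter = {
                j: base.positions[j] + rng.normal(scale=0.02, size=3)
                for j in JOINT_ORDER
            }
            frame = _rot_apply(
                kg.SkeletonFrame(0.0, jitter, base.orientations), R, t
            )
            for d in defs:
                got = plane_referenced_angle(frame, d)
                if np.isnan(got):  # projection too small to carry a direction
                    continue
                want = self._oracle(frame, d)
                assert got == pytest.approx(want, abs=1e-6)

    def test_output_range(self, neutral_frame, rng):
        d = default_definitions()["shoulder_left_elev"]
        for _ in range(200):
            jitter = {
                j: neutral_frame.positions[j] + rng.normal(scale=0.05, size=3)
                for j in JOINT_ORDER
            }
            frame = kg.SkeletonFrame(0.0, jitter, neutral_frame.orientations)
            v = plane_referenced_angle(frame, d)
            assert np.isnan(v) or -180.0 <= v <= 180.0


class TestThreePointFlexion:
    def test_straight_limb_reads_zero(self):
        assert three_point_flexion(
            np.array([0, 0, 1.0]), np.array([0, 0, 0.5]), np.array([0, 0, 0.0])
        ) == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_at_knee(self):
        assert three_point_flexion(
            np.array([0, 0, 1.0]), np.array([0, 0, 0.5]), np.array([0, 0.5, 0.5])
        ) == pytest.approx(90.0, abs=1e-9)

    def test_matches_dot_product_oracle(self, rng):
        for _ in range(1000):
            p1, p2, p3 = rng.normal(size=(3, 3))
            if min(np.linalg.norm(p1 - p2), np.linalg.norm(p3 - p2)) < 1e-3:
                continue
            got = three_point_flexion(p1, p2, p3)
            a, b = p1 - p2, p3 - p2
            cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            want = 180.0 - np.degrees(np.arccos(np.clip(cos, -1, 1)))
            assert got == pytest.approx(want, abs=1e-9)
            assert 0.0 <= got <= 180.0

    def test_zero_length_segment_rejected(self):
        p = np.array([0.0, 0, 0])
        with pytest.raises(GeometryError):
            three_point_flexion(np.array([1.0, 0, 0]), p, p)


class TestRelativeRotation:
    def test_identical_quaternions_give_identity(self):
        q = quat_normalize(np.array([0.3, 0.2, -0.4, 0.8]))
        assert np.allclose(relative_rotation(q, q), [1, 0, 0, 0], atol=1e-12)

    def test_identity_times_rotation(self):
        q2 = Rotation.from_euler("x", 30, degrees=True).as_quat(scalar_first=True)
        q12 = relative_rotation(np.array([1.0, 0, 0, 0]), q2)
        assert np.allclose(q12, q2, atol=1e-12)

    def test_matches_matrix_oracle(self, rng):
        for _ in range(1000):
            r1, r2 = Rotation.random(rng=rng), Rotation.random(rng=rng)
            q12 = relative_rotation(
                r1.as_quat(scalar_first=True), r2.as_quat(scalar_first=True)
            )
            want = r1.as_matrix().T @ r2.as_matrix()
            got = Rotation.from_quat(q12, scalar_first=True).as_matrix()
            assert np.allclose(got, want, atol=1e-9)
            assert q12[0] >= 0.0  # hemisphere fixed

    def test_zero_quaternion_rejected(self):
        with pytest.raises(GeometryError):
            relative_rotation(np.zeros(4), np.array([1.0, 0, 0, 0]))


class TestQuaternionAnglePair:
    def test_identity_gives_zero(self):
        q = np.array([1.0, 0, 0, 0])
        assert quaternion_angle_pair(q, q) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_pure_sagittal_tilt(self):
        q_neck = np.array([1.0, 0, 0, 0])
        q_head = Rotation.from_euler("y", 20, degrees=True).as_quat(scalar_first=True)
        inc, lat = quaternion_angle_pair(q_head, q_neck)
        assert inc == pytest.approx(20.0, abs=1e-9)
        assert lat == pytest.approx(0.0, abs=1e-9)

    def test_matches_euler_oracle_for_small_rotations(self, rng):
        for _ in range(500):
            rot = Rotation.from_rotvec(rng.uniform(-0.5, 0.5, 3))  # < ~30 deg
            q_neck = Rotation.random(rng=rng)
            q_head = q_neck * rot
            inc, lat = quaternion_angle_pair(
                q_head.as_quat(scalar_first=True), q_neck.as_quat(scalar_first=True)
            )
            pitch, roll, _ = rot.as_euler("YXZ", degrees=True)
            assert inc == pytest.approx(pitch, abs=1e-6)
            assert lat == pytest.approx(-roll, abs=1e-6)


class TestRecordingLevelInvariances:
    def test_rigid_motion_invariance(self, full_session, full_angles, rng):
        """A global rotation + translation of the whole recording leaves
        every angle unchanged."""
        rec = full_session.recording
        sl = slice(0, 2000, 4)
        sub = kg.KinematicRecording(
            "reference", rec.nominal_rate / 4,
            rec.times[sl], rec.positions[sl], rec.quaternions[sl],
        )
        R = Rotation.random(rng=rng)
        qR = R.as_quat(scalar_first=True)
        moved = kg.KinematicRecording(
            "reference", sub.nominal_rate, sub.times,
            sub.positions @ R.as_matrix().T + rng.normal(size=3),
            quat_mul(qR, sub.quaternions),
        )
        a0 = kg.compute_angle_series(sub)
        a1 = kg.compute_angle_series(moved)
        for name in kg.ANGLE_NAMES:
            m = a0[name].valid & a1[name].valid
            if name.endswith("_flex") and ("elbow" in name or "knee" in name):
                # arccos is ill-conditioned within ~1 deg of a straight limb;
                # float64 rounding alone moves the angle by more than 1e-6 deg
                well = m & (a0[name].values > 1.0)
                assert np.allclose(a0[name].values[well], a1[name].values[well],
                                   atol=1e-6)
                assert np.allclose(a0[name].values[m], a1[name].values[m],
                                   atol=1e-4)
            else:
                assert np.allclose(a0[name].values[m], a1[name].values[m],
                                   atol=1e-6)
            assert np.array_equal(a0[name].valid, a1[name].valid)

    def test_mirror_symmetry_swaps_left_right(self, full_session):
        """Mirroring a pose across the sagittal plane swaps left/right
        angle values exactly."""
        rec = full_session.recording
        sl = slice(0, 2000, 4)
        mirror_pos = rec.positions[sl].copy()
        mirror_pos[..., 1] *= -1.0
        swap = {"left": "right", "right": "left"}
        jidx = {j: k for k, j in enumerate(JOINT_ORDER)}
        swapped = mirror_pos.copy()
        for j in JOINT_ORDER:
            for a, b in swap.items():
                if a in j.value:
                    other = JointId(j.value.replace(a, b))
                    swapped[:, jidx[j]] = mirror_pos[:, jidx[other]]
        # reflection conjugation of a rotation across the y=0 plane flips
        # the in-plane axis components: (w, x, y, z) -> (w, -x, y, -z)
        mq = rec.quaternions[sl].copy()
        mq[..., 1] *= -1.0
        mq[..., 3] *= -1.0
        swq = mq.copy()
        for j in JOINT_ORDER:
            for a, b in swap.items():
                if a in j.value:
                    other = JointId(j.value.replace(a, b))
                    swq[:, jidx[j]] = mq[:, jidx[other]]
        mirrored = kg.KinematicRecording(
            "reference", rec.nominal_rate / 4, rec.times[sl], swapped, swq
        )
        plain = kg.KinematicRecording(
            "reference", rec.nominal_rate / 4, rec.times[sl],
            rec.positions[sl], rec.quaternions[sl],
        )
        a0 = kg.compute_angle_series(plain)
        a1 = kg.compute_angle_series(mirrored)
        for name in ("shoulder_left_elev", "elbow_left_flex", "knee_left_flex",
                     "hip_left_flex", "elbow_left_azim"):
            other = name.replace("left", "right")
            m = a0[name].valid & a1[other].valid
            assert np.allclose(a0[name].values[m], a1[other].values[m], atol=1e-6)


class TestComputeAngleSeries:
    def test_neutral_recording_is_constant(self, full_session):
        rec = full_session.recording
        n = int(2.0 * rec.nominal_rate)  # initial neutral stance
        sub = kg.KinematicRecording(
            "reference", rec.nominal_rate, rec.times[:n],
            rec.positions[:n], rec.quaternions[:n],
        )
        series = kg.compute_angle_series(sub)
        assert len(series) == 16
        for name, s in series.items():
            if s.valid.any():
                assert np.nanstd(s.values[s.valid]) < 1e-6, name

    def test_single_frame_recording(self, full_session):
        rec = full_session.recording
        sub = kg.KinematicRecording(
            "reference", rec.nominal_rate, rec.times[:1],
            rec.positions[:1], rec.quaternions[:1],
        )
        series = kg.compute_angle_series(sub)
        assert all(len(s) == 1 for s in series.values())

    def test_scripted_amplitude_reached(self, full_session, full_angles):
        """The elbow-curl movement spans at least the scripted amplitude."""
        windows = kg.select_linked_segments(full_session.annotations, "elbow_left_flex")
        seg = kg.concatenate_segments(full_angles["elbow_left_flex"], windows)
        rom = np.nanmax(seg.values) - np.nanmin(seg.values)
        assert rom >= 140.0 - 1.0
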