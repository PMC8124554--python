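"""Shared fixtures: generated sessions are expensive, so they are built once
per test session and shared read-only."""

from __future__ import annotations

import numpy as np
import pytest

import kinagree as kg
from kinagree.synth import DegradationParams


@pytest.fixture(scope="session")
def full_session() -> kg.Session:
    """One full scripted protocol session (reference stream + annotations)."""
    return kg.generate_reference_session()


@pytest.fixture(scope="session")
def full_angles(full_session) -> dict[str, kg.AngleSeries]:
    return kg.compute_angle_series(full_session.recording)


@pytest.fixture(scope="session")
def null_vr(full_session) -> kg.KinematicRecording:
    """VR stream with no degradation beyond the 90 Hz re-timing."""
    return kg.degrade_to_vr(
        full_session, DegradationParams(noise_sd=0.0, timestamp_jitter=0.0)
    )


@pytest.fixture(scope="session")
def neutral_frame(full_session) -> kg.SkeletonFrame:
    """A frame from the initial neutral stance."""
    return full_session.recording.frame(10)


def canonical_pose(arm: str = "down") -> kg.SkeletonFrame:
    """An upright skeleton frame with the left arm posed down/forward/backward/up."""
    sess = kg.generate_reference_session(
        script=kg.MotionScript(initial_neutral=1.0, movements=[],
                               post_preamble_neutral=0.0, final_neutral=0.0),
    )
    frame = sess.recording.frame(0)
    positions = dict(frame.positions)
    sh = positions[kg.JointId.shoulder_left]
    upper = 0.186 * 1.75
    fore = 0.146 * 1.75
    direction = {
        "down": np.array([0.0, 0.0, -1.0]),
        "forward": np.array([1.0, 0.0, 0.0]),
        "backward": np.array([-1.0, 0.0, 0.0]),
        "up": np.array([0.0, 0.0, 1.0]),
    }[arm]
    positions = {j: p.copy() for j, p in positions.items()}
    positions[kg.JointId.elbow_left] = sh + upper * direction
    positions[kg.JointId.hand_left] = sh + (upper + fore) * direction
    return kg.SkeletonFrame(frame.t, positions, frame.orientations)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
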