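"""Skeleton topology and anthropometry.

The internal coordinate frame is right-handed with z up, x pointing to the
subject's anterior and y to the subject's left.  The rest pose of the model
is the neutral-zero stance (upright, arms hanging down, feet forward): every
joint orientation is the identity quaternion in that pose, and all bone
offsets below are expressed in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConfigError


class JointId(str, Enum):
    """The 20 joints of the unified skeleton (both streams use this model)."""

    hip_center = "hip_center"
    spine_mid = "spine_mid"
    chest = "chest"
    neck = "neck"
    head = "head"
    shoulder_center = "shoulder_center"
    shoulder_left = "shoulder_left"
    shoulder_right = "shoulder_right"
    elbow_left = "elbow_left"
    elbow_right = "elbow_right"
    hand_left = "hand_left"
    hand_right = "hand_right"
    hip_left = "hip_left"
    hip_right = "hip_right"
    knee_left = "knee_left"
    knee_right = "knee_right"
    ankle_left = "ankle_left"
    ankle_right = "ankle_right"
    foot_left = "foot_left"
    foot_right = "foot_right"


JOINT_ORDER: tuple[JointId, ...] = tuple(JointId)

#: parent map; hip_center is the root.
PARENT: dict[JointId, JointId | None] = {
    JointId.hip_center: None,
    JointId.spine_mid: JointId.hip_center,
    JointId.chest: JointId.spine_mid,
    JointId.shoulder_center: JointId.chest,
    JointId.neck: JointId.shoulder_center,
    JointId.head: JointId.neck,
    JointId.shoulder_left: JointId.shoulder_center,
    JointId.shoulder_right: JointId.shoulder_center,
    JointId.elbow_left: JointId.shoulder_left,
    JointId.elbow_right: JointId.shoulder_right,
    JointId.hand_left: JointId.elbow_left,
    JointId.hand_right: JointId.elbow_right,
    JointId.hip_left: JointId.hip_center,
    JointId.hip_right: JointId.hip_center,
    JointId.knee_left: JointId.hip_left,
    JointId.knee_right: JointId.hip_right,
    JointId.ankle_left: JointId.knee_left,
    JointId.ankle_right: JointId.knee_right,
    JointId.foot_left: JointId.ankle_left,
    JointId.foot_right: JointId.ankle_right,
}


def topological_order() -> list[JointId]:
    """Joints ordered so every parent precedes its children."""
    out: list[JointId] = []
    seen: set[JointId] = set()

    def visit(j: JointId) -> None:
        if j in seen:
            return
        p = PARENT[j]
        if p is not None and p not in seen:
            visit(p)
        seen.add(j)
        out.append(j)

    for j in JOINT_ORDER:
        visit(j)
    return out


def validate_topology() -> None:
    """Check that the parent map is a tree rooted at hip_center."""
    roots = [j for j, p in PARENT.items() if p is None]
    if roots != [JointId.hip_center]:
        raise ConfigError("parent map must have hip_center as its only root")
    for j in JOINT_ORDER:
        seen = set()
        cur: JointId | None = j
        while cur is not None:
            if cur in seen:
                raise ConfigError(f"cycle in parent map at {cur}")
            seen.add(cur)
            cur = PARENT[cur]
        if JointId.hip_center not in seen:
            raise ConfigError(f"{j} not reachable from root")


# Rest-pose unit direction of each bone (parent -> child), neutral stance.
_DOWN = np.array([0.0, 0.0, -1.0])
_UP = np.array([0.0, 0.0, 1.0])
_LEFT = np.array([0.0, 1.0, 0.0])
_RIGHT = np.array([0.0, -1.0, 0.0])
_FWD = np.array([1.0, 0.0, 0.0])

REST_DIRECTION: dict[JointId, np.ndarray] = {
    JointId.spine_mid: _UP,
    JointId.chest: _UP,
    JointId.shoulder_center: _UP,
    JointId.neck: _UP,
    JointId.head: _UP,
    JointId.shoulder_left: _LEFT,
    JointId.shoulder_right: _RIGHT,
    JointId.elbow_left: _DOWN,
    JointId.elbow_right: _DOWN,
    JointId.hand_left: _DOWN,
    JointId.hand_right: _DOWN,
    JointId.hip_left: _LEFT,
    JointId.hip_right: _RIGHT,
    JointId.knee_left: _DOWN,
    JointId.knee_right: _DOWN,
    JointId.ankle_left: _DOWN,
    JointId.ankle_right: _DOWN,
    JointId.foot_left: _FWD,
    JointId.foot_right: _FWD,
}

# Bone lengths as fractions of stature, loosely following standard
# anthropometric segment proportions.
_LENGTH_FRACTION: dict[JointId, float] = {
    JointId.spine_mid: 0.12,
    JointId.chest: 0.10,
    JointId.shoulder_center: 0.08,
    JointId.neck: 0.04,
    JointId.head: 0.07,
    JointId.shoulder_left: 0.115,
    JointId.shoulder_right: 0.115,
    JointId.elbow_left: 0.186,
    JointId.elbow_right: 0.186,
    JointId.hand_left: 0.146,
    JointId.hand_right: 0.146,
    JointId.hip_left: 0.055,
    JointId.hip_right: 0.055,
    JointId.knee_left: 0.245,
    JointId.knee_right: 0.245,
    JointId.ankle_left: 0.246,
    JointId.ankle_right: 0.246,
    JointId.foot_left: 0.10,
    JointId.foot_right: 0.10,
}


@dataclass
class Anthropometry:
    """Segment lengths (meters) for every parent->child bone, plus stature."""

    stature: float = 1.75
    lengths: dict[JointId, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1.4 <= self.stature <= 2.1):
            raise ConfigError(f"stature {self.stature} m outside [1.4, 2.1] m")
        defaults = {j: f * self.stature for j, f in _LENGTH_FRACTION.items()}
        defaults.update(self.lengths)
        self.lengths = defaults
        for j, length in self.lengths.items():
            if not length > 0:
                raise ConfigError(f"non-positive bone length for {j}")

    def rest_offset(self, joint: JointId) -> np.ndarray:
        """Rest-pose offset of `joint` relative to its parent (meters)."""
        return REST_DIRECTION[joint] * self.lengths[joint]


validate_topology()
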