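"""Synthetic paired sessions: scripted skeleton motion plus VR degradations.

The generator emulates the recording protocol used for validating a
VR-tracker skeleton stream against a marker-based reference: an initial
neutral stance, a T-pose synchronization preamble (three 90-deg
elbow-flexion pulses), and twenty scripted movements, each performed as
three cosine ramp-hold-return repetitions separated by neutral dwells.

The skeleton is posed by forward kinematics from per-joint rotation
"channels"; each measurable joint angle has a channel constructed so that
the angle recomputed from the generated frames equals the scripted
trajectory (within discretization), giving recovery tests an exact ground
truth.  The degradation model re-times the stream to the VR rate and
injects, with recorded ground truth: a start delay, recording
interruptions that compress the time vector (producing time shifts),
visible sample drop-outs, per-angle neutral offsets, a smooth
angle-dependent systematic distortion g(theta), band-limited additive
noise, tracker-jump artifacts and rigid-limb episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .core import (
    MOVEMENT_TABLE,
    PREAMBLE_ID,
    AngleSeries,
    KinematicRecording,
    SegmentAnnotation,
    quat_mul,
    quat_rotate,
)
from .errors import ConfigError
from .skeleton import Anthropometry, JointId, PARENT, topological_order

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}

# channel -> (joint, rotation axis, sign); per-joint application order is the
# order of appearance in this table.
CHANNEL_DEFS: dict[str, tuple[JointId, str, float]] = {
    "pelvis_flex": (JointId.hip_center, "y", 1.0),
    "back_torsion": (JointId.chest, "z", 1.0),
    "back_latinc": (JointId.chest, "x", -1.0),
    "chest_flex": (JointId.chest, "y", 1.0),
    "neck_torsion": (JointId.neck, "z", 1.0),
    "neck_latflex": (JointId.neck, "x", -1.0),
    "neck_flex": (JointId.neck, "y", 1.0),
    "head_latinc": (JointId.head, "x", -1.0),
    "head_inc": (JointId.head, "y", 1.0),
    "elbow_left_azim": (JointId.shoulder_left, "z", 1.0),
    "elbow_right_azim": (JointId.shoulder_right, "z", -1.0),
    "tpose_abduction_left": (JointId.shoulder_left, "x", 1.0),
    "tpose_abduction_right": (JointId.shoulder_right, "x", -1.0),
    # down-pointing bones rotate anterior under Ry(-theta)
    "shoulder_left_elev": (JointId.shoulder_left, "y", -1.0),
    "shoulder_right_elev": (JointId.shoulder_right, "y", -1.0),
    "elbow_left_flex": (JointId.elbow_left, "y", -1.0),
    "elbow_right_flex": (JointId.elbow_right, "y", -1.0),
    "hip_left_flex": (JointId.hip_left, "y", -1.0),
    "hip_right_flex": (JointId.hip_right, "y", -1.0),
    "knee_left_flex": (JointId.knee_left, "y", 1.0),
    "knee_right_flex": (JointId.knee_right, "y", 1.0),
}

# plausible anatomical amplitude limits per channel (degrees)
_CHANNEL_RANGE: dict[str, tuple[float, float]] = {
    "pelvis_flex": (-30.0, 100.0),
    "back_torsion": (-90.0, 90.0),
    "back_latinc": (-60.0, 60.0),
    "chest_flex": (-30.0, 60.0),
    "neck_torsion": (-90.0, 90.0),
    "neck_latflex": (-60.0, 60.0),
    "neck_flex": (-60.0, 70.0),
    "head_latinc": (-60.0, 60.0),
    "head_inc": (-60.0, 70.0),
    "elbow_left_azim": (-100.0, 100.0),
    "elbow_right_azim": (-100.0, 100.0),
    "tpose_abduction_left": (0.0, 95.0),
    "tpose_abduction_right": (0.0, 95.0),
    "shoulder_left_elev": (-60.0, 175.0),
    "shoulder_right_elev": (-60.0, 175.0),
    "elbow_left_flex": (0.0, 150.0),
    "elbow_right_flex": (0.0, 150.0),
    "hip_left_flex": (-30.0, 120.0),
    "hip_right_flex": (-30.0, 120.0),
    "knee_left_flex": (0.0, 150.0),
    "knee_right_flex": (0.0, 150.0),
}


@dataclass
class PulseSpec:
    """The T-pose synchronization preamble: repeated elbow-flexion pulses."""

    amplitude: float = 90.0
    reps: int = 3
    ramp: float = 1.0
    hold: float = 0.4
    gap: float = 0.3
    abduction: float = 85.0  # deg, arms held near-horizontal (T-posture)


@dataclass
class MovementSpec:
    """One scripted movement: channels driven with ramp-hold-return reps.

    ``sustained`` channels are held at their amplitude across the whole
    segment instead of pulsing per repetition (e.g. the supporting shoulder
    elevation during elbow curls, which keeps the arm azimuth well-defined
    throughout the movement).
    """

    movement_id: str
    channels: dict[str, float]  # channel -> amplitude (deg)
    ramp: float = 1.0
    hold: float = 0.5
    ret: float = 1.0
    reps: int = 3
    rep_gap: float = 0.25
    dwell_before: float = 1.5  # neutral stance before the movement
    sustained: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.movement_id not in MOVEMENT_TABLE:
            raise ConfigError(f"unknown movement id {self.movement_id!r}")
        for ch, amp in self.channels.items():
            if ch not in CHANNEL_DEFS:
                raise ConfigError(f"unknown channel {ch!r}")
            lo, hi = _CHANNEL_RANGE[ch]
            if not (lo <= amp <= hi):
                raise ConfigError(
                    f"movement {self.movement_id}: amplitude {amp} deg for "
                    f"{ch} outside anatomical range [{lo}, {hi}]"
                )
        for ch in self.sustained:
            if ch not in self.channels:
                raise ConfigError(f"sustained channel {ch!r} not driven")


@dataclass
class MotionScript:
    initial_neutral: float = 5.0
    preamble: PulseSpec = field(default_factory=PulseSpec)
    post_preamble_neutral: float = 2.0
    movements: list[MovementSpec] = field(default_factory=list)
    final_neutral: float = 2.0


def _mv(movement_id: str, channels: dict[str, float], **kw) -> MovementSpec:
    # "normal speed": larger ranges of motion take proportionally longer
    biggest = max(abs(a) for a in channels.values())
    ramp = max(1.0, biggest / 100.0)
    return MovementSpec(movement_id, channels, ramp=ramp, ret=ramp, **kw)


def default_script(link_squat_knees: bool = False) -> MotionScript:
    """The full twenty-movement protocol with plausible range-of-motion
    amplitudes (head inclination 40 deg, lateral 30 deg, shoulder elevation
    up to 170 deg, elbow flexion 140 deg, knee flexion 120 deg)."""
    del link_squat_knees  # linkage is decided at annotation time
    mv = [
        _mv("01", {"neck_flex": 40.0, "head_inc": 40.0}),
        _mv("02", {"neck_latflex": 30.0, "head_latinc": 30.0}),
        _mv("03", {"neck_torsion": 60.0}),
        _mv("04", {"pelvis_flex": 45.0}),
        _mv("05", {"pelvis_flex": 30.0, "chest_flex": 25.0}),
        _mv("06", {"back_latinc": 25.0}),
        _mv("07", {"back_torsion": 60.0}),
        _mv("08", {"shoulder_left_elev": 90.0}),
        _mv("09", {"shoulder_right_elev": 90.0}),
        _mv("10", {"shoulder_left_elev": 120.0, "shoulder_right_elev": 120.0}),
        _mv("11", {"shoulder_left_elev": 170.0}),
        _mv("12", {"shoulder_right_elev": 170.0}),
        _mv("13", {"shoulder_left_elev": 150.0, "shoulder_right_elev": 150.0}),
        _mv("14", {"tpose_abduction_left": 85.0, "tpose_abduction_right": 85.0}),
        _mv(
            "15",
            {
                "shoulder_left_elev": 60.0,
                "shoulder_right_elev": 60.0,
                "elbow_left_azim": 45.0,
                "elbow_right_azim": 45.0,
                "elbow_left_flex": 140.0,
                "elbow_right_flex": 140.0,
            },
            sustained=("shoulder_left_elev", "shoulder_right_elev"),
        ),
        _mv("16", {"knee_left_flex": 120.0}),
        _mv("17", {"knee_right_flex": 120.0}),
        _mv(
            "18",
            {
                "knee_left_flex": 90.0,
                "knee_right_flex": 90.0,
                "hip_left_flex": 45.0,
                "hip_right_flex": 45.0,
            },
        ),
        _mv("19", {"hip_right_flex": 60.0, "knee_left_flex": 90.0}),
        _mv("20", {"hip_left_flex": 60.0, "knee_right_flex": 90.0}),
    ]
    return MotionScript(movements=mv)


# ---------------------------------------------------------------------------
# trajectory construction


def _ease(s: np.ndarray) -> np.ndarray:
    """Cosine ease 0 -> 1 for normalized ramp position s in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(s, 0.0, 1.0)))


def _fill_rep(
    values: np.ndarray,
    times: np.ndarray,
    t0: float,
    amplitude: float,
    ramp: float,
    hold: float,
    ret: float,
) -> float:
    """Write one ramp-hold-return pulse starting at t0; returns its end time."""
    t1, t2, t3 = t0 + ramp, t0 + ramp + hold, t0 + ramp + hold + ret
    m = (times >= t0) & (times < t1)
    values[m] = np.maximum(values[m], amplitude * _ease((times[m] - t0) / ramp))
    m = (times >= t1) & (times < t2)
    values[m] = amplitude
    m = (times >= t2) & (times < t3)
    values[m] = np.maximum(values[m], amplitude * _ease((t3 - times[m]) / ret))
    return t3


@dataclass
class GroundTruth:
    """Everything injected by the generator, for recovery tests."""

    times: np.ndarray
    channels: dict[str, np.ndarray]
    preamble_window: tuple[float, float]
    anthropometry: Anthropometry
    script: MotionScript
    degradation: "DegradationParams | None" = None

    def channel_series(self, name: str) -> AngleSeries:
        return AngleSeries(name, self.times, self.channels[name])


@dataclass
class Session:
    """A generated session: recording + annotations + ground truth."""

    recording: KinematicRecording
    annotations: list[SegmentAnnotation]
    truth: GroundTruth


def _build_trajectories(
    script: MotionScript, rate: float
) -> tuple[np.ndarray, dict[str, np.ndarray], list[SegmentAnnotation], tuple[float, float]]:
    # first pass: lay out the timeline
    events: list[tuple[str, float, float, MovementSpec | None]] = []
    t = script.initial_neutral
    pre = script.preamble
    pre_start = t
    pre_dur = pre.ramp  # abduction up
    pulses_start = t + pre_dur
    pulse_dur = pre.reps * (pre.ramp + pre.hold + pre.ramp) + (pre.reps - 1) * pre.gap
    pre_end = pulses_start + pulse_dur + pre.ramp  # abduction down
    t = pre_end + script.post_preamble_neutral
    seg_windows: list[tuple[MovementSpec, float, float]] = []
    for m in script.movements:
        t += m.dwell_before
        start = t
        dur = m.reps * (m.ramp + m.hold + m.ret) + (m.reps - 1) * m.rep_gap
        if m.sustained:
            # sustained channels settle before the repetitions start
            dur += 2.0 * m.ramp
        t = start + dur
        seg_windows.append((m, start, t))
    total = t + script.final_neutral
    n = int(np.floor(total * rate)) + 1
    times = np.arange(n) / rate

    channels = {ch: np.zeros(n) for ch in CHANNEL_DEFS}

    # preamble: abduct arms to the T-posture, pulse the elbows, lower arms
    for side in ("left", "right"):
        abd = channels[f"tpose_abduction_{side}"]
        hold_dur = pulse_dur
        _fill_rep(abd, times, pre_start, pre.abduction, pre.ramp, hold_dur, pre.ramp)
        flex = channels[f"elbow_{side}_flex"]
        t0 = pulses_start
        for _ in range(pre.reps):
            t0 = _fill_rep(flex, times, t0, pre.amplitude, pre.ramp, pre.hold, pre.ramp)
            t0 += pre.gap

    # movements
    annotations: list[SegmentAnnotation] = [
        SegmentAnnotation(PREAMBLE_ID, pre_start, pre_end, ())
    ]
    for m, start, end in seg_windows:
        rep_start = start + (m.ramp if m.sustained else 0.0)
        for ch, amp in m.channels.items():
            if ch in m.sustained:
                hold = (end - start) - m.ramp - m.ret
                _fill_rep(channels[ch], times, start, amp, m.ramp, hold, m.ret)
                continue
            t0 = rep_start
            for _ in range(m.reps):
                t0 = _fill_rep(channels[ch], times, t0, amp, m.ramp, m.hold, m.ret)
                t0 += m.rep_gap
        annotations.append(
            SegmentAnnotation(m.movement_id, start, end, MOVEMENT_TABLE[m.movement_id])
        )
    return times, channels, annotations, (pre_start, pre_end)


# ---------------------------------------------------------------------------
# forward kinematics


def _axis_quat(axis: str, angles_deg: np.ndarray, sign: float) -> np.ndarray:
    half = np.radians(angles_deg * sign) / 2.0
    q = np.zeros(angles_deg.shape + (4,))
    q[..., 0] = np.cos(half)
    ax = _AXES[axis]
    s = np.sin(half)
    q[..., 1] = s * ax[0]
    q[..., 2] = s * ax[1]
    q[..., 3] = s * ax[2]
    return q


def pose_skeleton(
    channels: dict[str, np.ndarray],
    anthropometry: Anthropometry,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics: (positions (N,20,3), quaternions (N,20,4)).

    Each joint's local rotation composes its channels in registry order;
    world orientation and position follow the kinematic chain from the hip
    upward/downward; bone lengths are conserved exactly.
    """
    order = topological_order()
    joints = list(JointId)
    idx = {j: k for k, j in enumerate(joints)}
    identity = np.zeros((n, 4))
    identity[:, 0] = 1.0

    local = {j: identity.copy() for j in joints}
    for ch, (joint, axis, sign) in CHANNEL_DEFS.items():
        vals = channels.get(ch)
        if vals is None or not np.any(vals):
            continue
        local[joint] = quat_mul(local[joint], _axis_quat(axis, vals, sign))

    positions = np.zeros((n, len(joints), 3))
    quats = np.zeros((n, len(joints), 4))
    hip_height = 0.53 * anthropometry.stature
    for j in order:
        k = idx[j]
        p = PARENT[j]
        if p is None:
            positions[:, k] = np.array([0.0, 0.0, hip_height])
            quats[:, k] = local[j]
        else:
            kp = idx[p]
            offset = anthropometry.rest_offset(j)
            positions[:, k] = positions[:, kp] + quat_rotate(quats[:, kp], offset)
            quats[:, k] = quat_mul(quats[:, kp], local[j])
    return positions, quats


def generate_reference_session(
    script: MotionScript | None = None,
    anthropometry: Anthropometry | None = None,
    rate: float = 100.0,
) -> Session:
    """Generate the reference-system stream for a scripted session."""
    if rate < 50.0:
        raise ConfigError("reference rate must be at least 50 Hz")
    script = script or default_script()
    anthropometry = anthropometry or Anthropometry()
    times, channels, annotations, pre_win = _build_trajectories(script, rate)
    positions, quats = pose_skeleton(channels, anthropometry, len(times))
    rec = KinematicRecording(
        system="reference",
        nominal_rate=rate,
        times=times,
        positions=positions,
        quaternions=quats,
    )
    truth = GroundTruth(
        times=times,
        channels=channels,
        preamble_window=pre_win,
        anthropometry=anthropometry,
        script=script,
    )
    return Session(recording=rec, annotations=annotations, truth=truth)


# ---------------------------------------------------------------------------
# degradation


@dataclass
class DegradationParams:
    """Injected VR-stream degradations (all retrievable as ground truth)."""

    vr_rate: float = 90.0
    tracker_config: int = 9
    start_delay: float = 0.0  # s, content lag of the VR stream
    timestamp_jitter: float = 0.0005  # s, SD of sample-clock irregularity
    interruptions: list[tuple[float, float]] = field(default_factory=list)
    dropouts: list[tuple[float, float]] = field(default_factory=list)
    noise_sd: float = 1.0  # deg, band-limited additive angle noise
    noise_cutoff: float = 6.0  # Hz, noise shaping low-pass
    neutral_offsets: dict[str, float] = field(default_factory=dict)
    distortion: dict[str, list[float]] = field(default_factory=dict)  # monomial coeffs
    jump_artifacts: list[tuple[float, float, tuple[str, ...]]] = field(default_factory=list)
    rigid_limb: list[tuple[float, float, str]] = field(default_factory=list)
    isolated_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t, s in list(self.interruptions) + list(self.dropouts):
            if s <= 0:
                raise ConfigError(f"non-positive span {s} at t={t}")
        for t, s, _ in list(self.jump_artifacts) + [
            (a, b, None) for a, b, _c in self.rigid_limb
        ]:
            if s <= 0:
                raise ConfigError(f"non-positive span {s} at t={t}")


def eval_distortion(coeffs: list[float], theta: np.ndarray) -> np.ndarray:
    """Evaluate a monomial distortion g(theta) (ascending coefficients)."""
    return np.polynomial.polynomial.polyval(np.asarray(theta, float), np.asarray(coeffs))


def make_smooth_distortion(
    rng: np.random.Generator, angle_names: list[str], scale: float = 1.0
) -> dict[str, list[float]]:
    """Random smooth per-angle distortions with g(0) = 0.

    Cubic in theta with coefficients sized so |g| stays within roughly
    5-8 deg over a +-150 deg range, emulating the consistent over- and
    underestimation produced by a differing inverse-kinematics solver.
    """
    out = {}
    for name in angle_names:
        # the linear term carries a guaranteed minimum slope: the modeled
        # phenomenon is a consistent over- or underestimation, not noise
        c1 = rng.choice([-1.0, 1.0]) * rng.uniform(0.02, 0.06) * scale
        c2 = rng.uniform(-2e-4, 2e-4) * scale
        c3 = rng.uniform(-1.5e-6, 1.5e-6) * scale
        out[name] = [0.0, float(c1), float(c2), float(c3)]
    return out


def _shaped_noise(rng: np.random.Generator, n: int, rate: float, sd: float, cutoff: float) -> np.ndarray:
    white = rng.normal(0.0, 1.0, n)
    if cutoff < rate / 2.0:
        sos = _signal.butter(2, cutoff, btype="low", fs=rate, output="sos")
        white = _signal.sosfiltfilt(sos, white)
    s = np.std(white)
    return white * (sd / s) if s > 0 else white


def degrade_to_vr(session: Session, params: DegradationParams) -> KinematicRecording:
    """Produce the degraded VR-system stream for a generated session.

    The scripted channels are resampled to the VR rate (with the configured
    start delay and clock jitter), distorted per angle as
    ``theta' = theta + g(theta) + offset + noise``, optionally frozen during
    rigid-limb episodes, and re-posed by forward kinematics.  Interruptions
    delete the affected frames and compress subsequent timestamps (the
    cumulative shift equals the deleted span); drop-outs delete frames but
    leave the clock intact (a visible gap).  Deterministic under ``seed``.
    """
    truth = session.truth
    t_ref = truth.times
    span = t_ref[-1]
    for t0, s in list(params.interruptions) + list(params.dropouts):
        if not (0.0 <= t0 and t0 + s <= span):
            raise ConfigError(f"interruption ({t0}, {s}) outside recording span")
    rng = np.random.default_rng(params.seed)

    n = int(np.floor(span * params.vr_rate)) + 1
    t_vr = np.arange(n) / params.vr_rate
    if params.timestamp_jitter > 0:
        jit = rng.normal(0.0, params.timestamp_jitter, n)
        t_vr = np.sort(t_vr + jit)
        t_vr[0] = max(t_vr[0], 0.0)

    sample_at = np.clip(t_vr - params.start_delay, 0.0, span)
    channels: dict[str, np.ndarray] = {}
    for ch, vals in truth.channels.items():
        v = np.interp(sample_at, t_ref, vals)
        coeffs = params.distortion.get(ch)
        if coeffs is not None:
            v = v + eval_distortion(coeffs, v)
        off = params.neutral_offsets.get(ch, 0.0)
        if off:
            v = v + off
        if params.noise_sd > 0:
            v = v + _shaped_noise(rng, n, params.vr_rate, params.noise_sd, params.noise_cutoff)
        channels[ch] = v
    for t0, s, ch in params.rigid_limb:
        if ch not in channels:
            raise ConfigError(f"rigid-limb episode names unknown channel {ch!r}")
        m = (t_vr >= t0) & (t_vr <= t0 + s)
        if m.any():
            channels[ch][m] = channels[ch][np.argmax(m)]

    positions, quats = pose_skeleton(channels, truth.anthropometry, n)

    joint_index = {j: k for k, j in enumerate(JointId)}
    for t0, s, joints in params.jump_artifacts:
        m = (t_vr >= t0) & (t_vr <= t0 + s)
        if not m.any():
            continue
        for jname in joints:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            positions[m, joint_index[JointId(jname)], :] += 0.6 * direction

    keep = np.ones(n, dtype=bool)
    if params.isolated_dropout_rate > 0:
        iso = rng.random(n) < params.isolated_dropout_rate
        iso[:1] = iso[-1:] = False
        positions[iso] = np.nan

    t_out = t_vr.copy()
    for t0, s in sorted(params.dropouts):
        keep &= ~((t_out > t0) & (t_out < t0 + s))
    for t0, s in sorted(params.interruptions):
        # half-open span: a frame exactly at t0+s is deleted, so the
        # compressed clock cannot collide with the frame kept at t0
        inside = (t_out > t0) & (t_out <= t0 + s)
        keep &= ~inside
        t_out = np.where(t_out > t0 + s, t_out - s, t_out)

    rec = KinematicRecording(
        system="vr",
        nominal_rate=params.vr_rate,
        times=t_out[keep],
        positions=positions[keep],
        quaternions=quats[keep],
        tracker_config=params.tracker_config,
    )
    truth.degradation = params
    return rec


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SubjectSession:
    subject_id: str
    session: Session
    vr_recording: KinematicRecording
    params: DegradationParams


@dataclass
class Cohort:
    subjects: list[SubjectSession]
    shared_distortion: dict[str, list[float]]
    ledger: dict


def generate_cohort(
    n_subjects: int,
    script: MotionScript | None = None,
    params_template: DegradationParams | None = None,
    seed: int = 0,
    distortion_scale: float = 1.0,
    rate: float = 100.0,
) -> Cohort:
    """Generate a cohort of paired sessions with a shared distortion.

    Per-subject anthropometry (stature 1.55-1.95 m) and neutral offsets are
    drawn independently, while the systematic distortion g(theta) is shared
    across subjects, as a solver-induced error would be.  Every injected
    parameter is recorded in the returned ledger.
    """
    if n_subjects < 1:
        raise ConfigError("need at least one subject")
    script = script or default_script()
    rng = np.random.default_rng(seed)
    measured = [ch for ch in CHANNEL_DEFS if not ch.startswith(("tpose", "back", "neck_tors"))]
    shared = make_smooth_distortion(rng, measured, scale=distortion_scale)
    template = params_template or DegradationParams()

    subjects: list[SubjectSession] = []
    ledger: dict = {"seed": seed, "shared_distortion": shared, "subjects": {}}
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        stature = float(rng.uniform(1.55, 1.95))
        offsets = {ch: float(rng.normal(0.0, 2.0)) for ch in measured}
        for ch in measured:
            if _CHANNEL_RANGE[ch][0] == 0.0:
                # flexions are folded non-negative measurements: a neutral
                # posture cannot sit below the anatomical zero
                offsets[ch] = abs(offsets[ch])
            if ch.endswith("azim"):
                # the azimuth of a hanging arm is undefined, so a neutral
                # offset is neither observable nor correctable
                offsets[ch] = 0.0
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = replace(
            template,
            distortion=dict(shared),
            neutral_offsets=offsets,
            seed=sub_seed,
        )
        sess = generate_reference_session(
            script=script, anthropometry=Anthropometry(stature=stature), rate=rate
        )
        vr = degrade_to_vr(sess, params)
        subjects.append(SubjectSession(sid, sess, vr, params))
        ledger["subjects"][sid] = {
            "stature": stature,
            "neutral_offsets": offsets,
            "seed": sub_seed,
            "interruptions": list(params.interruptions),
            "noise_sd": params.noise_sd,
        }
    return Cohort(subjects=subjects, shared_distortion=shared, ledger=ledger)
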