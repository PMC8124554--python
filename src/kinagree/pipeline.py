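"""End-to-end comparison pipeline.

The processing order is fixed and enforced:

1. shift of the origin to the hip center (re-referencing),
2. derivation of the 16 joint angles,
3. resampling to the reference rate, low-pass filtering, interpolation,
4. neutral-zero offset correction,
5. global time-offset from the T-pose preamble,
6. segmentation (annotations),
7. per-segment resynchronization (DTW coarse + FFT fine),
8. systematic polynomial correction,

followed by the per-angle agreement statistics.  Stages 1, 4 (both
re-referencing) and 5, 7 (synchronization) exist only for comparing the two
streams and can be skipped in a production setting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .angles import compute_angle_series, default_definitions
from .core import (
    ANGLE_NAMES,
    PREAMBLE_ID,
    AngleSeries,
    KinematicRecording,
    SegmentAnnotation,
    concatenate_segments,
    select_linked_segments,
)
from .correct import CorrectionFunction, apply_correction, fit_correction
from .errors import StageOrderError
from .preprocess import (
    PreprocessConfig,
    interpolate_isolated,
    lowpass,
    neutral_zero_offset,
    regularize,
    resample_to_rate,
    shift_origin_to_hip,
)
from .stats import AngleAgreement, agreement_for_angle
from .sync import SyncConfig, SyncResult, resync_segments, tpose_initial_offset

STAGES = (
    "origin_shift",
    "angles",
    "resample_filter",
    "offset",
    "tpose_sync",
    "segmentation",
    "resync",
    "systematic_correction",
)


class StageTracker:
    """Refuses out-of-order application of the pipeline stages."""

    def __init__(self) -> None:
        self._done: list[str] = []

    def enter(self, stage: str) -> None:
        idx = STAGES.index(stage)
        done_idx = [STAGES.index(s) for s in self._done]
        if done_idx and idx <= max(done_idx):
            raise StageOrderError(
                f"stage {stage!r} applied after {self._done[-1]!r}"
            )
        if any(i > idx for i in done_idx):
            raise StageOrderError(f"stage {stage!r} applied out of order")
        self._done.append(stage)

    @property
    def completed(self) -> tuple[str, ...]:
        return tuple(self._done)


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sync: SyncConfig = field(default_factory=SyncConfig)
    correction_degree: int = 12
    correction_mode: str = "pooled"  # pooled | held_out
    n_points: int = 2500
    seed: int = 0
    production: bool = False  # skip re-referencing and sync stages
    min_fit_samples_factor: int = 10

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "preprocess": vars(self.preprocess),
                "sync": vars(self.sync),
                "correction_degree": self.correction_degree,
                "correction_mode": self.correction_mode,
                "n_points": self.n_points,
                "seed": self.seed,
                "production": self.production,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PreparedPair:
    """Both streams after stages 1-7: aligned per-angle series on the
    reference grid, plus bookkeeping."""

    ref_angles: dict[str, AngleSeries]
    vr_angles: dict[str, AngleSeries]  # aligned to the reference grid
    annotations: list[SegmentAnnotation]
    offsets_ref: dict[str, float]
    offsets_vr: dict[str, float]
    tpose_shift: float
    sync_results: list[SyncResult]
    stages: tuple[str, ...]


def prepare_pair(
    ref_rec: KinematicRecording,
    vr_rec: KinematicRecording,
    annotations: list[SegmentAnnotation],
    config: RunConfig | None = None,
) -> PreparedPair:
    """Run stages 1-7 on one paired session."""
    cfg = config or RunConfig()
    pp = cfg.preprocess
    tracker = StageTracker()

    tracker.enter("origin_shift")
    if not cfg.production:
        ref_rec = shift_origin_to_hip(ref_rec)
        vr_rec = shift_origin_to_hip(vr_rec)

    tracker.enter("angles")
    defs = default_definitions()
    ref_angles = compute_angle_series(ref_rec, defs)
    vr_angles = compute_angle_series(vr_rec, defs)

    tracker.enter("resample_filter")
    from .preprocess import unwrap_degrees, wrap_degrees

    for name in list(ref_angles):
        # azimuths can cross +-180; unwrap before interpolation/filtering
        wraps = name.endswith("azim")
        r = ref_angles[name]
        v = vr_angles[name]
        if wraps:
            r, v = unwrap_degrees(r), unwrap_degrees(v)
        r = lowpass(r, pp.lowpass_cutoff, pp.lowpass_order)
        r = interpolate_isolated(r, pp.max_isolated_gap)
        v = regularize(v, vr_rec.nominal_rate)
        v = resample_to_rate(v, pp.target_rate)
        v = lowpass(v, pp.lowpass_cutoff, pp.lowpass_order)
        v = interpolate_isolated(v, pp.max_isolated_gap)
        if wraps:
            r, v = wrap_degrees(r), wrap_degrees(v)
        ref_angles[name] = r
        vr_angles[name] = v

    tracker.enter("offset")
    offsets_ref: dict[str, float] = {}
    offsets_vr: dict[str, float] = {}
    if not cfg.production:
        from .errors import LengthError

        for name in list(ref_angles):
            # angles undefined in the neutral stance (e.g. the azimuth of a
            # hanging arm) carry no neutral offset
            try:
                ref_angles[name], offsets_ref[name] = neutral_zero_offset(
                    ref_angles[name], pp.neutral_window
                )
            except LengthError:
                offsets_ref[name] = 0.0
            try:
                vr_angles[name], offsets_vr[name] = neutral_zero_offset(
                    vr_angles[name], pp.neutral_window
                )
            except LengthError:
                offsets_vr[name] = 0.0

    tracker.enter("tpose_sync")
    tpose_shift = 0.0
    if not cfg.production:
        pre = next((a for a in annotations if a.movement_id == PREAMBLE_ID), None)
        if pre is not None:
            sync_angle = cfg.sync.fallback_angle
            ref_pre = ref_angles[sync_angle].window(pre.t_start - 1.0, pre.t_end + 1.0)
            vr_pre = vr_angles[sync_angle].window(
                pre.t_start - 1.0 - 2.0, pre.t_end + 1.0 + 2.0
            )
            lag = tpose_initial_offset(ref_pre, vr_pre, cfg.sync)
            tpose_shift = -lag

    tracker.enter("segmentation")
    movement_annotations = [a for a in annotations if a.movement_id != PREAMBLE_ID]

    tracker.enter("resync")
    if cfg.production:
        aligned = {}
        for name, r in ref_angles.items():
            v = vr_angles[name]
            vals = np.interp(r.times, v.times, np.where(v.valid, v.values, np.nan))
            aligned[name] = AngleSeries(name, r.times.copy(), vals)
        sync_results: list[SyncResult] = []
    else:
        aligned, sync_results = resync_segments(
            ref_angles,
            vr_angles,
            movement_annotations,
            cfg.sync,
            initial_shift=tpose_shift,
        )

    return PreparedPair(
        ref_angles=ref_angles,
        vr_angles=aligned,
        annotations=movement_annotations,
        offsets_ref=offsets_ref,
        offsets_vr=offsets_vr,
        tpose_shift=tpose_shift,
        sync_results=sync_results,
        stages=tracker.completed,
    )


def _linked_concat(
    pair: PreparedPair, angle: str
) -> tuple[AngleSeries, AngleSeries]:
    windows = select_linked_segments(pair.annotations, angle)
    return (
        concatenate_segments(pair.ref_angles[angle], windows),
        concatenate_segments(pair.vr_angles[angle], windows),
    )


@dataclass
class ComparisonResult:
    agreements: dict[str, AngleAgreement]
    corrections: dict[str, CorrectionFunction]
    pairs: list[PreparedPair]
    config_hash: str
    seed: int


def fit_corrections(
    pairs: list[PreparedPair], config: RunConfig
) -> dict[str, CorrectionFunction]:
    """Fit per-angle corrections on the pooled linked segments of all pairs."""
    out: dict[str, CorrectionFunction] = {}
    for angle in ANGLE_NAMES:
        refs, vrs = [], []
        for p in pairs:
            r, v = _linked_concat(p, angle)
            refs.append(r)
            vrs.append(v)
        ref_all = _stack(refs)
        vr_all = _stack(vrs)
        need = config.min_fit_samples_factor * (config.correction_degree + 1)
        valid_n = int((ref_all.valid & vr_all.valid).sum())
        if valid_n < need:
            continue  # too little linked data; leave this angle uncorrected
        out[angle] = fit_correction(vr_all, ref_all, config.correction_degree)
    return out


def _stack(series: list[AngleSeries]) -> AngleSeries:
    """Concatenate series from different subjects on a running time base."""
    ts, vs, ms = [], [], []
    t_offset = 0.0
    name = series[0].name
    for s in series:
        if len(s) == 0:
            continue
        t = s.times - s.times[0] + t_offset
        ts.append(t)
        vs.append(s.values)
        ms.append(s.valid)
        t_offset = t[-1] + 1.0
    if not ts:
        return AngleSeries(name, np.empty(0), np.empty(0), np.empty(0, bool))
    return AngleSeries(name, np.concatenate(ts), np.concatenate(vs), np.concatenate(ms))


def run_comparison(
    sessions: list[tuple[KinematicRecording, KinematicRecording, list[SegmentAnnotation]]],
    config: RunConfig | None = None,
) -> ComparisonResult:
    """Full pipeline + statistics over one or more paired sessions.

    ``correction_mode='pooled'`` fits each angle's correction on all
    subjects and applies it to every subject (the default protocol);
    ``'held_out'`` fits on the other subjects before applying, which keeps
    the evaluated subject out of its own correction.
    """
    cfg = config or RunConfig()
    pairs = [prepare_pair(r, v, a, cfg) for r, v, a in sessions]

    corrected: dict[str, list[tuple[AngleSeries, AngleSeries]]] = {a: [] for a in ANGLE_NAMES}
    corrections = fit_corrections(pairs, cfg)
    for i, p in enumerate(pairs):
        if cfg.correction_mode == "held_out" and len(pairs) > 1:
            others = [q for j, q in enumerate(pairs) if j != i]
            fns = fit_corrections(others, cfg)
        else:
            fns = corrections
        for angle in ANGLE_NAMES:
            r, v = _linked_concat(p, angle)
            if angle in fns and len(v):
                v = apply_correction(v, fns[angle])
            corrected[angle].append((r, v))

    agreements: dict[str, AngleAgreement] = {}
    for angle in ANGLE_NAMES:
        ref_all = _stack([r for r, _ in corrected[angle]])
        vr_all = _stack([v for _, v in corrected[angle]])
        if len(ref_all) == 0:
            continue
        agreements[angle] = agreement_for_angle(
            ref_all, vr_all, n_points=cfg.n_points, seed=cfg.seed
        )
    return ComparisonResult(
        agreements=agreements,
        corrections=corrections,
        pairs=pairs,
        config_hash=cfg.config_hash(),
        seed=cfg.seed,
    )


def report_rows(result: ComparisonResult, tracker_config: int | None = None) -> list[dict]:
    rows = []
    for angle, ag in result.agreements.items():
        rows.append(
            {
                "angle": angle,
                "tracker_config": tracker_config,
                "n": ag.n,
                "ipr_p5": ag.ipr[0],
                "ipr_p95": ag.ipr[1],
                "median_diff": ag.median_diff,
                "accuracy_class": ag.accuracy_class,
                "ccc": ag.ccc.ccc,
                "mcbride_band": ag.ccc.mcbride_band,
                "ba_mean": ag.bland_altman.mean,
                "ba_loa_low": ag.bland_altman.loa_low,
                "ba_loa_high": ag.bland_altman.loa_high,
                "ref_q25": ag.rom_ref.q25,
                "ref_q50": ag.rom_ref.q50,
                "ref_q75": ag.rom_ref.q75,
                "ref_mean": ag.rom_ref.mean,
                "ref_sd": ag.rom_ref.sd,
                "ref_min": ag.rom_ref.min,
                "ref_max": ag.rom_ref.max,
                "vr_q25": ag.rom_vr.q25,
                "vr_q50": ag.rom_vr.q50,
                "vr_q75": ag.rom_vr.q75,
                "vr_mean": ag.rom_vr.mean,
                "vr_sd": ag.rom_vr.sd,
                "vr_min": ag.rom_vr.min,
                "vr_max": ag.rom_vr.max,
                "config_hash": result.config_hash,
                "seed": result.seed,
            }
        )
    return rows
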