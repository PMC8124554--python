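"""Time-synchronization of the VR stream against the reference stream.

The VR stream suffers short recording interruptions: spans of samples are
missing and the time vector is compressed, so all content after a gap is
shifted.  Synchrony is reconstructed in three passes:

1. a global offset from the T-pose preamble (three 90-deg elbow-flexion
   pulses) via cross-correlation;
2. a coarse per-segment shift (0.5 s < |shift| < 2 s) from the dynamic time
   warping path: matched pairs on locally diagonal (one-to-one) stretches of
   the path have a locally constant index offset that measures clock offset,
   while staircase stretches encode speed differences and are excluded; the
   mean over diagonal pairs is the coarse shift;
3. a fine shift (< 0.5 s) from the frequency-domain cross-correlation peak
   with parabolic sub-sample refinement.

All offsets are reported as the *lag* of the VR content relative to the
reference (positive: VR later); the applied correction subtracts the lag
from the VR time vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import AngleSeries, SegmentAnnotation
from .errors import SyncError

FLAT_FLAG = "uninformative_segment"
LOWCONF_FLAG = "low_confidence"
OUT_OF_RANGE_FLAG = "coarse_out_of_range"
SHORT_FLAG = "segment_too_short"


@dataclass
class SyncConfig:
    coarse_min: float = 0.5  # s, smallest coarse shift considered real
    coarse_max: float = 2.0  # s, largest coarse shift considered real
    fine_max: float = 0.5  # s, fine-search half-window
    dtw_rate: float = 20.0  # Hz, decimated rate for the DTW pass
    dtw_band: float = 3.0  # s, Sakoe-Chiba band half-width
    min_diag_run: int = 5  # consecutive diagonal steps forming a usable run
    flat_sd: float = 0.5  # deg, below this a segment is uninformative
    margin: float = 2.5  # s, extra VR context around each segment
    min_peak_corr: float = 0.2  # normalized correlation for confidence
    cumulative: bool = True  # carry each segment's shift into the next
    fallback_angle: str = "elbow_left_flex"  # sync angle for unlinked segments
    pulse_amplitude: float = 90.0  # deg, preamble elbow pulses


@dataclass
class SyncResult:
    segment_id: str
    coarse_shift: float  # s, applied coarse correction (0 if not applied)
    fine_shift: float  # s, applied fine correction
    total_shift: float  # s, cumulative correction added to VR times
    flags: list[str] = field(default_factory=list)


def _clean(series: AngleSeries) -> tuple[np.ndarray, np.ndarray]:
    """(times, values) with invalid samples linearly filled."""
    t, v = series.times, series.values.copy()
    if not series.valid.all():
        if series.valid.sum() < 2:
            raise SyncError("segment has too few valid samples")
        v = np.interp(t, t[series.valid], v[series.valid])
    return t, v


def detect_gaps(
    times: np.ndarray, nominal_rate: float, factor: float = 1.5
) -> list[tuple[float, float]]:
    """Inter-frame gaps larger than ``factor`` nominal steps: (start, width)."""
    dt = np.diff(times)
    thr = factor / nominal_rate
    idx = np.nonzero(dt > thr)[0]
    return [(float(times[i]), float(dt[i])) for i in idx]


def tpose_initial_offset(
    ref_series: AngleSeries,
    vr_series: AngleSeries,
    config: SyncConfig | None = None,
) -> float:
    """Global VR lag (s) from the T-pose elbow-flexion preamble.

    Both series are expected to be restricted to (a window around) the
    preamble.  A preamble is accepted when at least three flexion pulses
    exceed half the configured pulse amplitude in each stream.
    """
    cfg = config or SyncConfig()
    half = cfg.pulse_amplitude / 2.0
    for s, label in ((ref_series, "reference"), (vr_series, "vr")):
        _, v = _clean(s)
        peaks, _ = signal.find_peaks(v, height=half, distance=5)
        if len(peaks) < 3:
            raise SyncError(
                f"no T-pose preamble in {label} stream "
                f"({len(peaks)} pulses above {half:.0f} deg)"
            )
    return _xcorr_lag(ref_series, vr_series, max_lag=None)[0]


def _xcorr_lag(
    ref: AngleSeries, vr: AngleSeries, max_lag: float | None
) -> tuple[float, float]:
    """(lag, normalized peak) via FFT cross-correlation, parabolic refined."""
    rt, rv = _clean(ref)
    vt, vv = _clean(vr)
    dt = float(np.median(np.diff(rt)))
    # put both on the reference's uniform grid spacing
    rg = np.arange(rt[0], rt[-1] + dt / 2, dt)
    vg = np.arange(vt[0], vt[-1] + dt / 2, dt)
    if len(rg) < 4 or len(vg) < 4:
        raise SyncError("segment too short for cross-correlation")
    rv = np.interp(rg, rt, rv) - np.mean(rv)
    vv = np.interp(vg, vt, vv) - np.mean(vv)
    c = signal.correlate(vv, rv, mode="full", method="fft")
    lags = signal.correlation_lags(len(vv), len(rv), mode="full") * dt
    lags = lags + (vg[0] - rg[0])
    denom = np.linalg.norm(rv) * np.linalg.norm(vv)
    if denom < 1e-12:
        return 0.0, 0.0
    c = c / denom
    if max_lag is not None:
        m = np.abs(lags) <= max_lag
        if not m.any():
            raise SyncError("no admissible lag in search window")
        c, lags = c[m], lags[m]
    k = int(np.argmax(c))
    lag = lags[k]
    if 0 < k < len(c) - 1:  # parabolic sub-sample refinement
        y0, y1, y2 = c[k - 1], c[k], c[k + 1]
        denom2 = y0 - 2 * y1 + y2
        if abs(denom2) > 1e-12:
            lag = lag + 0.5 * (y0 - y2) / denom2 * dt
    return float(lag), float(c[k])


def fft_fine_offset(
    ref_segment: AngleSeries,
    vr_segment: AngleSeries,
    config: SyncConfig | None = None,
) -> tuple[float, list[str]]:
    """Sub-sample VR lag within (-fine_max, fine_max) seconds."""
    cfg = config or SyncConfig()
    lag, peak = _xcorr_lag(ref_segment, vr_segment, max_lag=cfg.fine_max)
    flags = [] if peak >= cfg.min_peak_corr else [LOWCONF_FLAG]
    return lag, flags


def _dtw_path(x: np.ndarray, y: np.ndarray, band: int) -> list[tuple[int, int]]:
    """Warping path of two z-normalized sequences under a banded constraint.

    The band is slanted to cover the length difference of the two
    sequences, so both endpoints are always admissible.
    """
    n, m = len(x), len(y)
    lo = min(0, m - n) - band
    hi = max(0, m - n) + band
    big = np.inf
    D = np.full((n + 1, m + 1), big)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo = max(1, i + lo)
        j_hi = min(m, i + hi)
        xi = x[i - 1]
        row = D[i]
        prev = D[i - 1]
        for j in range(j_lo, j_hi + 1):
            cost = abs(xi - y[j - 1])
            row[j] = cost + min(prev[j], row[j - 1], prev[j - 1])
    # backtrack
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        steps = (D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
        k = int(np.argmin(steps))
        if k == 0:
            i, j = i - 1, j - 1
        elif k == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    return path


def dtw_coarse_offset(
    ref_segment: AngleSeries,
    vr_segment: AngleSeries,
    config: SyncConfig | None = None,
    core: tuple[float, float] | None = None,
) -> tuple[float, bool, list[str]]:
    """Coarse VR lag from DTW diagonal pairs.

    Returns (lag seconds, applied?, flags).  A lag outside
    [coarse_min, coarse_max] in magnitude is reported but flagged
    not-applied; flat segments (SD below ``flat_sd``) return 0 with a flag.

    When both inputs carry context beyond the movement itself, ``core``
    restricts the averaged pairs to the movement window; the surrounding
    context still takes part in the alignment, which disambiguates the
    period aliases of repeated-movement protocols.
    """
    cfg = config or SyncConfig()
    flags: list[str] = []
    rt, rv = _clean(ref_segment)
    vt, vv = _clean(vr_segment)
    if np.std(rv) < cfg.flat_sd or np.std(vv) < cfg.flat_sd:
        return 0.0, False, [FLAT_FLAG]
    dt = 1.0 / cfg.dtw_rate
    rg = np.arange(rt[0], rt[-1], dt)
    vg = np.arange(vt[0], vt[-1], dt)
    if len(rg) < 2 * cfg.min_diag_run or len(vg) < 2 * cfg.min_diag_run:
        return 0.0, False, [SHORT_FLAG]
    x = np.interp(rg, rt, rv)
    y = np.interp(vg, vt, vv)
    # shared normalization: both series carry the same angle in degrees (and
    # are neutral-zeroed upstream), so one common center and scale keeps the
    # matching amplitude-independent without introducing a vertical offset
    # between windows of different dwell fractions
    center = np.median(x)
    scale = max(float(np.percentile(np.abs(x - center), 95)), 1e-9)
    x = (x - center) / scale
    y = (y - center) / scale
    band = int(round(cfg.dtw_band / dt)) + 1

    # matched pairs constrain the clock only where the signal is changing;
    # flat stretches match arbitrarily and would bias the average
    slope = np.abs(np.gradient(x))
    informative = slope > max(0.1 * slope.max(), 1e-6)
    if core is not None:
        informative &= (rg >= core[0]) & (rg <= core[1])

    # the backtrack has a one-sample orientation bias; estimate on the
    # forward and the time-reversed pair and average the two
    estimates: list[float] = []
    for reverse in (False, True):
        if reverse:
            path = [
                (len(x) - 1 - i, len(y) - 1 - j)
                for i, j in _dtw_path(x[::-1], y[::-1], band)
            ]
        else:
            path = _dtw_path(x, y, band)
        offsets = _diagonal_offsets(path, rg, vg, informative, cfg.min_diag_run)
        if offsets:
            estimates.append(float(np.median(offsets)))
    if not estimates:
        return 0.0, False, [FLAT_FLAG]
    lag = float(np.mean(estimates))
    applied = cfg.coarse_min <= abs(lag) <= cfg.coarse_max
    if not applied and abs(lag) > cfg.coarse_max:
        flags.append(OUT_OF_RANGE_FLAG)
    return lag, applied, flags


def _sync_angle(
    ann: SegmentAnnotation, ref_series: dict[str, AngleSeries], cfg: SyncConfig
) -> str:
    """The segment's sync angle: the linked angle moving most within the
    segment (falls back to elbow flexion for unlinked segments)."""
    if not ann.linked_angles:
        return cfg.fallback_angle
    best, best_sd = ann.linked_angles[0], -1.0
    for a in ann.linked_angles:
        seg = ref_series[a].window(ann.t_start, ann.t_end)
        if seg.valid.sum() < 2:
            continue
        sd = float(np.std(seg.values[seg.valid]))
        if sd > best_sd:
            best, best_sd = a, sd
    return best


def _diagonal_offsets(
    path: list[tuple[int, int]],
    rg: np.ndarray,
    vg: np.ndarray,
    informative: np.ndarray,
    min_run: int,
) -> list[float]:
    """Time offsets of informative pairs on diagonal runs of a warping path."""
    path = sorted(path)
    offsets: list[float] = []
    run: list[tuple[int, int]] = [path[0]]

    def harvest(r: list[tuple[int, int]]) -> None:
        if len(r) >= min_run:
            offsets.extend(vg[j] - rg[i] for i, j in r if informative[i])

    for (i0, j0), (i1, j1) in zip(path, path[1:]):
        if i1 - i0 == 1 and j1 - j0 == 1:
            run.append((i1, j1))
        else:
            harvest(run)
            run = [(i1, j1)]
    harvest(run)
    return offsets


def _shifted(series: AngleSeries, shift: float) -> AngleSeries:
    return AngleSeries(
        series.name, series.times + shift, series.values, series.valid
    )


def resync_segments(
    ref_series: dict[str, AngleSeries],
    vr_series: dict[str, AngleSeries],
    annotations: list[SegmentAnnotation],
    config: SyncConfig | None = None,
    initial_shift: float = 0.0,
) -> tuple[dict[str, AngleSeries], list[SyncResult]]:
    """Per-segment resynchronization of the VR angle series.

    The VR stream is assumed globally pre-shifted by the T-pose offset
    (``initial_shift`` is the correction already in effect and is carried in
    the reported totals).  For each movement segment the coarse (DTW) and
    fine (FFT) shifts are estimated on the segment's sync angle — its first
    linked angle, or elbow flexion for unlinked segments — and applied
    cumulatively.  Inter-segment gaps inherit the nearest preceding shift.

    Returns the VR series re-interpolated onto the reference time grid
    (piecewise-constant shift per segment) and the per-segment results.
    """
    cfg = config or SyncConfig()
    anns = sorted(annotations, key=lambda a: a.t_start)
    shift = initial_shift
    results: list[SyncResult] = []
    seg_shift: list[tuple[float, float, float]] = []  # (t0, t1, shift)

    for ann in anns:
        angle = _sync_angle(ann, ref_series, cfg)
        flags: list[str] = []
        coarse_applied = 0.0
        fine_applied = 0.0
        ref_seg = ref_series[angle].window(ann.t_start, ann.t_end)
        if len(ref_seg) < 4:
            flags.append(SHORT_FLAG)
        else:
            # both windows carry neighbor context; the VR window additionally
            # covers the largest admissible coarse shift
            ref_ctx = ref_series[angle].window(
                ann.t_start - cfg.margin, ann.t_end + cfg.margin
            )
            vr_shift0 = _shifted(vr_series[angle], shift)
            vr_seg = vr_shift0.window(
                ann.t_start - cfg.margin - cfg.coarse_max,
                ann.t_end + cfg.margin + cfg.coarse_max,
            )
            if len(vr_seg) < 4 or vr_seg.valid.sum() < 2:
                flags.append(SHORT_FLAG)
            else:
                lag, applied, cflags = dtw_coarse_offset(
                    ref_ctx, vr_seg, cfg, core=(ann.t_start, ann.t_end)
                )
                flags.extend(cflags)
                if applied:
                    coarse_applied = -lag
                    shift += coarse_applied
                if FLAT_FLAG not in flags:
                    # the fine pass is iterated: each application can leave a
                    # residual when the true lag sits near the search edge
                    for _ in range(3):
                        vr_seg2 = _shifted(vr_series[angle], shift).window(
                            ann.t_start - cfg.fine_max - 0.2,
                            ann.t_end + cfg.fine_max + 0.2,
                        )
                        if len(vr_seg2) < 4:
                            break
                        lag_f, fflags = fft_fine_offset(ref_seg, vr_seg2, cfg)
                        for fl in fflags:
                            if fl not in flags:
                                flags.append(fl)
                        fine_applied += -lag_f
                        shift += -lag_f
                        if abs(lag_f) < 0.005:
                            break
        results.append(
            SyncResult(
                segment_id=ann.movement_id,
                coarse_shift=coarse_applied,
                fine_shift=fine_applied,
                total_shift=shift,
                flags=flags,
            )
        )
        seg_shift.append((ann.t_start, ann.t_end, shift))
        if not cfg.cumulative:
            shift = initial_shift

    aligned = {
        name: _interp_piecewise(ref_series[name], vr_series[name], seg_shift, initial_shift)
        for name in ref_series
        if name in vr_series
    }
    return aligned, results


def _interp_piecewise(
    ref: AngleSeries,
    vr: AngleSeries,
    seg_shift: list[tuple[float, float, float]],
    initial_shift: float,
) -> AngleSeries:
    """VR values on the reference grid under a piecewise-constant shift."""
    t = ref.times
    shifts = np.full(len(t), initial_shift)
    prev = initial_shift
    for t0, t1, s in seg_shift:
        shifts[(t >= t0) & (t <= t1)] = s
        shifts[t > t1] = s  # gaps inherit the nearest preceding shift
        prev = s
    vt, vv = _clean(vr)
    values = np.empty(len(t))
    for s in np.unique(shifts):
        m = shifts == s
        values[m] = np.interp(t[m], vt + s, vv)
    # validity: inside the (shifted) VR support and near valid VR samples
    valid = np.ones(len(t), dtype=bool)
    valid &= (t >= vt[0] + shifts.min() - 0.5) & (t <= vt[-1] + shifts.max() + 0.5)
    if not vr.valid.all():
        bad_frac = np.interp(t - shifts, vt, (~vr.valid).astype(float))
        valid &= bad_frac < 0.5
    values = np.where(valid, values, np.nan)
    return AngleSeries(ref.name, t.copy(), values, valid)
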