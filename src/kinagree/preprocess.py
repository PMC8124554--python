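"""Re-referencing, resampling, filtering and neutral-zero offsetting.

The comparison pipeline is sensitive to phase: filter lag would masquerade
as a time shift in sample-wise differences, so the low-pass filter is
applied zero-phase (forward-backward Butterworth).  Angles that can wrap
across +-180 deg are unwrapped before resampling/filtering and re-wrapped
afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import AngleSeries, KinematicRecording
from .errors import ConfigError, LengthError
from .skeleton import JOINT_ORDER, JointId


@dataclass
class PreprocessConfig:
    """Tunables of the preprocessing stage.

    target_rate : common output rate in Hz (the reference system's rate).
    lowpass_cutoff, lowpass_order : zero-phase Butterworth design.
    neutral_window : seconds of initial neutral stance averaged for the
        per-angle zero offset.
    max_isolated_gap : longest run of missing samples filled by linear
        interpolation; longer runs are left to the synchronization stage.
    """

    target_rate: float = 100.0
    lowpass_cutoff: float = 3.0
    lowpass_order: int = 2
    neutral_window: float = 2.0
    max_isolated_gap: int = 1

    def __post_init__(self) -> None:
        if min(self.target_rate, self.lowpass_cutoff, self.neutral_window) <= 0:
            raise ConfigError("preprocess parameters must be positive")
        if self.lowpass_order < 1 or self.max_isolated_gap < 0:
            raise ConfigError("invalid filter order / gap length")
        if self.target_rate <= 2.0 * self.lowpass_cutoff:
            raise ConfigError("target_rate must exceed twice the low-pass cutoff")


def shift_origin_to_hip(recording: KinematicRecording) -> KinematicRecording:
    """Translate every frame so hip_center sits at the origin.

    Orientations are untouched; inter-joint distances are preserved.  The
    operation is idempotent.
    """
    out = recording.copy()
    k = JOINT_ORDER.index(JointId.hip_center)
    out.positions = out.positions - out.positions[:, k : k + 1, :]
    return out


def regularize(series: AngleSeries, rate: float) -> AngleSeries:
    """Linear-interpolate a (possibly irregular) series onto a uniform grid.

    Invalid samples are excluded from the interpolation support; output
    samples farther than one nominal step from any valid input sample are
    flagged invalid.
    """
    if len(series) < 2:
        raise LengthError("series too short to regularize")
    t0, t1 = series.times[0], series.times[-1]
    n = int(np.floor((t1 - t0) * rate)) + 1
    times = t0 + np.arange(n) / rate
    src_t = series.times[series.valid]
    src_v = series.values[series.valid]
    if len(src_t) < 2:
        raise LengthError("too few valid samples to regularize")
    values = np.interp(times, src_t, src_v)
    # distance to nearest valid support sample
    idx = np.searchsorted(src_t, times).clip(1, len(src_t) - 1)
    near = np.minimum(np.abs(times - src_t[idx - 1]), np.abs(times - src_t[idx]))
    valid = near <= 1.0 / rate
    values = np.where(valid, values, np.nan)
    return AngleSeries(series.name, times, values, valid)


def resample_to_rate(series: AngleSeries, target_rate: float) -> AngleSeries:
    """Fourier-based resampling of a uniformly sampled series.

    The output covers the same span on a uniform grid at ``target_rate``.
    """
    if len(series) < 2:
        raise LengthError("series too short to resample")
    t = series.times
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise ConfigError("resample_to_rate requires uniform sampling; regularize first")
    # output count chosen so the uniform spacing lands on 1/target_rate
    # (Fourier resampling spreads n*dt over n_out samples)
    n_out = max(2, int(round(len(t) * float(np.median(dt)) * target_rate)))
    vals = series.values.copy()
    if np.any(~series.valid):  # Fourier resampling cannot carry NaNs
        vals = np.interp(t, t[series.valid], vals[series.valid])
    resampled, times = signal.resample(vals, n_out, t=t)
    out_valid = np.interp(times, t, series.valid.astype(float)) > 0.5
    resampled = np.where(out_valid, resampled, np.nan)
    return AngleSeries(series.name, times, resampled, out_valid)


def lowpass(series: AngleSeries, cutoff: float = 3.0, order: int = 2) -> AngleSeries:
    """Zero-phase Butterworth low-pass with unit DC gain."""
    if len(series) < 2:
        raise LengthError("series too short to filter")
    dt = np.diff(series.times)
    rate = 1.0 / float(np.median(dt))
    if rate <= 2.0 * cutoff:
        raise ConfigError(f"sample rate {rate:.1f} Hz too low for cutoff {cutoff} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    vals = series.values.copy()
    if np.any(~series.valid):
        vals = np.interp(series.times, series.times[series.valid], vals[series.valid])
    filtered = signal.sosfiltfilt(sos, vals)
    filtered = np.where(series.valid, filtered, np.nan)
    return AngleSeries(series.name, series.times.copy(), filtered, series.valid.copy())


def interpolate_isolated(series: AngleSeries, max_gap: int = 1) -> AngleSeries:
    """Fill runs of at most ``max_gap`` missing samples by linear interpolation.

    Longer runs remain flagged for the synchronization stage.
    """
    valid = series.valid.copy()
    values = series.values.copy()
    if valid.all() or not valid.any():
        return series.copy()
    n = len(valid)
    i = 0
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        run = j - i
        if run <= max_gap and i > 0 and j < n:
            values[i:j] = np.interp(
                series.times[i:j],
                [series.times[i - 1], series.times[j]],
                [values[i - 1], values[j]],
            )
            valid[i:j] = True
        i = j
    return AngleSeries(series.name, series.times.copy(), values, valid)


def neutral_zero_offset(
    series: AngleSeries, neutral_window: float = 2.0, min_coverage: float = 0.5
) -> tuple[AngleSeries, float]:
    """Subtract the mean of the initial neutral-stance window.

    Returns the corrected series and the offset (degrees).  The recording
    protocol guarantees the series opens with a neutral standing phase; the
    offset re-zeros each angle in the neutral-zero-method sense.  At least
    ``min_coverage`` of the window's samples must be valid — an angle that
    is undefined in the neutral posture (e.g. the azimuth of a hanging arm)
    must not receive an offset from a few stray marginal samples.
    """
    if len(series) == 0:
        raise LengthError("empty series")
    t0 = series.times[0]
    in_window = series.times <= t0 + neutral_window
    m = in_window & series.valid
    if series.times[-1] - t0 < neutral_window:
        raise LengthError("neutral window exceeds series span")
    if m.sum() < min_coverage * in_window.sum():
        raise LengthError("too few valid samples in neutral window")
    offset = float(np.mean(series.values[m]))
    return (
        AngleSeries(
            series.name, series.times.copy(), series.values - offset, series.valid.copy()
        ),
        offset,
    )


def unwrap_degrees(series: AngleSeries) -> AngleSeries:
    """Unwrap +-180 deg crossings (valid samples only)."""
    vals = series.values.copy()
    v = series.valid
    vals[v] = np.degrees(np.unwrap(np.radians(vals[v])))
    return AngleSeries(series.name, series.times.copy(), vals, v.copy())


def wrap_degrees(series: AngleSeries) -> AngleSeries:
    """Wrap values back into (-180, 180]."""
    vals = series.values.copy()
    v = series.valid
    vals[v] = ((vals[v] + 180.0) % 360.0) - 180.0
    vals[v] = np.where(vals[v] == -180.0, 180.0, vals[v])
    return AngleSeries(series.name, series.times.copy(), vals, v.copy())
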