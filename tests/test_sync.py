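"""Synchronization: preamble offset, DTW coarse shift, FFT fine shift,
per-segment resynchronization, and gap detection."""

import numpy as np
import pytest

import kinagree as kg
from kinagree.core import AngleSeries
from kinagree.errors import SyncError
from kinagree.sync import (
    FLAT_FLAG,
    LOWCONF_FLAG,
    SyncConfig,
    detect_gaps,
    dtw_coarse_offset,
    fft_fine_offset,
    resync_segments,
    tpose_initial_offset,
)


def _pulses(t, starts, amplitude=90.0, ramp=1.0, hold=0.4, ret=1.0):
    v = np.zeros_like(t)
    for t0 in starts:
        m = (t >= t0) & (t < t0 + ramp)
        v[m] = np.maximum(v[m], amplitude * 0.5 * (1 - np.cos(np.pi * (t[m] - t0) / ramp)))
        m = (t >= t0 + ramp) & (t < t0 + ramp + hold)
        v[m] = amplitude
        m = (t >= t0 + ramp + hold) & (t < t0 + ramp + hold + ret)
        v[m] = np.maximum(
            v[m], amplitude * 0.5 * (1 - np.cos(np.pi * (t0 + ramp + hold + ret - t[m]) / ret))
        )
    return v


def _lagged(t_src, v_src, lag, rate=90.0, lo=-3.0, hi=3.0, noise=0.0, rng=None):
    """A series whose content is `lag` seconds later than the source."""
    tv = np.arange(t_src[0] + lo, t_src[-1] + hi, 1.0 / rate)
    pad_t = np.concatenate([[tv[0] - lag - 10], t_src, [tv[-1] - lag + 10]])
    pad_v = np.concatenate([[v_src[0]], v_src, [v_src[-1]]])
    vv = np.interp(tv - lag, pad_t, pad_v)
    if noise and rng is not None:
        vv = vv + rng.normal(0, noise, len(tv))
    return AngleSeries("a", tv, vv)


class TestTposeOffset:
    def test_injected_delay_recovered(self):
        t = np.arange(0, 15, 0.01)
        ref = AngleSeries("a", t, _pulses(t, [2.0, 4.7, 7.4]))
        vr = _lagged(t, ref.values, 0.37)
        lag = tpose_initial_offset(ref, vr)
        assert lag == pytest.approx(0.37, abs=0.01)

    def test_zero_delay(self):
        t = np.arange(0, 15, 0.01)
        ref = AngleSeries("a", t, _pulses(t, [2.0, 4.7, 7.4]))
        vr = _lagged(t, ref.values, 0.0)
        assert tpose_initial_offset(ref, vr) == pytest.approx(0.0, abs=0.01)

    def test_missing_preamble_rejected(self):
        t = np.arange(0, 15, 0.01)
        ref = AngleSeries("a", t, _pulses(t, [2.0, 4.7, 7.4]))
        flat = AngleSeries("a", t, np.zeros(len(t)))
        with pytest.raises(SyncError):
            tpose_initial_offset(ref, flat)

    def test_two_pulses_not_enough(self):
        t = np.arange(0, 15, 0.01)
        ref = AngleSeries("a", t, _pulses(t, [2.0, 4.7, 7.4]))
        vr = AngleSeries("a", t, _pulses(t, [2.0, 4.7]))
        with pytest.raises(SyncError):
            tpose_initial_offset(ref, vr)


class TestDtwCoarse:
    def test_injected_shift_recovered(self, rng):
        t = np.arange(0, 9, 0.01)
        ref = AngleSeries("a", t + 50, _pulses(t, [0.5, 3.25, 6.0], amplitude=140))
        vr = _lagged(t + 50, ref.values, 1.2, noise=0.5, rng=rng)
        lag, applied, flags = dtw_coarse_offset(ref, vr)
        assert applied and abs(lag - 1.2) <= 0.05

    def test_identical_segments_give_zero(self):
        t = np.arange(0, 9, 0.01)
        v = _pulses(t, [0.5, 3.25, 6.0], amplitude=140)
        ref = AngleSeries("a", t, v)
        vr = _lagged(t, v, 0.0)
        lag, applied, flags = dtw_coarse_offset(ref, vr)
        assert abs(lag) <= 0.05
        assert not applied  # below the coarse threshold

    def test_constant_segments_flagged(self):
        t = np.arange(0, 9, 0.01)
        ref = AngleSeries("a", t, np.full(len(t), 1.0))
        vr = AngleSeries("a", t, np.full(len(t), 1.0))
        lag, applied, flags = dtw_coarse_offset(ref, vr)
        assert lag == 0.0 and not applied and FLAT_FLAG in flags

    def test_out_of_range_shift_reported_not_applied(self, rng):
        t = np.arange(0, 9, 0.01)
        ref = AngleSeries("a", t + 50, _pulses(t, [0.5], amplitude=140))
        vr = _lagged(t + 50, ref.values, 2.6, lo=-4, hi=4, noise=0.3, rng=rng)
        cfg = SyncConfig(dtw_band=4.0)
        lag, applied, flags = dtw_coarse_offset(ref, vr, cfg)
        assert not applied
        assert abs(lag) > 2.0


class TestFftFine:
    def test_sub_sample_shift_recovered(self, rng):
        t = np.arange(0, 8, 0.01)
        v = _pulses(t, [1.0, 4.0], amplitude=90)
        ref = AngleSeries("a", t, v)
        vr = _lagged(t, v, 0.083, lo=-0.6, hi=0.6, noise=0.3, rng=rng)
        lag, flags = fft_fine_offset(ref, vr)
        assert lag == pytest.approx(0.083, abs=0.005)

    def test_zero_shift(self):
        t = np.arange(0, 8, 0.01)
        v = _pulses(t, [1.0, 4.0])
        ref = AngleSeries("a", t, v)
        vr = _lagged(t, v, 0.0, lo=-0.6, hi=0.6)
        lag, _ = fft_fine_offset(ref, vr)
        assert abs(lag) <= 0.005

    def test_white_noise_pair_low_confidence(self, rng):
        t = np.arange(0, 8, 0.01)
        ref = AngleSeries("a", t, rng.normal(size=len(t)))
        vr = AngleSeries("a", t, rng.normal(size=len(t)))
        _, flags = fft_fine_offset(ref, vr)
        assert LOWCONF_FLAG in flags


class TestGapDetector:
    def test_dropped_spans_detected(self, full_session):
        from kinagree.synth import DegradationParams

        params = DegradationParams(
            noise_sd=0.0, timestamp_jitter=0.0, dropouts=[(30.0, 0.5), (80.0, 0.2)]
        )
        vr = kg.degrade_to_vr(full_session, params)
        gaps = detect_gaps(vr.times, 90.0, factor=1.5)
        starts = [g[0] for g in gaps]
        assert any(abs(s - 30.0) < 0.1 for s in starts)
        assert any(abs(s - 80.0) < 0.1 for s in starts)
        assert len(gaps) == 2

    def test_clean_stream_has_no_gaps(self, full_session):
        gaps = detect_gaps(full_session.recording.times, 100.0)
        assert gaps == []


def _segment_pair(full_session, full_angles, vr_rec):
    vr_angles = kg.compute_angle_series(vr_rec)
    anns = [a for a in full_session.annotations if a.movement_id != kg.PREAMBLE_ID]
    return full_angles, vr_angles, anns


def _interruptions_after(annotations, ids_spans):
    """Interruption list placed just after given movements, in the VR clock
    (which earlier interruptions have already compressed), plus the
    expected cumulative shift per movement id."""
    anns = {a.movement_id: a for a in annotations if a.movement_id != kg.PREAMBLE_ID}
    placed = []
    cum = 0.0
    ref_pos = []
    for mid, span in ids_spans:
        t_ref = anns[mid].t_end + 0.2
        placed.append((t_ref - cum, span))
        ref_pos.append((t_ref, span))
        cum += span
    expected = {}
    for a in anns.values():
        expected[a.movement_id] = sum(s for t, s in ref_pos if t < a.t_start)
    return placed, expected


class TestResyncSegments:
    def _residual_lag(self, ref, aligned, t0, t1, search=0.3):
        """Residual lag inside a window by dense cross-correlation over the
        commonly valid samples, searched within +-`search` seconds."""
        m = (ref.times >= t0) & (ref.times <= t1) & ref.valid & aligned.valid
        if m.sum() < 100:
            return 0.0
        x = ref.values[m] - np.mean(ref.values[m])
        y = aligned.values[m] - np.mean(aligned.values[m])
        c = np.correlate(y, x, mode="full")
        lags = (np.arange(len(c)) - (len(x) - 1)) * 0.01
        w = np.abs(lags) <= search
        return lags[w][np.argmax(c[w])]

    def test_single_interruption_recovered(self, full_session, full_angles):
        from kinagree.synth import DegradationParams

        placed, _ = _interruptions_after(full_session.annotations, [("10", 0.7)])
        params = DegradationParams(
            noise_sd=0.5, timestamp_jitter=0.0, interruptions=placed, seed=5
        )
        vr_rec = kg.degrade_to_vr(full_session, params)
        ref_angles, vr_angles, anns = _segment_pair(full_session, full_angles, vr_rec)
        # preprocess vr onto a regular grid first
        from kinagree.preprocess import lowpass, regularize, resample_to_rate

        vr_angles = {
            n: lowpass(resample_to_rate(regularize(s, 90.0), 100.0), 3.0)
            for n, s in vr_angles.items()
        }
        ref_angles = {n: lowpass(s, 3.0) for n, s in ref_angles.items()}
        aligned, results = resync_segments(ref_angles, vr_angles, anns)
        for ann in anns:
            for angle in ann.linked_angles:
                seg = ref_angles[angle].window(ann.t_start, ann.t_end)
                if np.std(seg.values[seg.valid]) < 5.0:
                    continue  # angle barely moves here; lag is unobservable
                lag = self._residual_lag(
                    ref_angles[angle], aligned[angle], ann.t_start, ann.t_end
                )
                assert abs(lag) < 0.02, f"segment {ann.movement_id} {angle}"

    def test_no_interruption_small_shifts(self, full_session, full_angles, null_vr):
        ref_angles, vr_angles, anns = _segment_pair(full_session, full_angles, null_vr)
        from kinagree.preprocess import regularize, resample_to_rate

        vr_angles = {
            n: resample_to_rate(regularize(s, 90.0), 100.0)
            for n, s in vr_angles.items()
        }
        _, results = resync_segments(ref_angles, vr_angles, anns)
        for r in results:
            assert abs(r.total_shift) <= 0.011, r.segment_id

    def test_three_interruptions_cumulative(self, full_session, full_angles):
        from kinagree.preprocess import lowpass, regularize, resample_to_rate
        from kinagree.synth import DegradationParams

        placed, cum = _interruptions_after(
            full_session.annotations, [("02", 0.6), ("09", 0.9), ("15", 1.5)]
        )
        params = DegradationParams(
            noise_sd=0.5, timestamp_jitter=0.0, interruptions=placed, seed=6
        )
        vr_rec = kg.degrade_to_vr(full_session, params)
        ref_angles, vr_angles, anns = _segment_pair(full_session, full_angles, vr_rec)
        vr_angles = {
            n: lowpass(resample_to_rate(regularize(s, 90.0), 100.0), 3.0)
            for n, s in vr_angles.items()
        }
        ref_angles = {n: lowpass(s, 3.0) for n, s in ref_angles.items()}
        _, results = resync_segments(ref_angles, vr_angles, anns)
        for r in results:
            if FLAT_FLAG in r.flags or "segment_too_short" in r.flags:
                continue
            assert r.total_shift == pytest.approx(cum[r.segment_id], abs=0.05), (
                r.segment_id
            )

    def test_invariants_on_results(self, full_session, full_angles):
        from kinagree.preprocess import lowpass, regularize, resample_to_rate
        from kinagree.synth import DegradationParams

        params = DegradationParams(
            noise_sd=0.5, timestamp_jitter=0.0, interruptions=[(100.0, 1.0)], seed=7
        )
        vr_rec = kg.degrade_to_vr(full_session, params)
        ref_angles, vr_angles, anns = _segment_pair(full_session, full_angles, vr_rec)
        vr_angles = {
            n: lowpass(resample_to_rate(regularize(s, 90.0), 100.0), 3.0)
            for n, s in vr_angles.items()
        }
        ref_angles = {n: lowpass(s, 3.0) for n, s in ref_angles.items()}
        _, results = resync_segments(ref_angles, vr_angles, anns)
        for r in results:
            if r.coarse_shift != 0.0:
                assert 0.5 <= abs(r.coarse_shift) <= 2.0
            assert abs(r.fine_shift) < 1.0  # iterated fine passes, each < 0.5

    def test_resync_of_synchronized_pair_is_noop(self, full_session, full_angles):
        """Applying resync to an already synchronized pair changes the RMS
        difference by less than 0.1 deg."""
        ref_angles = full_angles
        vr_angles = {n: s.copy() for n, s in ref_angles.items()}
        anns = [a for a in full_session.annotations if a.movement_id != kg.PREAMBLE_ID]
        aligned, _ = resync_segments(ref_angles, vr_angles, anns)
        for name in ("elbow_left_flex", "neck_flex", "knee_left_flex"):
            m = aligned[name].valid & ref_angles[name].valid
            rms = np.sqrt(np.mean((aligned[name].values[m] - ref_angles[name].values[m]) ** 2))
            assert rms < 0.1
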