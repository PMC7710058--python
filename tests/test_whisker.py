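"""Whisker motion energy, bout detection, and tip-displacement analysis."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.stats import spearmanr

from satkit.whisker import (
    Bout,
    MotionTrace,
    WhiskerTrack,
    detect_bouts,
    displacement_and_area,
    motion_energy,
    normalize_trace,
    percent_whisking,
    synth_whisker_video,
    whisking_threshold,
)

FPS = 30.0


def make_trace(values, onset=40, normalized=False):
    return MotionTrace(
        values=np.asarray(values, dtype=float),
        frame_rate_hz=FPS,
        stim_onset_frame=onset,
        normalized=normalized,
    )


def brute_force_bouts(above, fps, min_s):
    """Oracle: scan run lengths of a boolean trace by hand."""
    bouts, start = [], None
    for i, flag in enumerate(list(above) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if (i - start) / fps >= min_s - 1e-12:
                bouts.append((start / fps, i / fps))
            start = None
    return bouts


class TestMotionEnergy:
    def test_static_scene_trace_is_flat(self):
        frames, _ = synth_whisker_video(n_frames=60, noise_sigma=0.0, rng=0)
        trace = motion_energy(frames, stim_onset_frame=40)
        interior = trace.values[6:-6]  # clear of temporal-kernel edge effects
        assert np.ptp(interior) < 1e-6 * max(np.mean(trace.values), 1e-30) + 1e-12

    def test_moving_filament_beats_static_frames(self):
        n = 120
        defl = np.zeros(n)
        defl[40:80] = 4 * np.sin(2 * np.pi * 6 * np.arange(40) / FPS)
        frames, _ = synth_whisker_video(n_frames=n, deflection_px=defl, rng=1)
        trace = motion_energy(frames, stim_onset_frame=40)
        moving = trace.values[45:75].mean()
        still = trace.values[10:35].mean()
        assert moving > 5 * still

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            motion_energy(np.zeros((1, 8, 8)))

    def test_rank_correlates_with_frame_difference_oracle(self):
        n = 300
        rng = np.random.default_rng(0)
        tt = np.arange(n) / FPS
        envelope = np.abs(gaussian_filter1d(rng.normal(0, 1, size=n), 15))
        defl = 6 * envelope * np.sin(2 * np.pi * 6 * tt)
        frames, _ = synth_whisker_video(n_frames=n, deflection_px=defl, rng=rng)
        trace = motion_energy(frames, stim_onset_frame=60)
        oracle = np.zeros(n)
        oracle[1:] = np.sum(np.diff(frames, axis=0) ** 2, axis=(1, 2))
        oracle = np.convolve(oracle, np.ones(5) / 5, mode="same")
        rho = spearmanr(trace.values[6:-6], oracle[6:-6]).statistic
        assert rho > 0.8


class TestNormalization:
    def test_constant_trace_normalizes_to_zero(self):
        trace = make_trace(np.full(100, 7.3))
        assert np.allclose(normalize_trace(trace).values, 0.0)

    def test_shift_invariance(self, rng):
        values = rng.random(120)
        a = normalize_trace(make_trace(values)).values
        b = normalize_trace(make_trace(values + 11.0)).values
        assert np.allclose(a, b)

    def test_low_20th_percentile_subset_mean(self):
        # pre-window exactly {1..10} twice (36 frames needed -> pad with 10s)
        pre = np.array(list(range(1, 11)) * 4, dtype=float)[:36]
        values = np.concatenate([pre, np.zeros(30)])
        normed = normalize_trace(make_trace(values, onset=36))
        # 20th percentile of the window is 2.8 -> subset {1, 2}*k, mean 1.5
        assert np.allclose(normed.values, values - 1.5)

    def test_insufficient_prestimulus_data_is_error(self):
        with pytest.raises(ValueError):
            normalize_trace(make_trace(np.zeros(100), onset=10))


class TestThreshold:
    def test_all_zero_baseline_gives_zero(self):
        trace = make_trace(np.zeros(100), normalized=True)
        assert whisking_threshold(trace) == 0.0

    def test_standard_normal_baseline_approaches_three(self):
        rng = np.random.default_rng(8)
        n_pre = 3000
        trace = MotionTrace(
            values=rng.standard_normal(n_pre + 10),
            frame_rate_hz=n_pre / 1.2,  # whole pre-window inside 1.2 s
            stim_onset_frame=n_pre,
            normalized=True,
        )
        assert whisking_threshold(trace) == pytest.approx(3.0, abs=0.15)

    def test_scale_equivariance(self, rng):
        values = rng.random(120)
        t1 = make_trace(values, normalized=True)
        t2 = make_trace(2 * values, normalized=True)
        assert whisking_threshold(t2) == pytest.approx(2 * whisking_threshold(t1))

    def test_requires_normalized_trace(self):
        with pytest.raises(ValueError):
            whisking_threshold(make_trace(np.zeros(100), normalized=False))


class TestBoutDetection:
    def _trace_from_runs(self, runs):
        """runs: list of (n_frames, above?) pairs."""
        vals = np.concatenate([np.full(n, 1.0 if above else -1.0) for n, above in runs])
        return make_trace(vals, normalized=True)

    def test_run_shorter_than_half_second_dropped(self):
        trace = self._trace_from_runs([(30, False), (12, True), (30, False)])  # 0.4 s
        assert len(detect_bouts(trace, 0.0)) == 0

    def test_run_of_0_6_s_is_one_bout(self):
        trace = self._trace_from_runs([(30, False), (18, True), (30, False)])
        bouts = detect_bouts(trace, 0.0)
        assert len(bouts) == 1
        assert bouts.bouts[0].duration_s == pytest.approx(0.6)

    def test_exactly_half_second_kept(self):
        trace = self._trace_from_runs([(30, False), (15, True), (30, False)])
        assert len(detect_bouts(trace, 0.0)) == 1

    def test_single_subthreshold_sample_splits_bouts(self):
        trace = self._trace_from_runs(
            [(30, False), (18, True), (1, False), (18, True), (30, False)]
        )
        assert len(detect_bouts(trace, 0.0)) == 2

    def test_agrees_with_run_length_oracle_on_random_traces(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            above = rng.random(rng.integers(10, 200)) < 0.5
            trace = make_trace(np.where(above, 1.0, -1.0), normalized=True)
            got = [(b.start_s, b.end_s) for b in detect_bouts(trace, 0.0)]
            expected = brute_force_bouts(above, FPS, 0.5)
            assert got == pytest.approx(expected)

    def test_no_detected_bout_shorter_than_minimum(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            trace = make_trace(rng.normal(size=300), normalized=True)
            for bout in detect_bouts(trace, 0.5):
                assert bout.duration_s >= 0.5 - 1e-12


class TestPercentWhisking:
    def _trial_with_bout(self, whisk, rng):
        n = 150  # 5 s; onset at 1.2 s
        vals = rng.normal(0, 0.05, size=n)
        if whisk:
            vals[81:111] += 5.0  # 1.5-2.5 s post-onset, 1 s long
        return make_trace(vals, onset=36)

    def test_every_trial_whisking(self, rng):
        trials = [self._trial_with_bout(True, rng) for _ in range(20)]
        assert percent_whisking(trials) == 100.0

    def test_no_trial_whisking(self, rng):
        trials = [self._trial_with_bout(False, rng) for _ in range(20)]
        assert percent_whisking(trials) == 0.0

    def test_binomial_recovery_of_trial_probability(self):
        rng = np.random.default_rng(99)
        trials = [self._trial_with_bout(rng.random() < 0.6, rng) for _ in range(500)]
        assert percent_whisking(trials) == pytest.approx(60.0, abs=5.0)

    def test_empty_trial_list_is_error(self):
        with pytest.raises(ValueError):
            percent_whisking([])


class TestDisplacement:
    def _track(self, x, y, onset=36):
        return WhiskerTrack(x=np.asarray(x, float), y=np.asarray(y, float),
                            frame_rate_hz=FPS, stim_onset_frame=onset)

    def test_stationary_tip_zero_area(self):
        track = self._track(np.full(100, 5.0), np.full(100, 7.0))
        disp, area = displacement_and_area(track, (0.0, 0.5))
        assert np.allclose(disp, 0.0)
        assert area == 0.0

    def test_constant_offset_rectangle_area(self):
        x = np.full(100, 5.0)
        y = np.full(100, 7.0)
        y[36:] += 3.0  # offset by d=3 from stimulus onset onward
        disp, area = displacement_and_area(self._track(x, y), (0.0, 0.5))
        assert area == pytest.approx(3.0 * 0.5)

    def test_sinusoid_matches_analytic_integral(self):
        n = 200
        t = np.arange(n) / FPS
        amp = 4.0
        y = np.where(np.arange(n) >= 36, amp * np.sin(2 * np.pi * 1.0 * (t - 36 / FPS)), 0.0)
        disp, area = displacement_and_area(self._track(np.zeros(n), y), (0.0, 1.0))
        # integral of |amp sin| over one full period = 2 * amp / (pi * f) ... per second
        expected = 2 * amp / np.pi
        assert area == pytest.approx(expected, rel=0.01)

    def test_gap_in_track_is_error(self):
        x = np.full(100, 5.0)
        x[50] = np.nan
        with pytest.raises(ValueError, match="gap"):
            displacement_and_area(self._track(x, np.zeros(100)), (0.0, 0.5))


class TestEndToEnd:
    def test_synthetic_whisking_epoch_recovered(self):
        """Rendered whisking epoch -> detected bout with >= 0.9 IoU."""
        rng = np.random.default_rng(0)
        n = 240
        tt = np.arange(n) / FPS
        epoch = (tt >= 4.0) & (tt < 7.0)
        defl = np.zeros(n)
        defl[epoch] = 5 * np.sin(2 * np.pi * 8 * tt[epoch]) + gaussian_filter1d(
            rng.normal(0, 3, size=epoch.sum()), 1.0
        )
        frames, _ = synth_whisker_video(n_frames=n, deflection_px=defl, rng=rng)
        trace = motion_energy(frames, stim_onset_frame=60)
        normed = normalize_trace(trace)
        bouts = detect_bouts(normed, whisking_threshold(normed))
        assert len(bouts) >= 1
        lo = min(b.start_s for b in bouts)
        hi = max(b.end_s for b in bouts)
        inter = max(0.0, min(hi, 7.0) - max(lo, 4.0))
        union = max(hi, 7.0) - min(lo, 4.0)
        assert inter / union >= 0.9

    def test_zero_deflection_detects_nothing(self):
        frames, _ = synth_whisker_video(n_frames=120, noise_sigma=0.02, rng=3)
        trace = motion_energy(frames, stim_onset_frame=40)
        normed = normalize_trace(trace)
        bouts = detect_bouts(normed, whisking_threshold(normed))
        assert len(bouts) == 0

    def test_ground_truth_track_self_consistency(self):
        n = 120
        defl = np.zeros(n)
        defl[40:] = 3.0
        _, track = synth_whisker_video(n_frames=n, deflection_px=defl, rng=4)
        track.stim_onset_frame = 36
        disp, area = displacement_and_area(track, (0.2, 0.5))
        assert np.allclose(disp[:40], 0.0, atol=1e-9)
        assert np.allclose(disp[40:], 3.0, atol=1e-9)
        assert area == pytest.approx(3.0 * 0.3, rel=1e-6)
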