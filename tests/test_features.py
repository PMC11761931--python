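"""Track preprocessing and walking-feature extraction."""

import numpy as np
import pandas as pd
import pytest

from broilerwalk.features import (
    IMPUTED,
    MASKED,
    OBSERVED,
    TrajectoryFit,
    build_track,
    completion_time,
    extract_walk_features,
    fit_trajectory,
    interpolate_gaps,
    lateral_oscillation,
    lw_ratio_series,
    mask_backward_facing,
    smooth,
    step_count,
)
from broilerwalk.synthetic import BirdWalkParams, simulate_track

from conftest import make_records


def residual_fit(res):
    res = np.asarray(res, float)
    return TrajectoryFit("b", 5, np.zeros(6), np.arange(len(res), dtype=float),
                         np.zeros(len(res)), res)


class TestBuildTrack:
    def test_center_is_box_midpoint(self):
        rec = pd.DataFrame({
            "bird_id": "b", "frame": [0], "conf": 0.9,
            "x_min": [0.0], "y_min": [0.0], "x_max": [10.0], "y_max": [20.0],
            "head_x": [8.0], "head_y": [10.0],
        })
        tr = build_track(rec, fps=11)
        assert (tr.cx[0], tr.cy[0]) == (5.0, 10.0)

    def test_missing_frames_inserted_masked(self):
        rec = make_records([1.0, 2.0, 3.0], frames=[0, 1, 3])
        tr = build_track(rec, fps=11)
        assert len(tr) == 4
        assert tr.status.tolist() == [OBSERVED, OBSERVED, MASKED, OBSERVED]
        assert np.isnan(tr.cy[2])

    def test_unsorted_input_rejected(self):
        rec = make_records([1.0, 2.0], frames=[1, 0])
        with pytest.raises(ValueError):
            build_track(rec, fps=11)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_track(make_records([]).iloc[:0], fps=11)


class TestMaskBackwardFacing:
    def _track(self, head_dx):
        return build_track(make_records(np.zeros(5), head_dx=head_dx), fps=11)

    def test_forward_kept_backward_masked(self):
        assert (mask_backward_facing(self._track(60), 1).status == OBSERVED).all()
        assert (mask_backward_facing(self._track(-60), 1).status == MASKED).all()

    def test_head_exactly_at_center_counts_as_forward(self):
        tr = mask_backward_facing(self._track(0.0), 1)
        assert (tr.status == OBSERVED).all()

    def test_direction_sign(self):
        tr = mask_backward_facing(self._track(60), -1)
        assert (tr.status == MASKED).all()


class TestInterpolateGaps:
    def _gappy(self, n, masked_idx):
        rec = make_records(np.arange(n, dtype=float) * 2)
        keep = ~np.isin(np.arange(n), masked_idx)
        return build_track(rec.loc[keep], fps=11)

    def test_linear_midpoint(self):
        tr = interpolate_gaps(self._gappy(3, [1]))
        assert tr.cy[1] == pytest.approx((tr.cy[0] + tr.cy[2]) / 2)
        assert tr.status[1] == IMPUTED

    def test_gap_of_five_imputed(self):
        tr = interpolate_gaps(self._gappy(10, [2, 3, 4, 5, 6]), max_gap=5)
        assert not tr.excluded
        assert (tr.status[2:7] == IMPUTED).all()
        assert np.allclose(tr.cy, np.arange(10) * 2)

    def test_gap_of_six_flags_exclusion(self):
        tr = interpolate_gaps(self._gappy(12, [2, 3, 4, 5, 6, 7]), max_gap=5)
        assert tr.excluded
        assert (tr.status[2:8] == MASKED).all()

    def test_masked_endpoints_trimmed(self):
        rec = make_records(np.arange(6, dtype=float), frames=[0, 1, 2, 3, 4, 6])
        tr = build_track(rec, fps=11)
        tr.status[0] = MASKED
        tr.cy[0] = np.nan
        out = interpolate_gaps(tr)
        assert out.frames[0] == 1           # masked leading frame trimmed
        assert out.frames[-1] == 6          # observed endpoint retained
        assert out.status[np.flatnonzero(out.frames == 5)[0]] == IMPUTED


class TestSmooth:
    def test_constant_series_fixed_point(self):
        tr = build_track(make_records(np.full(6, 7.0)), fps=11)
        assert np.allclose(smooth(tr).cy, 7.0)

    def test_interior_and_truncated_ends(self):
        tr = build_track(make_records([0.0, 3.0, 6.0]), fps=11)
        sm = smooth(tr, window=3)
        assert sm.cy[1] == pytest.approx(3.0)
        assert sm.cy[0] == pytest.approx(1.5)   # mean of first two only
        assert sm.cy[2] == pytest.approx(4.5)

    def test_even_or_nonpositive_window_rejected(self):
        tr = build_track(make_records(np.zeros(5)), fps=11)
        for w in (2, 0, -3):
            with pytest.raises(ValueError):
                smooth(tr, window=w)


class TestTrajectoryFit:
    def test_quintic_truth_gives_zero_residuals(self):
        t = np.arange(40, dtype=float)
        y = 1 + 0.5 * t - 0.02 * t**2 + 1e-4 * t**3 - 1e-6 * t**4 + 1e-8 * t**5
        tr = build_track(make_records(y), fps=11)
        fit = fit_trajectory(tr)
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_mean_residual_vanishes(self):
        rng = np.random.default_rng(0)
        y = rng.normal(200, 10, 60)
        fit = fit_trajectory(build_track(make_records(y), fps=11))
        assert abs(fit.residuals.mean()) < 1e-9 * y.std()

    def test_cubic_drift_plus_sinusoid_residual_rms(self):
        n, c = 2000, 12
        t = np.arange(n, dtype=float)
        sinus = 8 * np.sin(2 * np.pi * c * t / n + 0.4)
        drift = 200 + 0.05 * t - 1e-4 * t**2 + 2e-8 * t**3
        fit = fit_trajectory(build_track(make_records(drift + sinus), fps=11))
        rms = np.sqrt(np.mean(fit.residuals**2))
        assert rms == pytest.approx(np.sqrt(np.mean(sinus**2)), rel=0.05)

    def test_short_tracks_rejected_or_flagged(self):
        with pytest.raises(ValueError):
            fit_trajectory(build_track(make_records(np.zeros(6)), fps=11))
        fit = fit_trajectory(build_track(make_records(np.zeros(10)), fps=11))
        assert fit.short_track


class TestOscillationAndSteps:
    def test_mean_absolute_residual(self):
        assert lateral_oscillation(residual_fit([1, -1, 1, -1])) == 1.0
        assert lateral_oscillation(residual_fit(np.zeros(5))) == 0.0

    def test_dense_sinusoid_approaches_2A_over_pi(self):
        t = np.arange(5000)
        res = 10 * np.sin(2 * np.pi * 10 * t / 5000 + 0.3)
        assert lateral_oscillation(residual_fit(res)) == pytest.approx(
            20 / np.pi, rel=0.01)

    @pytest.mark.parametrize("signs,expected", [
        ([1, 1, 1], 0),
        ([1, -1, 1, -1], 3),
        ([1, 0, -1], 1),        # zero inherits previous sign: one crossing
        ([0, 0, 1, -1], 1),     # leading zeros take the first nonzero sign
    ])
    def test_sign_change_counting(self, signs, expected):
        assert step_count(residual_fit(signs)) == expected

    @pytest.mark.parametrize("c", range(1, 11))
    def test_sinusoid_crossings_twice_per_cycle(self, c):
        t = np.arange(200 * c)
        res = np.sin(2 * np.pi * c * t / len(t) + 0.5)
        assert step_count(residual_fit(res)) == 2 * c

    def test_even_crossings_when_ends_share_sign(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            res = rng.normal(0, 1, rng.integers(5, 60))
            if np.sign(res[0]) == np.sign(res[-1]) and res[0] != 0:
                assert step_count(residual_fit(res)) % 2 == 0


class TestCompletionAndRatio:
    def test_completion_time_values(self):
        assert completion_time(build_track(make_records(np.zeros(11)), fps=11)) == 1.0
        assert completion_time(build_track(make_records(np.zeros(80)), fps=11)) == \
            pytest.approx(80 / 11)
        assert completion_time(build_track(make_records(np.zeros(1)), fps=11)) == \
            pytest.approx(1 / 11)

    def test_lw_ratio(self):
        tr = build_track(make_records(np.zeros(4), box_l=40, box_w=20), fps=11)
        assert np.allclose(lw_ratio_series(tr), 2.0)
        sq = build_track(make_records(np.zeros(4), box_l=30, box_w=30), fps=11)
        assert np.allclose(lw_ratio_series(sq), 1.0)

    def test_width_doubling_halves_ratio(self):
        tr = build_track(make_records(np.zeros(4), box_l=40, box_w=20), fps=11)
        tr.width[2] *= 2
        ratio = lw_ratio_series(tr)
        assert ratio[2] == pytest.approx(ratio[0] / 2)

    def test_zero_width_rejected(self):
        tr = build_track(make_records(np.zeros(4)), fps=11)
        tr.width[:] = 0.0
        with pytest.raises(ValueError):
            lw_ratio_series(tr)


def long_walk_params(phase, amplitude=15.0, freq=0.9, duration_s=30.0,
                     noise_sd=0.0, drift=(10.0, -20.0, 15.0)):
    fps = 11.0
    n = int(duration_s * fps)
    return BirdWalkParams(
        bird_id="b1", fps=fps, corridor_length_px=1500.0,
        speed_px_per_frame=1500.0 / n, osc_amplitude_px=amplitude,
        osc_freq_hz=freq, phase_rad=phase, drift_coeffs=drift,
        noise_sd=noise_sd, pause_prob=0.0, pause_len=5,
        backward_facing_prob=0.0, missing_prob=0.0,
        lateral_center_px=200.0, box_length_px=110.0, box_width_px=70.0,
        expected_frames=n,
    )


class TestEndToEndRecovery:
    @pytest.mark.parametrize("phase", [0.3, 1.2, 2.5, 4.0])
    def test_noiseless_long_walk_recovers_ground_truth_exactly(self, phase):
        # in the many-cycle regime the quintic absorbs only the drift, so
        # crossings and duration match the programmed walk exactly
        rec, gt = simulate_track(long_walk_params(phase), seed=0)
        wf = extract_walk_features(rec, fps=11)
        assert wf.step_count == gt.true_crossings
        assert wf.completion_time == pytest.approx(gt.true_duration)

    def test_study_scale_crossings_within_boundary_tolerance(self):
        # shorter walks (~7 oscillation cycles) pick up at most +-2 extra
        # crossings where the polynomial fit wiggles at the track ends
        for seed in range(8):
            rng = np.random.default_rng(seed)
            rec, gt = simulate_track(
                long_walk_params(rng.uniform(0, 2 * np.pi), duration_s=7.5), seed=seed)
            wf = extract_walk_features(rec, fps=11)
            assert abs(wf.step_count - gt.true_crossings) <= 2

    def test_oscillation_within_2pct_with_smoothing(self):
        # >= 20 frames/cycle, many cycles: mean |residual| ~ 2A/pi scaled
        # by the known moving-average gain
        from broilerwalk.synthetic import moving_average_gain

        fps, freq, amp = 11.0, 0.5, 12.0   # 22 frames per cycle
        rec, gt = simulate_track(
            long_walk_params(0.8, amplitude=amp, freq=freq, duration_s=60.0),
            seed=0)
        wf = extract_walk_features(rec, fps=fps, window=3)
        expected = 2 * amp * moving_average_gain(freq, fps) / np.pi
        assert wf.lateral_oscillation == pytest.approx(expected, rel=0.02)

    def test_oscillation_invariant_to_cubic_drift(self):
        base, _ = simulate_track(long_walk_params(0.8, drift=(0.0, 0.0, 0.0)), seed=0)
        drifted, _ = simulate_track(long_walk_params(0.8, drift=(40.0, -60.0, 35.0)), seed=0)
        a = extract_walk_features(base, fps=11, window=1).lateral_oscillation
        b = extract_walk_features(drifted, fps=11, window=1).lateral_oscillation
        assert abs(a - b) < 1e-6

    def test_zero_amplitude_gives_zero_oscillation(self):
        rec, _ = simulate_track(long_walk_params(0.0, amplitude=0.0), seed=0)
        wf = extract_walk_features(rec, fps=11, window=1)
        assert wf.lateral_oscillation == pytest.approx(0.0, abs=1e-9)
        assert wf.step_count == 0
        # window-3 smoothing only perturbs the two truncated end frames
        wf3 = extract_walk_features(rec, fps=11, window=3)
        assert wf3.lateral_oscillation < 0.01

    def test_pipeline_order_regression(self):
        # mask -> interpolate -> smooth -> fit; smoothing before
        # interpolation would average across NaN gaps and change outputs
        rec, _ = simulate_track(long_walk_params(1.0, duration_s=15.0), seed=3)
        drop = rec.index[10:13]
        gappy = rec.drop(drop)
        tr = build_track(gappy, fps=11)
        tr = mask_backward_facing(tr, 1)
        with pytest.raises(ValueError):
            smooth(tr)  # unresolved gaps must be rejected before smoothing
        wf = extract_walk_features(gappy, fps=11)
        assert wf.n_frames == len(rec)  # gap re-inserted, then imputed
        assert not wf.excluded
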