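"""Generator contracts: sampling grid, determinism, track loss, bias control."""

import numpy as np
import pandas as pd
import pytest

import gazecourse as gc
from gazecourse.synthetic import all_stimulus_ids


def binomial_ci99(p, n):
    half = 2.576 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


class TestSamplingGrid:
    def test_sample_count_per_trial(self, small_session):
        cfg, samples, _ = small_session
        counts = samples.groupby(["subject_id", "trial_number"]).size()
        assert (counts == cfg.samples_per_trial).all()
        assert cfg.samples_per_trial == 900  # 7500 ms at 120 Hz

    def test_timestamps_strictly_increasing(self, small_session):
        _, samples, _ = small_session
        for _, grp in samples.groupby(["subject_id", "trial_number"]):
            dt = np.diff(grp["time_ms"].to_numpy())
            assert (dt > 0).all()
            assert np.allclose(dt, 1000.0 / 120.0)

    def test_valid_coordinates_within_screen(self, small_session):
        cfg, samples, _ = small_session
        ok = samples[samples["valid"] == 1]
        assert ok["x_px"].between(0, cfg.screen_width_px).all()
        assert ok["y_px"].between(0, cfg.screen_height_px).all()

    def test_design_has_four_conditions_twice(self, small_session):
        _, samples, _ = small_session
        per_subj = samples.groupby("subject_id").apply(
            lambda g: g.groupby(["face_race", "speech_type"])["trial_number"].nunique(),
            include_groups=False,
        )
        assert (per_subj == 2).all().all()


class TestDeterminism:
    def test_identical_seed_bitwise_identical(self):
        cfg = gc.SimConfig(n_subjects=2, seed=5)
        s1, t1 = gc.simulate_session(cfg)
        s2, t2 = gc.simulate_session(cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(t1.planted_fixations, t2.planted_fixations)
        pd.testing.assert_frame_equal(t1.subjects, t2.subjects)

    def test_subject_streams_unperturbed_by_cohort_size(self):
        big, _ = gc.simulate_session(gc.SimConfig(n_subjects=3, seed=5))
        small, _ = gc.simulate_session(gc.SimConfig(n_subjects=2, seed=5))
        pd.testing.assert_frame_equal(
            big[big["subject_id"].isin(["s001", "s002"])].reset_index(drop=True),
            small.reset_index(drop=True),
        )


class TestTrackLoss:
    def test_zero_rate_all_valid(self):
        samples, _ = gc.simulate_session(
            gc.SimConfig(n_subjects=2, trackloss_rate=0.0, seed=3)
        )
        assert (samples["valid"] == 1).all()
        assert samples[["x_px", "y_px"]].notna().all().all()

    def test_rate_recovered_within_ci(self):
        # Stationary loss probability equals trackloss_rate. Loss is bursty
        # (two-state Markov), so the 99% CI uses the chain's variance
        # inflation (1+rho)/(1-rho) rather than the iid binomial variance.
        rate = 0.2
        cfg = gc.SimConfig(
            n_subjects=10, trackloss_rate=rate, high_loss_trial_fraction=0.0, seed=7
        )
        samples, _ = gc.simulate_session(cfg)
        n = len(samples)
        assert n >= 10_000
        burst = cfg.trackloss_burst_ms / cfg.sample_period_ms
        b = 1.0 / burst
        a = rate * b / (1.0 - rate)
        rho = 1.0 - a - b
        inflation = (1.0 + rho) / (1.0 - rho)
        half = 2.576 * np.sqrt(rate * (1 - rate) * inflation / n)
        assert abs((samples["valid"] == 0).mean() - rate) <= half

    def test_loss_is_bursty(self):
        cfg = gc.SimConfig(
            n_subjects=3, trackloss_rate=0.2, high_loss_trial_fraction=0.0, seed=9
        )
        samples, _ = gc.simulate_session(cfg)
        lost = (samples["valid"] == 0).to_numpy()
        runs = np.diff(np.flatnonzero(np.diff(lost.astype(int)) != 0))
        # mean run length far above the iid expectation (~1.25 samples)
        assert runs.mean() > 3.0

    def test_invalid_samples_have_no_coordinates(self, small_session):
        _, samples, _ = small_session
        lost = samples[samples["valid"] == 0]
        assert lost[["x_px", "y_px"]].isna().all().all()


class TestAOITrajectory:
    def test_zero_amplitude_is_static(self):
        cfg = gc.SimConfig(n_subjects=1, face_motion_amplitude_px=0.0, seed=1)
        traj = gc.make_aoi_trajectory(cfg, 0)
        assert np.allclose(traj.upper, traj.upper[0])
        assert np.allclose(traj.lower, traj.lower[0])

    def test_rectangle_dimensions_from_cm(self):
        cfg = gc.SimConfig(n_subjects=1, seed=1)
        traj = gc.make_aoi_trajectory(cfg, 0)
        for rects in (traj.upper, traj.lower):
            assert np.allclose(rects[:, 2] - rects[:, 0], round(16.0 * cfg.px_per_cm))
            assert np.allclose(rects[:, 3] - rects[:, 1], round(8.5 * cfg.px_per_cm))

    def test_halves_abut_at_every_timestamp(self):
        cfg = gc.SimConfig(n_subjects=1, seed=2)
        traj = gc.make_aoi_trajectory(cfg, 3)
        assert np.array_equal(traj.upper[:, 3], traj.lower[:, 1])  # shared edge
        assert np.array_equal(traj.upper[:, [0, 2]], traj.lower[:, [0, 2]])

    def test_trajectories_stay_on_screen(self, small_session):
        cfg, _, truth = small_session
        for traj in truth.aoi_trajectories.values():
            assert traj.upper[:, 0].min() >= 0 and traj.upper[:, 2].max() <= cfg.screen_width_px
            assert traj.upper[:, 1].min() >= 0 and traj.lower[:, 3].max() <= cfg.screen_height_px


class TestPlantedFixations:
    def test_nonoverlapping_ordered_and_above_threshold(self, small_session):
        _, _, truth = small_session
        for _, grp in truth.planted_fixations.groupby(["subject_id", "trial_number"]):
            grp = grp.sort_values("start_ms")
            assert (grp["end_ms"].to_numpy()[:-1] <= grp["start_ms"].to_numpy()[1:]).all()
            below = grp["end_ms"] - grp["start_ms"] < 80.0
            assert (grp.loc[below, "sub_threshold"]).all()

    def test_constant_bias_recovered(self):
        # Constant 0.7 lower-half profile: the share of planted fixations
        # targeting the lower AOI must sit in the 99% binomial CI of 0.7.
        cfg = gc.SimConfig(
            n_subjects=200,
            bias_profile=gc.BiasProfile(baseline=0.7),
            trackloss_rate=0.0,
            seed=13,
        )
        _, truth = gc.simulate_session(cfg)
        fx = truth.planted_fixations
        frac = (fx["target_aoi"] == "lower").mean()
        lo, hi = binomial_ci99(0.7, len(fx))
        assert lo <= frac <= hi
        # duration-weighted fraction agrees closely (durations independent of target)
        dur = fx["end_ms"] - fx["start_ms"]
        weighted = dur[fx["target_aoi"] == "lower"].sum() / dur.sum()
        assert abs(weighted - 0.7) < 0.02


class TestInjectBias:
    def test_zero_magnitude_is_identity(self):
        cfg = gc.SimConfig(n_subjects=2, seed=1)
        assert gc.inject_bias(cfg, (2000, 4000), 0.0) is cfg

    def test_full_window_equals_constant_profile(self):
        cfg = gc.SimConfig(n_subjects=2, seed=1, bias_profile=gc.BiasProfile(baseline=0.5))
        shifted = gc.inject_bias(cfg, (0, 7500), 0.25)
        const = gc.BiasProfile(baseline=0.75)
        for t in np.linspace(0, 7499, 40):
            for cond in gc.CONDITIONS:
                assert shifted.bias_profile.lookup(t, cond) == const.lookup(t, cond)

    def test_out_of_range_probability_rejected(self):
        cfg = gc.SimConfig(bias_profile=gc.BiasProfile(baseline=0.9))
        with pytest.raises(gc.ConfigError):
            gc.inject_bias(cfg, (0, 1000), 0.2)
        with pytest.raises(gc.ConfigError):
            gc.inject_bias(cfg, (5000, 9000), -0.1)

    def test_window_bias_recovered_inside_and_outside(self):
        cfg = gc.SimConfig(
            n_subjects=100,
            bias_profile=gc.BiasProfile(baseline=0.5),
            trackloss_rate=0.0,
            seed=29,
        )
        cfg = gc.inject_bias(cfg, (2000.0, 4000.0), 0.25)
        _, truth = gc.simulate_session(cfg)
        fx = truth.planted_fixations
        inside = fx[(fx["start_ms"] >= 2000.0) & (fx["start_ms"] < 4000.0)]
        outside = fx[(fx["start_ms"] < 2000.0) | (fx["start_ms"] >= 4000.0)]
        for grp, p in ((inside, 0.75), (outside, 0.5)):
            frac = (grp["target_aoi"] == "lower").mean()
            lo, hi = binomial_ci99(p, len(grp))
            assert lo <= frac <= hi


def test_invalid_configs_rejected():
    with pytest.raises(gc.ConfigError):
        gc.SimConfig(trackloss_rate=1.5).validate()
    with pytest.raises(gc.ConfigError):
        gc.SimConfig(trial_duration_ms=-1).validate()
    with pytest.raises(gc.ConfigError):
        gc.SimConfig(bias_profile=gc.BiasProfile(baseline=1.2)).validate()


def test_eight_stimulus_movies():
    ids = all_stimulus_ids()
    assert len(ids) == 8 and len(set(ids)) == 8
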