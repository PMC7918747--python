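"""I-DT detector, AOI labelling, and exclusion-rule behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gazecourse as gc
from gazecourse.aoi import AOI_LOWER, AOI_NONE, AOI_UPPER, DynamicAOIPair
from oracles import brute_dispersion, idt_oracle

PERIOD = 1000.0 / 120.0


def grid(n):
    return np.arange(n) * PERIOD


def static_aois(cx=840.0, cy=450.0, w=568.0, h=302.0, until=7500.0):
    upper = np.array([[cx - w / 2, cy - h, cx + w / 2, cy]])
    lower = np.array([[cx - w / 2, cy, cx + w / 2, cy + h]])
    return DynamicAOIPair(np.array([0.0]), upper, lower, valid_until_ms=until)


class TestDispersion:
    def test_identical_points_zero(self):
        assert gc.dispersion([5.0] * 4, [7.0] * 4) == 0.0

    def test_two_point_arithmetic(self):
        assert gc.dispersion([0.0, 30.0], [0.0, 40.0]) == 70.0

    def test_random_clouds_match_extrema_recomputation(self, rng):
        for _ in range(30):
            x = rng.normal(size=20) * 50
            y = rng.normal(size=20) * 50
            assert gc.dispersion(x, y) == pytest.approx(brute_dispersion(x, y))

    def test_empty_rejected(self):
        with pytest.raises(gc.DataError):
            gc.dispersion([], [])


class TestDetector:
    def test_single_point_fixation(self):
        t = grid(60)
        x = np.full(60, 100.0)
        y = np.full(60, 200.0)
        fixes = gc.detect_fixations(t, x, y)
        assert len(fixes) == 1
        fx = fixes[0]
        assert fx.duration_ms == pytest.approx(500.0)
        assert (fx.centroid_x, fx.centroid_y) == (100.0, 200.0)
        assert fx.index == 1

    def test_sixtysix_ms_window_not_a_fixation(self):
        # 8 stable samples (~66 ms) between two distant stable positions:
        # the middle stretch is below the 80 ms minimum.
        t = grid(48)
        x = np.concatenate([np.full(20, 100.0), np.full(8, 600.0), np.full(20, 1100.0)])
        y = np.full(48, 500.0)
        fixes = gc.detect_fixations(t, x, y)
        assert len(fixes) == 2
        assert not any(abs(f.centroid_x - 600.0) < 100 for f in fixes)

    def test_empty_input(self):
        assert gc.detect_fixations([], [], []) == []

    def test_unordered_timestamps_rejected(self):
        with pytest.raises(gc.DataError):
            gc.detect_fixations([0.0, 10.0, 5.0], [0, 0, 0], [0, 0, 0])

    def test_trackloss_breaks_windows(self):
        t = grid(40)
        x = np.full(40, 100.0)
        y = np.full(40, 100.0)
        valid = np.ones(40, bool)
        valid[20] = False  # single lost sample splits the stable stretch
        fixes = gc.detect_fixations(t, x, y, valid)
        assert len(fixes) == 2
        assert fixes[0].end_ms <= t[20]
        assert fixes[1].start_ms >= t[21]

    def test_outputs_satisfy_thresholds_and_do_not_overlap(self, processed):
        _, fixations, _, _ = processed
        assert (fixations["duration_ms"] >= 80.0 - 1e-9).all()
        for _, grp in fixations.groupby(["subject_id", "trial_number"]):
            grp = grp.sort_values("start_ms")
            assert (grp["end_ms"].to_numpy()[:-1] <= grp["start_ms"].to_numpy()[1:] + 1e-9).all()
            assert list(grp["fixation_index"]) == list(range(1, len(grp) + 1))


def random_gaze_instance(rng, n_max=300):
    """Random mixture of stable platforms, drifts and noise, with track loss."""
    n = int(rng.integers(20, n_max + 1))
    t = grid(n)
    x = np.empty(n)
    y = np.empty(n)
    i = 0
    px, py = rng.uniform(0, 1600), rng.uniform(0, 1000)
    while i < n:
        seg = int(rng.integers(3, 40))
        kind = rng.random()
        if kind < 0.5:  # stable platform with jitter
            sd = rng.uniform(0, 30)
            x[i : i + seg] = px + rng.normal(0, sd, size=min(seg, n - i))
            y[i : i + seg] = py + rng.normal(0, sd, size=min(seg, n - i))
        else:  # jump + drift
            px, py = rng.uniform(0, 1600), rng.uniform(0, 1000)
            x[i : i + seg] = px + np.linspace(0, rng.uniform(-200, 200), min(seg, n - i))
            y[i : i + seg] = py + np.linspace(0, rng.uniform(-200, 200), min(seg, n - i))
        i += seg
    valid = rng.random(n) > 0.1
    return t, x, y, valid


class TestDetectorEqualsOracle:
    def test_random_instances_match_brute_force(self, rng):
        cfg = gc.DetectorConfig()
        for _ in range(40):
            t, x, y, valid = random_gaze_instance(rng)
            got = gc.detect_fixations(t, x, y, valid, cfg)
            want = idt_oracle(t, x, y, valid, cfg.min_duration_ms, cfg.max_dispersion_px)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g.start_ms == pytest.approx(w["start_ms"])
                assert g.end_ms == pytest.approx(w["end_ms"])
                assert g.centroid_x == pytest.approx(w["centroid_x"])
                assert g.n_samples == w["n_samples"]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**9), st.floats(40.0, 160.0), st.floats(30.0, 200.0))
    def test_property_random_thresholds(self, seed, min_dur, max_disp):
        rng = np.random.default_rng(seed)
        cfg = gc.DetectorConfig(min_duration_ms=min_dur, max_dispersion_px=max_disp)
        t, x, y, valid = random_gaze_instance(rng, n_max=150)
        got = gc.detect_fixations(t, x, y, valid, cfg)
        want = idt_oracle(t, x, y, valid, min_dur, max_disp)
        assert [(g.start_ms, g.end_ms) for g in got] == pytest.approx(
            [(w["start_ms"], w["end_ms"]) for w in want]
        )


class TestSampleAOI:
    def test_center_of_lower_rect(self):
        aois = static_aois()
        assert gc.assign_sample_aoi(100.0, 840.0, 600.0, aois) == "lower"
        assert gc.assign_sample_aoi(100.0, 840.0, 300.0, aois) == "upper"
        assert gc.assign_sample_aoi(100.0, 10.0, 10.0, aois) == "none"

    def test_shared_boundary_belongs_to_upper(self):
        aois = static_aois(cy=450.0)
        assert gc.assign_sample_aoi(0.0, 840.0, 450.0, aois) == "upper"

    def test_labels_flip_when_face_moves(self):
        # Same screen point before/after the face shifts by one AOI height,
        # so the upper rectangle comes to cover what the lower one did.
        h = 302.0
        times = np.array([0.0, 1000.0])
        upper = np.array([[556.0, 148.0, 1124.0, 450.0], [556.0, 148.0 + h, 1124.0, 450.0 + h]])
        lower = upper.copy()
        lower[:, 1] += h
        lower[:, 3] += h
        aois = DynamicAOIPair(times, upper, lower, valid_until_ms=2000.0)
        x, y = 840.0, 600.0  # centre of the initial lower rect
        assert gc.assign_sample_aoi(500.0, x, y, aois) == "lower"
        assert gc.assign_sample_aoi(1500.0, x, y, aois) == "upper"

    def test_lookup_outside_coverage_rejected(self):
        aois = static_aois(until=1000.0)
        with pytest.raises(gc.DataError):
            gc.assign_sample_aoi(1500.0, 840.0, 600.0, aois)

    def test_labels_partition_valid_samples(self, processed):
        _, _, labeled, _ = processed
        assert set(labeled["aoi"]) <= {"upper", "lower", "none"}
        assert (labeled.loc[labeled["valid"] == 0, "aoi"] == "none").all()


class TestFixationAOI:
    def make_fix(self, n):
        return gc.Fixation(0.0, n * PERIOD, 0.0, 0.0, 1, n_samples=n,
                           sample_indices=np.arange(n))

    def test_unanimous(self):
        codes = np.full(10, AOI_LOWER)
        assert gc.assign_fixation_aoi(self.make_fix(10), codes) == "lower"

    def test_majority(self):
        codes = np.array([AOI_LOWER] * 6 + [AOI_UPPER] * 4)
        assert gc.assign_fixation_aoi(self.make_fix(10), codes) == "lower"

    def test_tie_goes_to_first_in_aoi_sample(self):
        codes = np.array([AOI_NONE, AOI_UPPER, AOI_LOWER, AOI_UPPER, AOI_LOWER])
        assert gc.assign_fixation_aoi(self.make_fix(5), codes) == "upper"

    def test_majority_none_is_none(self):
        codes = np.array([AOI_NONE] * 6 + [AOI_LOWER] * 4)
        assert gc.assign_fixation_aoi(self.make_fix(10), codes) == "none"

    def test_all_out_of_aoi_is_none(self):
        codes = np.full(4, AOI_NONE)
        assert gc.assign_fixation_aoi(self.make_fix(4), codes) == "none"


class TestTrialExclusion:
    def make_trial(self, total_ms, n=2):
        rows = [gc.Fixation(0.0, total_ms / n, 0, 0, i + 1) for i in range(n)]
        for i, f in enumerate(rows):
            f.start_ms = i * total_ms / n
            f.end_ms = (i + 1) * total_ms / n
        return rows

    def test_just_below_threshold_dropped(self):
        assert gc.apply_trial_exclusion(self.make_trial(999.0)) is False

    def test_exact_threshold_kept(self):
        assert gc.apply_trial_exclusion(self.make_trial(1000.0)) is True

    def test_typical_trial_kept(self):
        assert gc.apply_trial_exclusion(self.make_trial(5876.70)) is True

    def test_exclusion_is_per_trial_pure(self, processed, conftest=None):
        _, fixations, _, _ = processed
        kept_all, audit_all = gc.apply_exclusions(fixations)
        # dropping one subject's rows leaves every other trial's outcome intact
        subset = fixations[fixations["subject_id"] != "s001"]
        kept_sub, audit_sub = gc.apply_exclusions(subset)
        merged = audit_all.merge(audit_sub, on=["subject_id", "trial_number"],
                                 suffixes=("_all", "_sub"))
        assert (merged["kept_all"] == merged["kept_sub"]).all()
        assert (merged["total_looking_ms_all"] == merged["total_looking_ms_sub"]).all()


class TestRoundTrip:
    def test_planted_fixations_recovered_without_trackloss(self):
        cfg = gc.SimConfig(n_subjects=3, trackloss_rate=0.0, seed=17)
        samples, truth = gc.simulate_session(cfg)
        fixations, _ = gc.process_samples(samples, truth.aoi_trajectories)
        period = cfg.sample_period_ms
        planted = truth.planted_fixations
        planted = planted[planted["end_ms"] - planted["start_ms"] >= 120.0]
        recovered = 0
        for _, row in planted.iterrows():
            cand = fixations[
                (fixations["subject_id"] == row["subject_id"])
                & (fixations["trial_number"] == row["trial_number"])
                & (abs(fixations["start_ms"] - row["start_ms"]) <= 2 * period)
                & (abs(fixations["end_ms"] - row["end_ms"]) <= 2 * period)
            ]
            recovered += len(cand) > 0
        assert recovered / len(planted) >= 0.95
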