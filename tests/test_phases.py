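"""Landmark detection and phase segmentation of the J-shaped trajectory."""

import itertools
import math

import numpy as np
import pytest

from glidekin import (PhaseLandmarks, PipelineConfig, analyze_trial,
                      detect_landmarks, glide_initiation_landmark,
                      kinematic_series, segment_phases, terminal_speed_landmark)
from glidekin.kinematics import KinematicSeries, noise_matched_tolerance
from glidekin.records import GRAVITY
from glidekin.simulate import add_tracking_noise, drag_only_trial, make_cohort


def synthetic_kin(t, uz=None, ax=None, z=None):
    """Hand-built kinematic series for landmark contract tests (cm units)."""
    n = t.size
    uz = np.zeros(n) if uz is None else np.asarray(uz, float)
    ax = np.zeros(n) if ax is None else np.asarray(ax, float)
    z = -np.cumsum(uz) * np.median(np.diff(t)) if z is None else z
    vel = np.column_stack([np.ones(n), -uz])
    acc = np.column_stack([ax, np.zeros(n)])
    com = np.column_stack([np.zeros(n), z])
    speed = np.hypot(vel[:, 0], vel[:, 1])
    theta = np.degrees(np.arctan2(uz, vel[:, 0]))
    valid = np.ones(n, bool)
    valid[:2] = valid[-2:] = False
    return KinematicSeries("synthetic", t, com, vel, acc, speed, uz, theta,
                           np.zeros(n), theta, valid)


class TestTerminalSpeedLandmark:
    def test_drag_only_fall_matches_closed_form_time(self, young_morph):
        trial, fall = drag_only_trial(young_morph, duration=1.5)
        kin = kinematic_series(trial, PipelineConfig(smoothing_tolerance=0.0))
        uz_max, t_ts, h_ts = terminal_speed_landmark(kin, 0.95)
        # 95% of the trial maximum is crossed within one sample of the
        # analytic time for 95% of the asymptotic terminal speed
        t_analytic = (fall.terminal_speed / GRAVITY) * math.atanh(
            0.95 * uz_max / 100.0 / fall.terminal_speed)
        assert abs(t_ts - t_analytic) <= 0.02 + 1e-9
        assert h_ts == pytest.approx(-(fall.z_m[int(round(t_ts * 50))]) * 100, abs=0.5)

    def test_first_crossing_semantics_on_monotone_series(self):
        t = np.arange(30) / 50
        uz = np.linspace(0, 100, 30)
        kin = synthetic_kin(t, uz=uz)
        uz_max, t_ts, _ = terminal_speed_landmark(kin, 0.95)
        valid_uz = np.where(kin.valid, uz, np.nan)
        expected_i = np.flatnonzero(valid_uz >= 0.95 * np.nanmax(valid_uz))[0]
        assert t_ts == pytest.approx(t[expected_i])

    def test_constant_descent_crosses_at_first_valid_sample(self):
        t = np.arange(30) / 50
        kin = synthetic_kin(t, uz=np.full(30, 50.0))
        _, t_ts, _ = terminal_speed_landmark(kin, 0.95)
        assert t_ts == pytest.approx(t[2])  # first non-edge sample

    def test_ascending_trial_yields_null_with_warning(self):
        t = np.arange(30) / 50
        kin = synthetic_kin(t, uz=np.full(30, -10.0))
        with pytest.warns(UserWarning, match="never positive"):
            uz_max, t_ts, h = terminal_speed_landmark(kin, 0.95)
        assert uz_max is None and t_ts is None and h is None


class TestGlideInitiationLandmark:
    def test_drag_only_fall_has_no_initiation(self, young_morph):
        trial, _ = drag_only_trial(young_morph, duration=1.5)
        kin = kinematic_series(trial, PipelineConfig(smoothing_tolerance=0.0))
        with pytest.warns(UserWarning, match="no glide initiation"):
            t_gi, ax, h = glide_initiation_landmark(kin, None)
        assert t_gi is None and ax is None and h is None

    def test_peak_near_generator_switch(self, std_pair, std_analysis):
        _, truth = std_pair
        t_gi = std_analysis.landmarks.t_glide_init
        # a_x peaks within 0.06 s of the truth-trajectory a_x maximum
        ax_true = truth.a_air[:, 0]
        t_true = truth.t[np.argmax(ax_true)]
        assert abs(t_gi - t_true) <= 0.06

    def test_exact_tie_breaks_to_earlier_time(self):
        t = np.arange(30) / 50
        ax = np.zeros(30)
        ax[[10, 20]] = 5.0
        kin = synthetic_kin(t, uz=np.full(30, 50.0), ax=ax)
        t_gi, ax_pk, _ = glide_initiation_landmark(kin, None)
        assert t_gi == pytest.approx(t[10])

    def test_search_starts_at_terminal_landmark(self):
        t = np.arange(50) / 50
        ax = np.zeros(50)
        ax[5] = 9.0   # pre-terminal artifact
        ax[30] = 5.0
        kin = synthetic_kin(t, uz=np.full(50, 50.0), ax=ax)
        t_gi, _, _ = glide_initiation_landmark(kin, search_start=0.2)
        assert t_gi == pytest.approx(t[30])


class TestSegmentation:
    def test_standard_trial_phases_in_order(self, std_analysis):
        labels = std_analysis.landmarks.phase_labels
        order = [k for k, _ in itertools.groupby(labels)]
        assert order == ["pre-terminal", "parachuting", "initiation", "gliding"]

    def test_terminal_always_precedes_initiation(self, std_analysis):
        lm = std_analysis.landmarks
        assert lm.t_terminal < lm.t_glide_init

    def test_null_initiation_leaves_parachuting_after_terminal(self, young_morph):
        trial, _ = drag_only_trial(young_morph, duration=1.5)
        kin = kinematic_series(trial, PipelineConfig(smoothing_tolerance=0.0))
        with pytest.warns(UserWarning):
            lm = detect_landmarks(kin)
        labels = lm.phase_labels
        after = kin.t > lm.t_terminal
        assert set(labels[after]) == {"parachuting"}
        assert lm.t_glide_init is None

    def test_landing_stats_match_configured_steady_glide(self, std_analysis, std_truth):
        landing = std_analysis.landmarks.landing
        assert landing["mean_glide_angle_deg"] == pytest.approx(
            std_truth.theta_star_deg, abs=0.5)

    def test_height_losses_nonnegative_and_ordered(self, std_analysis):
        lm = std_analysis.landmarks
        assert 0 <= lm.height_loss_at_terminal <= lm.height_loss_at_glide_init


class TestLandmarkRobustness:
    def test_t_gi_stable_under_tracking_noise(self, std_pair, std_analysis):
        """sigma = 0.3 cm digitisation noise moves t_GI by <= 3 samples."""
        trial, _ = std_pair
        t_gi0 = std_analysis.landmarks.t_glide_init
        tol = noise_matched_tolerance(trial.n_samples, 0.3)
        cfg = PipelineConfig(smoothing_tolerance=tol)
        hits = 0
        n_rep = 100
        for k in range(n_rep):
            noisy = add_tracking_noise(trial, 0.3, seed=20_000 + k)
            lm = detect_landmarks(kinematic_series(noisy, cfg), cfg)
            if lm.t_glide_init is not None and abs(lm.t_glide_init - t_gi0) <= 0.06 + 1e-9:
                hits += 1
        assert hits >= 95

    def test_cohort_landmarks_ordered_by_wing_loading(self):
        pairs = make_cohort(n_per_group=3, seed=11, noise_sigma_cm=0.3)
        by_group: dict = {}
        for trial, _ in pairs:
            cfg = PipelineConfig(
                smoothing_tolerance=noise_matched_tolerance(trial.n_samples, 0.3))
            lm = detect_landmarks(kinematic_series(trial, cfg), cfg)
            g = by_group.setdefault(trial.morph.age_group, {"uz": [], "t": [], "h": []})
            g["uz"].append(lm.uz_max)
            g["t"].append(lm.t_terminal)
            g["h"].append(lm.height_loss_at_terminal)
        groups = ["0-DAH", "5-DAH", "9-DAH", "15-DAH"]
        for key in ("uz", "t", "h"):
            means = [np.mean(by_group[g][key]) for g in groups]
            assert np.all(np.diff(means) >= 0), (key, means)
        for trial, truth in pairs:
            if truth.switch_time is None:
                continue
            cfg = PipelineConfig(
                smoothing_tolerance=noise_matched_tolerance(trial.n_samples, 0.3))
            lm = detect_landmarks(kinematic_series(trial, cfg), cfg)
            if lm.t_terminal is not None and lm.t_glide_init is not None:
                assert lm.t_terminal < lm.t_glide_init
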