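"""Simulator physics: closed forms, equilibria, cohorts, noise, determinism."""

import math

import numpy as np
import pytest

from glidekin import ValidationError
from glidekin import io as gio
from glidekin.records import AIR_DENSITY, GRAVITY, MorphRecord
from glidekin.simulate import (AeroModel, PostureState, SimConfig,
                               add_tracking_noise, aero_model_for_steady_glide,
                               default_sim_config, drag_only_trial, make_cohort,
                               simulate_drag_only_cylinder, simulate_glide,
                               tune_pitch_dynamics)


def drag_only_config(morph, c_d=1.0, v0=0.2, duration=1.5):
    """Two-posture config degenerated to a lift-free vertical fall."""
    aero = AeroModel(cd0=c_d, cd1=0.0, cl1=0.0, lift_scale=0.0)
    km, c, inertia = tune_pitch_dynamics(morph, AeroModel(), f_n_hz=4.7, zeta=0.23)
    post = PostureState(90.0, km, c)
    return SimConfig(morph=morph, aero=aero, parachute=post, glide=post,
                     pitch_inertia_I=inertia, switch_trigger=("none",),
                     initial_state=(0.0, 0.0, 0.0, -v0, 0.0, 0.0),
                     duration=duration)


class TestDragOnlyReference:
    def test_terminal_speed_of_hatchling_cylinder(self, young_morph):
        fall = simulate_drag_only_cylinder(young_morph, c_d=1.0)
        expected = math.sqrt(2 * 22.7e-6 * GRAVITY / (AIR_DENSITY * 1.0 * 66.1e-6))
        assert fall.terminal_speed == pytest.approx(expected, rel=1e-12)
        assert fall.terminal_speed == pytest.approx(2.37, abs=0.01)

    def test_time_to_95_percent_terminal(self, young_morph):
        fall = simulate_drag_only_cylinder(young_morph, c_d=1.0)
        vt = fall.terminal_speed
        t95 = fall.time_to_fraction(0.95)
        assert t95 == pytest.approx((vt / GRAVITY) * math.atanh(0.95), rel=1e-12)
        # for v_t = 2.4 m/s the closed form gives ~0.448 s
        fall24 = simulate_drag_only_cylinder(
            MorphRecord(mass_mg=22.7, body_length_mm=20.0,
                        planform_area_mm2=66.1 * (fall.terminal_speed / 2.4) ** 2),
            c_d=1.0)
        assert fall24.time_to_fraction(0.95) == pytest.approx(0.448, abs=0.002)

    def test_doubling_drag_scales_terminal_by_inv_sqrt2(self, young_morph):
        v1 = simulate_drag_only_cylinder(young_morph, c_d=1.0).terminal_speed
        v2 = simulate_drag_only_cylinder(young_morph, c_d=2.0).terminal_speed
        assert v2 == pytest.approx(v1 / math.sqrt(2), rel=1e-12)

    def test_ode_fall_matches_tanh_closed_form(self, young_morph):
        cfg = drag_only_config(young_morph, v0=0.2)
        _, truth = simulate_glide(cfg)
        fall = simulate_drag_only_cylinder(young_morph, 1.0, duration=cfg.duration,
                                           v0=0.2)
        assert np.max(np.abs(-truth.vel_xy[:, 1] - fall.descent_speed)) < 1e-6
        assert np.max(np.abs(truth.com_xy_m[:, 1] - fall.z_m)) < 1e-6

    def test_parachute_limit_no_horizontal_drift(self, young_morph):
        _, truth = simulate_glide(drag_only_config(young_morph))
        assert np.max(np.abs(truth.com_xy_m[:, 0])) < 1e-10

    def test_energy_nonincreasing_in_drag_only_fall(self, young_morph):
        fall = simulate_drag_only_cylinder(young_morph, 1.0)
        energy = 0.5 * fall.descent_speed ** 2 + GRAVITY * fall.z_m
        assert np.all(np.diff(energy) <= 1e-12)


class TestSteadyGlide:
    def test_trim_solver_hits_requested_landing_state(self, young_morph):
        aero = aero_model_for_steady_glide(70.8, 2.376, young_morph,
                                           alpha_trim_glide_deg=67.8, cd0=0.4)
        a = math.radians(67.8)
        assert math.degrees(math.atan2(aero.cd(a), aero.cl(a))) == pytest.approx(70.8, abs=1e-9)

    def test_glide_angle_from_drag_lift_ratio(self):
        # C_D/C_L = 2.87 at trim corresponds to a 70.8 deg glide
        assert math.degrees(math.atan(2.87)) == pytest.approx(70.8, abs=0.05)
        cfg = default_sim_config(seed=0)
        theta_star, u_star = cfg.steady_glide()
        assert theta_star == pytest.approx(70.8, abs=1e-9)
        assert u_star == pytest.approx(2.376, abs=1e-9)

    def test_trajectory_converges_to_steady_glide(self, std_truth):
        tail = std_truth.t >= std_truth.t[-1] - 0.2
        assert np.nanmean(std_truth.theta_deg[tail]) == pytest.approx(70.8, abs=0.05)
        speed = np.hypot(std_truth.vel_xy[tail, 0], std_truth.vel_xy[tail, 1])
        assert speed.mean() * 100 == pytest.approx(237.6, abs=0.5)

    def test_pitch_settles_at_glide_posture(self, std_truth):
        tail = std_truth.t >= std_truth.t[-1] - 0.2
        # equilibrium pitch = theta* - alpha_trim = 70.8 - 67.8 = -3.0 deg
        assert np.mean(std_truth.beta_deg[tail]) == pytest.approx(-3.0, abs=0.1)

    def test_switch_produces_decaying_nose_down_oscillation(self, std_truth):
        after = std_truth.t > std_truth.switch_time
        beta = std_truth.beta_deg[after]
        assert beta.min() < -15.0  # deep nose-down excursion
        # full-cycle amplitudes (paired half-swings, drift-robust) decay
        dev = beta - beta[-10:].mean()
        extrema = np.flatnonzero(np.diff(np.sign(np.diff(dev)))) + 1
        swings = np.abs(np.diff(dev[extrema]))
        cycles = swings[:swings.size // 2 * 2].reshape(-1, 2).sum(axis=1) / 2
        big = cycles[cycles > 0.1]
        assert big.size >= 3 and np.all(np.diff(big) < 0)


class TestTruthInvariants:
    def test_drag_and_lift_directions_orthonormal(self, std_truth):
        dot = np.einsum("ij,ij->i", std_truth.n_drag, std_truth.n_lift)
        assert np.max(np.abs(dot)) < 1e-12
        assert np.allclose(np.linalg.norm(std_truth.n_drag, axis=1), 1.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(std_truth.n_lift, axis=1), 1.0, atol=1e-12)

    def test_angle_sum_identity_in_truth(self, std_truth):
        assert np.allclose(std_truth.alpha_deg,
                           std_truth.theta_deg + std_truth.beta_deg, atol=1e-12)

    def test_zero_initial_speed_rejected(self, young_morph):
        cfg = drag_only_config(young_morph, v0=0.0)
        from glidekin import IntegrationError
        with pytest.raises(IntegrationError, match="speed"):
            simulate_glide(cfg)


class TestCohort:
    def test_wing_loading_ratio_and_monotonicity(self):
        from glidekin.simulate import default_age_templates
        tpl = default_age_templates()
        loads = [m.wing_loading for m in tpl]
        assert np.all(np.diff(loads) > 0)
        assert loads[-1] / loads[0] == pytest.approx((66.2 / 72.1) / (22.7 / 66.1), rel=1e-9)
        assert loads[-1] / loads[0] == pytest.approx(2.67, abs=0.01)

    def test_equal_masses_give_equal_terminal_speeds(self, young_morph):
        v1 = simulate_drag_only_cylinder(young_morph, 1.0).terminal_speed
        v2 = simulate_drag_only_cylinder(
            MorphRecord(mass_mg=22.7, body_length_mm=25.0, planform_area_mm2=66.1,
                        age_group="x"), 1.0).terminal_speed
        assert v1 == v2

    def test_heavier_groups_have_larger_terminal_speed(self):
        pairs = make_cohort(n_per_group=1, seed=4, jitter_frac=0.0, noise_sigma_cm=0.0)
        vts = [truth.terminal_speed for _, truth in pairs]
        assert np.all(np.diff(vts) > 0)

    def test_cohort_reruns_byte_identical(self, tmp_path):
        outs = []
        for run in ("a", "b"):
            pairs = make_cohort(n_per_group=2, seed=5)
            d = tmp_path / run
            for trial, _ in pairs:
                gio.write_trial(trial, d)
            outs.append(sorted(p.read_bytes() for p in d.glob("*.csv")))
        assert outs[0] == outs[1]

    def test_n_per_group_validated(self):
        with pytest.raises(ValidationError):
            make_cohort(n_per_group=0)


class TestTrackingNoise:
    def test_zero_sigma_is_identity(self, std_trial):
        assert add_tracking_noise(std_trial, 0.0, seed=1) is std_trial

    def test_noise_sd_matches_requested_sigma(self, young_morph):
        trial, _ = drag_only_trial(young_morph, duration=9.98)  # 500 samples
        noisy = add_tracking_noise(trial, 0.3, seed=2)
        added = np.concatenate([(noisy.head_xy - trial.head_xy).ravel(),
                                (noisy.abd_xy - trial.abd_xy).ravel()])
        assert added.std() == pytest.approx(0.3, rel=0.1)

    def test_same_seed_reproduces_noise(self, std_trial):
        a = add_tracking_noise(std_trial, 0.3, seed=7)
        b = add_tracking_noise(std_trial, 0.3, seed=7)
        assert np.array_equal(a.head_xy, b.head_xy)

    def test_negative_sigma_rejected(self, std_trial):
        with pytest.raises(ValidationError):
            add_tracking_noise(std_trial, -0.1, seed=1)
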