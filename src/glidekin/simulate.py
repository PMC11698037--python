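"""Physics-based synthetic glide trials.

A falling first-instar nymph is modelled as a 2D point mass with
quasi-steady aerodynamics plus a single rotational degree of freedom (body
pitch).  The pitch dynamics implement the two-posture mechanism of glide
initiation: both the parachuting and the gliding posture are statically
stable (pitching-moment coefficient with negative slope in angle of attack),
and a rapid switch of the trim angle of attack from the high-AoA parachuting
trim to the low-AoA gliding trim produces a nose-down excursion followed by
a damped pitch oscillation, exactly the behaviour the analysis modules are
built to measure.

Equations of motion (state ``x, z, v_x, v_z, beta, betadot``; SI units,
angles in radians internally)::

    xdot  = v_x                 zdot = v_z
    theta = atan2(-v_z, v_x)    alpha = theta + beta
    q     = 0.5 * rho * |v|**2 * A
    a     = g + (q/m) * (C_D(alpha) * n_D + C_L(alpha) * n_L)
    I * betaddot = q * A * L * C_M(alpha; posture) - c * betadot

with ``n_D = -v_hat`` (drag opposes motion) and ``n_L`` perpendicular to the
velocity with non-negative vertical component during descent, so lift that
supports weight is positive.  ``C_M(alpha) = -k_m * (alpha - alpha_trim)``
for the active posture.

Every simulated trial carries its full per-sample ground truth so each
analysis stage can be checked against known values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, ValidationError
from .records import AIR_DENSITY, GRAVITY, MorphRecord, TrackedTrial

__all__ = [
    "AeroModel",
    "PostureState",
    "SimConfig",
    "GroundTruth",
    "DragOnlyFall",
    "simulate_glide",
    "simulate_drag_only_cylinder",
    "drag_only_trial",
    "make_cohort",
    "default_age_templates",
    "add_tracking_noise",
    "aero_model_for_steady_glide",
    "tune_pitch_dynamics",
    "default_sim_config",
    "pitch_step_response",
    "simulate_prescribed_ld_ramp",
]


# ---------------------------------------------------------------------------
# Aerodynamic and posture models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AeroModel:
    """Quasi-steady whole-body force coefficients versus angle of attack.

    The default parametric shapes are the standard blunt-body / flat-plate
    forms

    .. math::

        C_D(\\alpha) = C_{D0} + C_{D1} \\sin^2\\alpha, \\qquad
        C_L(\\alpha) = C_{L1} \\sin\\alpha \\cos\\alpha

    which give a drag-dominated, near-zero-lift regime at high AoA
    (parachuting) and a higher-lift regime at intermediate AoA (gliding).
    ``lift_scale`` multiplies the lift curve and setting it to zero yields a
    drag-only body (the physical reference model).
    """

    cd0: float = 0.10
    cd1: float = 1.20
    cl1: float = 0.70
    lift_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.cd0 <= 0:
            raise ValidationError(f"cd0 must be > 0 (C_D bounded below), got {self.cd0}")
        if self.cd1 < 0 or self.cl1 < 0 or self.lift_scale < 0:
            raise ValidationError("cd1, cl1 and lift_scale must be >= 0")

    def cd(self, alpha_rad):
        return self.cd0 + self.cd1 * np.sin(alpha_rad) ** 2

    def cl(self, alpha_rad):
        return self.lift_scale * self.cl1 * np.sin(alpha_rad) * np.cos(alpha_rad)


@dataclass(frozen=True)
class PostureState:
    """One statically stable pitch posture.

    The pitching-moment coefficient about the CoM is linear in AoA with a
    negative slope, vanishing at the trim angle:
    ``C_M(alpha) = -k_m (alpha - alpha_trim)`` with ``k_m > 0``.
    """

    trim_alpha_deg: float
    moment_slope_km: float
    pitch_damping_c: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.moment_slope_km <= 0:
            raise ValidationError("moment_slope_km must be > 0 (static stability)")
        if self.pitch_damping_c < 0:
            raise ValidationError("pitch_damping_c must be >= 0")

    def cm(self, alpha_rad):
        return -self.moment_slope_km * (alpha_rad - math.radians(self.trim_alpha_deg))


@dataclass
class SimConfig:
    """Full specification of one synthetic trial.

    ``switch_trigger`` selects when the parachute->glide posture switch
    happens: ``("time", t_s)`` for a fixed time, or
    ``("terminal_fraction", f)`` to switch when descent speed first reaches
    ``f`` times the analytic parachuting terminal speed.  ``initial_state``
    is ``(x_m, z_m, vx_m_s, vz_m_s, beta_deg, betadot_deg_s)``.
    """

    morph: MorphRecord
    aero: AeroModel
    parachute: PostureState
    glide: PostureState
    pitch_inertia_I: float
    air_density: float = AIR_DENSITY
    gravity: float = GRAVITY
    switch_trigger: tuple = ("terminal_fraction", 0.95)
    switch_ramp_s: float = 0.0
    initial_state: tuple = (0.0, 0.0, 0.05, -0.20, 0.0, 0.0)
    duration: float = 2.5
    stop_height_m: float | None = None
    sample_rate: float = 50.0
    noise_sigma_cm: float = 0.0
    seed: int = 0
    trial_id: str = "sim"

    def __post_init__(self) -> None:
        if self.pitch_inertia_I <= 0:
            raise ValidationError("pitch_inertia_I must be > 0")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValidationError("duration and sample_rate must be > 0")
        if self.noise_sigma_cm < 0:
            raise ValidationError("noise_sigma_cm must be >= 0")
        kind = self.switch_trigger[0]
        if kind not in ("time", "terminal_fraction", "none"):
            raise ValidationError(f"unknown switch trigger {kind!r}")
        if self.switch_ramp_s < 0:
            raise ValidationError("switch_ramp_s must be >= 0")

    # Analytic references ------------------------------------------------
    @property
    def terminal_speed_parachute(self) -> float:
        """Analytic terminal speed of the parachuting posture, m/s.

        Vertical force balance m g = 0.5 rho u^2 C_D A with C_D evaluated at
        the parachuting trim AoA (lift is negligible there by construction).
        """
        cd = float(self.aero.cd(math.radians(self.parachute.trim_alpha_deg)))
        return math.sqrt(2 * self.morph.mass_kg * self.gravity
                         / (self.air_density * cd * self.morph.planform_area_m2))

    def steady_glide(self) -> tuple[float, float]:
        """Equilibrium glide angle (deg below horizontal) and speed (m/s).

        At trim AoA of the gliding posture, tan(theta*) = C_D/C_L and the
        total aerodynamic force balances weight:
        0.5 rho u*^2 A sqrt(C_D^2 + C_L^2) = m g.
        """
        a = math.radians(self.glide.trim_alpha_deg)
        cd, cl = float(self.aero.cd(a)), float(self.aero.cl(a))
        if cl <= 0:
            theta = 90.0
        else:
            theta = math.degrees(math.atan2(cd, cl))
        ctot = math.hypot(cd, cl)
        u = math.sqrt(2 * self.morph.mass_kg * self.gravity
                      / (self.air_density * ctot * self.morph.planform_area_m2))
        return theta, u


@dataclass
class GroundTruth:
    """Per-sample true state of a simulated trial plus analytic constants.

    Linear quantities in SI (m, m/s, m/s^2); angles in degrees.
    """

    t: np.ndarray
    com_xy_m: np.ndarray
    vel_xy: np.ndarray
    beta_deg: np.ndarray
    theta_deg: np.ndarray
    alpha_deg: np.ndarray
    a_air: np.ndarray
    a_drag: np.ndarray
    a_lift: np.ndarray
    ld_ratio: np.ndarray
    n_drag: np.ndarray
    n_lift: np.ndarray
    switch_time: float | None
    terminal_speed: float
    theta_star_deg: float
    u_star: float
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _flow_frame(vx, vz):
    """Unit drag/lift directions for velocity (vx, vz).

    n_D = -v_hat; n_L = v_hat rotated +90 deg, sign-fixed so its vertical
    component is non-negative (lift supporting weight is positive during
    descent).
    """
    speed = math.hypot(vx, vz)
    if speed == 0.0:
        raise IntegrationError("zero speed: drag direction undefined")
    vhx, vhz = vx / speed, vz / speed
    ndx, ndz = -vhx, -vhz
    nlx, nlz = -vhz, vhx
    if nlz < 0:
        nlx, nlz = -nlx, -nlz
    return speed, (ndx, ndz), (nlx, nlz)


def _landmarks_from_com(com_xy_m: np.ndarray, beta_rad: np.ndarray, length_m: float):
    """Head/abdomen positions (cm) for a CoM track and pitch series."""
    half = 0.5 * length_m
    offset = half * np.column_stack([np.cos(beta_rad), np.sin(beta_rad)])
    head = (com_xy_m + offset) * 100.0
    abd = (com_xy_m - offset) * 100.0
    return head, abd


# ---------------------------------------------------------------------------
# Main simulator
# ---------------------------------------------------------------------------

def _rhs(cfg: SimConfig, posture: PostureState, trim_fn=None):
    """RHS of the 6-state dynamics for one posture.

    ``trim_fn(t)`` optionally overrides the posture's trim AoA (radians),
    used for a ramped posture switch.
    """
    m = cfg.morph.mass_kg
    A = cfg.morph.planform_area_m2
    L = cfg.morph.body_length_m
    rho, g, inertia = cfg.air_density, cfg.gravity, cfg.pitch_inertia_I
    trim_const = math.radians(posture.trim_alpha_deg)

    def fun(t, y):
        x, z, vx, vz, beta, betadot = y
        speed, (ndx, ndz), (nlx, nlz) = _flow_frame(vx, vz)
        theta = math.atan2(-vz, vx)
        alpha = theta + beta
        q = 0.5 * rho * speed * speed * A
        cd = cfg.aero.cd0 + cfg.aero.cd1 * math.sin(alpha) ** 2
        cl = cfg.aero.lift_scale * cfg.aero.cl1 * math.sin(alpha) * math.cos(alpha)
        ax = (q / m) * (cd * ndx + cl * nlx)
        az = -g + (q / m) * (cd * ndz + cl * nlz)
        trim = trim_fn(t) if trim_fn is not None else trim_const
        cm = -posture.moment_slope_km * (alpha - trim)
        betaddot = (q * L * cm - posture.pitch_damping_c * betadot) / inertia
        return (vx, vz, ax, az, betadot, betaddot)

    return fun


def _integrate(cfg: SimConfig, rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the two-phase dynamics.

    Returns ``(t_samples, states, t_switch, t_land)`` where ``t_land`` is
    the floor-crossing time (None if the trial runs to ``duration``).
    Event detection places the posture switch and the floor exactly; each
    phase is integrated separately so the switch discontinuity is never
    smeared by the adaptive integrator.
    """
    y0 = list(cfg.initial_state)
    y0[4] = math.radians(y0[4])
    y0[5] = math.radians(y0[5])
    if math.hypot(y0[2], y0[3]) == 0.0:
        raise IntegrationError("initial speed must be nonzero (drag direction undefined)")

    def make_floor():
        if cfg.stop_height_m is None:
            return None
        if cfg.stop_height_m <= 0:
            raise ValidationError("stop_height_m must be > 0")
        z0 = y0[1]

        def floor(t, y):
            return (y[1] - z0) + cfg.stop_height_m

        floor.terminal = True
        floor.direction = -1.0
        return floor

    kind = cfg.switch_trigger[0]
    events1 = []
    crossing = None
    if kind == "terminal_fraction":
        frac = float(cfg.switch_trigger[1])
        if not 0.0 < frac < 1.0:
            raise ValidationError("terminal_fraction trigger must be in (0, 1)")
        target = frac * cfg.terminal_speed_parachute

        def crossing(t, y):
            return (-y[3]) - target

        crossing.terminal = True
        crossing.direction = 1.0
        events1.append(crossing)
    floor = make_floor()
    if floor is not None:
        events1.append(floor)

    end1 = cfg.duration
    if kind == "time":
        end1 = float(cfg.switch_trigger[1])
        if not 0.0 < end1 < cfg.duration:
            raise ValidationError("fixed switch time must lie inside (0, duration)")

    sol1 = solve_ivp(_rhs(cfg, cfg.parachute), (0.0, end1), y0,
                     method="DOP853", rtol=rtol, atol=atol,
                     dense_output=True, events=events1 or None)
    if not sol1.success:
        raise IntegrationError(f"parachute-phase integration failed: {sol1.message}")

    t_switch: float | None = None
    t_land: float | None = None
    if kind == "time" and sol1.t[-1] >= end1:
        t_switch = end1
    if crossing is not None and sol1.t_events[0].size:
        t_switch = float(sol1.t_events[0][0])
    if floor is not None and sol1.t_events[len(events1) - 1].size:
        t_land = float(sol1.t_events[len(events1) - 1][0])
        t_switch = None  # hit the floor while still parachuting

    sol2 = None
    if t_switch is not None:
        y_sw = sol1.sol(t_switch)
        trim_fn = None
        if cfg.switch_ramp_s > 0:
            a0 = math.radians(cfg.parachute.trim_alpha_deg)
            a1 = math.radians(cfg.glide.trim_alpha_deg)
            t0, ramp = t_switch, cfg.switch_ramp_s

            def trim_fn(t, a0=a0, a1=a1, t0=t0, ramp=ramp):
                s = min(1.0, max(0.0, (t - t0) / ramp))
                return a0 + (a1 - a0) * s

        floor2 = make_floor()
        sol2 = solve_ivp(_rhs(cfg, cfg.glide, trim_fn), (t_switch, cfg.duration), y_sw,
                         method="DOP853", rtol=rtol, atol=atol, dense_output=True,
                         events=floor2)
        if not sol2.success:
            raise IntegrationError(f"glide-phase integration failed: {sol2.message}")
        if floor2 is not None and sol2.t_events[0].size:
            t_land = float(sol2.t_events[0][0])

    t_end = t_land if t_land is not None else cfg.duration
    n = int(math.floor(t_end * cfg.sample_rate + 1e-9)) + 1
    t_samples = np.arange(n) / cfg.sample_rate
    states = np.empty((6, n))
    if sol2 is None:
        states[:] = sol1.sol(t_samples)
    else:
        pre = t_samples <= t_switch
        if np.any(pre):
            states[:, pre] = sol1.sol(t_samples[pre])
        if np.any(~pre):
            states[:, ~pre] = sol2.sol(t_samples[~pre])
    if not np.all(np.isfinite(states)):
        bad = t_samples[~np.all(np.isfinite(states), axis=0)][0]
        raise IntegrationError(f"non-finite state at t={bad:.4f} s")
    return t_samples, states.T, t_switch, t_land


def _truth_from_states(cfg: SimConfig, t: np.ndarray, states: np.ndarray,
                       t_switch: float | None) -> GroundTruth:
    com = states[:, 0:2].copy()
    vel = states[:, 2:4].copy()
    beta = states[:, 4]
    n = t.size
    theta = np.degrees(np.arctan2(-vel[:, 1], vel[:, 0]))
    alpha = theta + np.degrees(beta)
    a_air = np.empty((n, 2))
    nd = np.empty((n, 2))
    nl = np.empty((n, 2))
    a_d = np.empty(n)
    a_l = np.empty(n)
    m = cfg.morph.mass_kg
    A = cfg.morph.planform_area_m2
    # aero coefficients depend on alpha only; the posture acts through C_M
    for i in range(n):
        speed, (ndx, ndz), (nlx, nlz) = _flow_frame(vel[i, 0], vel[i, 1])
        al_rad = math.radians(alpha[i])
        q = 0.5 * cfg.air_density * speed * speed * A
        a_d[i] = (q / m) * float(cfg.aero.cd(al_rad))
        a_l[i] = (q / m) * float(cfg.aero.cl(al_rad))
        nd[i] = (ndx, ndz)
        nl[i] = (nlx, nlz)
        a_air[i] = a_d[i] * nd[i] + a_l[i] * nl[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        ld = np.where(a_d > 0, a_l / a_d, np.nan)
    theta_star, u_star = cfg.steady_glide()
    return GroundTruth(
        t=t, com_xy_m=com, vel_xy=vel, beta_deg=np.degrees(beta),
        theta_deg=theta, alpha_deg=alpha, a_air=a_air, a_drag=a_d, a_lift=a_l,
        ld_ratio=ld, n_drag=nd, n_lift=nl, switch_time=t_switch,
        terminal_speed=cfg.terminal_speed_parachute,
        theta_star_deg=theta_star, u_star=u_star,
    )


def simulate_glide(cfg: SimConfig) -> tuple[TrackedTrial, GroundTruth]:
    """Simulate one trial; return the noisy tracked trial and its truth."""
    t, states, t_switch, t_land = _integrate(cfg)
    truth = _truth_from_states(cfg, t, states, t_switch)
    truth.extras["landing_time"] = t_land
    head, abd = _landmarks_from_com(truth.com_xy_m, np.radians(truth.beta_deg),
                                    cfg.morph.body_length_m)
    trial = TrackedTrial(
        trial_id=cfg.trial_id, t=t, head_xy=head, abd_xy=abd, morph=cfg.morph,
        meta={"seed": cfg.seed, "switch_time": t_switch, "landing_time": t_land,
              "noise_sigma_cm": 0.0, "sample_rate": cfg.sample_rate},
    )
    if cfg.noise_sigma_cm > 0:
        trial = add_tracking_noise(trial, cfg.noise_sigma_cm, cfg.seed)
    return trial, truth


# ---------------------------------------------------------------------------
# Drag-only reference model
# ---------------------------------------------------------------------------

@dataclass
class DragOnlyFall:
    """Closed-form vertical fall of a drag-only body (physical reference).

    m vdot = m g - 0.5 rho C_D A v^2 gives descent speed
    v(t) = v_t tanh(g t / v_t + atanh(v0 / v_t)) with terminal speed
    v_t = sqrt(2 m g / (rho C_D A)).
    """

    t: np.ndarray
    descent_speed: np.ndarray   # m/s, positive downward
    z_m: np.ndarray             # vertical position, m (starts at 0, decreases)
    terminal_speed: float

    def time_to_fraction(self, fraction: float, v0: float = 0.0) -> float:
        """Time at which descent speed first reaches ``fraction * v_t``."""
        if not 0.0 < fraction < 1.0:
            raise ValidationError("fraction must be in (0, 1)")
        vt, g = self.terminal_speed, GRAVITY
        return (vt / g) * (math.atanh(fraction) - math.atanh(v0 / vt))


def simulate_drag_only_cylinder(morph: MorphRecord, c_d: float = 1.0,
                                rho: float = AIR_DENSITY, g: float = GRAVITY,
                                duration: float = 2.5, sample_rate: float = 50.0,
                                v0: float = 0.0) -> DragOnlyFall:
    """Vertical fall of a cylinder with the insect's mass and planform area."""
    if c_d <= 0 or rho <= 0 or g <= 0:
        raise ValidationError("c_d, rho and g must all be > 0")
    vt = math.sqrt(2 * morph.mass_kg * g / (rho * c_d * morph.planform_area_m2))
    if not 0.0 <= v0 < vt:
        raise ValidationError("initial descent speed must satisfy 0 <= v0 < v_t")
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    phi0 = math.atanh(v0 / vt)
    arg = g * t / vt + phi0
    v = vt * np.tanh(arg)
    z = -(vt ** 2 / g) * (np.log(np.cosh(arg)) - math.log(math.cosh(phi0)))
    return DragOnlyFall(t=t, descent_speed=v, z_m=z, terminal_speed=vt)


def drag_only_trial(morph: MorphRecord, c_d: float = 1.0, *, trial_id: str = "cylinder",
                    duration: float = 1.5, sample_rate: float = 50.0,
                    v0: float = 0.0, noise_sigma_cm: float = 0.0,
                    seed: int = 0) -> tuple[TrackedTrial, DragOnlyFall]:
    """Drag-only fall packaged as a tracked trial (horizontal body, beta=0)."""
    fall = simulate_drag_only_cylinder(morph, c_d, duration=duration,
                                       sample_rate=sample_rate, v0=v0)
    com = np.column_stack([np.zeros_like(fall.t), fall.z_m])
    head, abd = _landmarks_from_com(com, np.zeros_like(fall.t), morph.body_length_m)
    trial = TrackedTrial(trial_id=trial_id, t=fall.t, head_xy=head, abd_xy=abd,
                         morph=morph, meta={"drag_only": True, "c_d": c_d})
    if noise_sigma_cm > 0:
        trial = add_tracking_noise(trial, noise_sigma_cm, seed)
    return trial, fall


# ---------------------------------------------------------------------------
# Tracking noise
# ---------------------------------------------------------------------------

def add_tracking_noise(trial: TrackedTrial, sigma_cm: float, seed: int) -> TrackedTrial:
    """Add i.i.d. Gaussian digitisation noise to both landmark tracks.

    ``sigma_cm`` is the per-coordinate standard deviation in cm, emulating
    video digitisation error at the few-pixels-per-cm calibration of the
    original recordings.
    """
    if sigma_cm < 0:
        raise ValidationError("noise sigma must be >= 0")
    if sigma_cm == 0:
        return trial
    rng = np.random.default_rng(seed)
    head = trial.head_xy + rng.normal(0.0, sigma_cm, trial.head_xy.shape)
    abd = trial.abd_xy + rng.normal(0.0, sigma_cm, trial.abd_xy.shape)
    return trial.with_tracks(head, abd, noise_sigma_cm=sigma_cm, noise_seed=seed)


# ---------------------------------------------------------------------------
# Configuration builders
# ---------------------------------------------------------------------------

def aero_model_for_steady_glide(theta_star_deg: float, u_star_m_s: float,
                                morph: MorphRecord, rho: float = AIR_DENSITY,
                                g: float = GRAVITY, alpha_trim_glide_deg: float = 50.0,
                                cd0: float = 0.10) -> AeroModel:
    """Coefficient curves whose glide trim matches a target steady glide.

    Solves the steady-glide force balance for the coefficient values needed
    at the gliding trim AoA — ``tan(theta*) = C_D/C_L`` together with
    ``0.5 rho u*^2 A sqrt(C_D^2+C_L^2) = m g`` — and fits the default
    parametric curve shapes through them.
    """
    if not 0.0 < theta_star_deg < 90.0:
        raise ValidationError("theta_star_deg must be in (0, 90)")
    if u_star_m_s <= 0:
        raise ValidationError("u_star_m_s must be > 0")
    th = math.radians(theta_star_deg)
    c_tot = 2 * morph.mass_kg * g / (rho * u_star_m_s ** 2 * morph.planform_area_m2)
    cd_req = c_tot * math.sin(th)
    cl_req = c_tot * math.cos(th)
    a = math.radians(alpha_trim_glide_deg)
    if cd_req <= cd0:
        raise ValidationError("requested glide C_D is below cd0; lower cd0")
    cd1 = (cd_req - cd0) / math.sin(a) ** 2
    cl1 = cl_req / (math.sin(a) * math.cos(a))
    return AeroModel(cd0=cd0, cd1=cd1, cl1=cl1)


def tune_pitch_dynamics(morph: MorphRecord, aero: AeroModel, *,
                        f_n_hz: float, zeta: float,
                        alpha_trim_glide_deg: float = 50.0,
                        rho: float = AIR_DENSITY, g: float = GRAVITY,
                        inertia: float | None = None):
    """Moment slope, damping and inertia giving a target pitch response.

    Linearising the pitch equation about the gliding trim (where dynamic
    pressure is the steady-glide value q*) gives a second-order system with
    ``omega_n^2 = q* A L k_m / I`` and ``2 zeta omega_n = c / I``.  The body
    is treated as a uniform rod, ``I = m L^2 / 12``, unless an inertia is
    supplied.

    Returns ``(k_m, c, I)``.
    """
    if f_n_hz <= 0:
        raise ValidationError("f_n_hz must be > 0")
    I = inertia if inertia is not None else morph.mass_kg * morph.body_length_m ** 2 / 12.0
    a = math.radians(alpha_trim_glide_deg)
    ctot = math.hypot(float(aero.cd(a)), float(aero.cl(a)))
    u_star = math.sqrt(2 * morph.mass_kg * g / (rho * ctot * morph.planform_area_m2))
    q_star_A = 0.5 * rho * u_star ** 2 * morph.planform_area_m2
    omega_n = 2 * math.pi * f_n_hz
    k_m = omega_n ** 2 * I / (q_star_A * morph.body_length_m)
    c = 2 * zeta * omega_n * I
    return k_m, c, I


#: Landing-state study conditions of the youngest (0-DAH) group: steady
#: glide angle 70.8 deg at 237.6 cm/s, pitch oscillation near 4.7 Hz with
#: damping ratio 0.23.  The gliding trim AoA of 67.8 deg makes the
#: equilibrium pitch theta* - alpha_trim = -3.0 deg, the observed
#: near-horizontal gliding posture, and together with a flat drag curve (high cd0) keeps the
#: drag curve flat enough between the two trims that the parachuting
#: terminal descent speed slightly exceeds the gliding one — so the
#: vertical speed peaks at the transition and decelerates afterwards, the
#: characteristic J-shape profile.
DEFAULT_CONDITIONS = {
    "mass_mg": 22.7, "body_length_mm": 20.0, "planform_area_mm2": 66.1,
    "theta_star_deg": 70.8, "u_star_cm_s": 237.6,
    "f_n_hz": 4.7, "zeta": 0.23,
    "alpha_trim_glide_deg": 67.8, "alpha_trim_parachute_deg": 88.0,
    "cd0": 0.4,
    "switch_fraction": 0.99, "switch_ramp_s": 0.16,
    "noise_sigma_cm": 0.3,
}


def default_sim_config(*, seed: int = 0, trial_id: str = "sim",
                       noise_sigma_cm: float = 0.0, duration: float = 2.5,
                       morph: MorphRecord | None = None,
                       aero: AeroModel | None = None,
                       theta_star_deg: float | None = None,
                       u_star_cm_s: float | None = None,
                       f_n_hz: float | None = None,
                       zeta: float | None = None,
                       switch_trigger: tuple | None = None) -> SimConfig:
    """Standard trial configuration emulating a young first-instar nymph.

    The defaults reproduce the landing state of the youngest age group: a
    steep steady glide (70.8 deg) at 237.6 cm/s with an underdamped pitch
    oscillation (4.7 Hz, damping ratio 0.23), reached after a near-
    equilibrium parachuting stretch.  The posture switch triggers at 99% of
    the parachuting terminal speed and ramps the trim AoA over 0.16 s (the
    leg-sweep posture change takes a finite time), which keeps the
    descent-speed overshoot small enough that terminal speed is attained
    during parachuting, a clear interval before glide initiation.
    """
    c = DEFAULT_CONDITIONS
    morph = morph or MorphRecord(mass_mg=c["mass_mg"], body_length_mm=c["body_length_mm"],
                                 planform_area_mm2=c["planform_area_mm2"], age_group="0-DAH")
    theta_star = theta_star_deg if theta_star_deg is not None else c["theta_star_deg"]
    u_star = (u_star_cm_s if u_star_cm_s is not None else c["u_star_cm_s"]) / 100.0
    f_n = f_n_hz if f_n_hz is not None else c["f_n_hz"]
    z = zeta if zeta is not None else c["zeta"]
    a_glide = c["alpha_trim_glide_deg"]
    if aero is None:
        aero = aero_model_for_steady_glide(theta_star, u_star, morph,
                                           alpha_trim_glide_deg=a_glide, cd0=c["cd0"])
    k_m, damp, inertia = tune_pitch_dynamics(morph, aero, f_n_hz=f_n, zeta=z,
                                             alpha_trim_glide_deg=a_glide)
    parachute = PostureState(trim_alpha_deg=c["alpha_trim_parachute_deg"],
                             moment_slope_km=k_m, pitch_damping_c=damp, label="parachute")
    glide = PostureState(trim_alpha_deg=a_glide, moment_slope_km=k_m,
                         pitch_damping_c=damp, label="glide")
    return SimConfig(
        morph=morph, aero=aero, parachute=parachute, glide=glide,
        pitch_inertia_I=inertia,
        switch_trigger=switch_trigger or ("terminal_fraction", c["switch_fraction"]),
        switch_ramp_s=c["switch_ramp_s"],
        duration=duration, noise_sigma_cm=noise_sigma_cm, seed=seed,
        trial_id=trial_id,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def default_age_templates() -> list[MorphRecord]:
    """Morphometric templates spanning the first instar.

    Endpoint masses (22.7 -> 66.2 mg) and planform areas (66.1 -> 72.1 mm²)
    follow the reported ontogenetic range; intermediate groups are linearly
    interpolated.  Body length grows ~20% over the instar.
    """
    ages = ["0-DAH", "5-DAH", "9-DAH", "15-DAH"]
    masses = np.linspace(22.7, 66.2, 4)
    areas = np.linspace(66.1, 72.1, 4)
    lengths = np.linspace(20.0, 24.0, 4)
    return [MorphRecord(mass_mg=float(m), body_length_mm=float(l),
                        planform_area_mm2=float(a), age_group=g)
            for m, l, a, g in zip(masses, lengths, areas, ages)]


def make_cohort(age_templates: list[MorphRecord] | None = None, n_per_group: int = 5,
                seed: int = 0, *, jitter_frac: float = 0.05,
                noise_sigma_cm: float = 0.3, duration: float = 2.5,
                stop_height_cm: float | None = 450.0,
                ) -> list[tuple[TrackedTrial, GroundTruth]]:
    """Simulate a cohort of trials across age groups.

    Each trial's individual draws mass and area with a small multiplicative
    jitter around its group template (5% by default), then runs the standard
    two-posture simulation.  Wing loading, and hence terminal speed, rises
    with age group by construction of the templates.  Trials end at the
    floor (``stop_height_cm`` below the release point, matching the several-
    metre under-canopy drop height of indoor trials) or at ``duration``, whichever comes
    first — so heavier groups, which burn more height before gliding,
    convert less of their descent into horizontal travel.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    if jitter_frac < 0:
        raise ValidationError("jitter_frac must be >= 0")
    templates = age_templates if age_templates is not None else default_age_templates()
    rng = np.random.default_rng(seed)
    # one aero model for the whole cohort (the animal's shape changes little
    # over the instar); morphology alone drives the speed differences
    shared_aero = aero_model_for_steady_glide(
        DEFAULT_CONDITIONS["theta_star_deg"], DEFAULT_CONDITIONS["u_star_cm_s"] / 100.0,
        templates[0], alpha_trim_glide_deg=DEFAULT_CONDITIONS["alpha_trim_glide_deg"],
        cd0=DEFAULT_CONDITIONS["cd0"])
    out: list[tuple[TrackedTrial, GroundTruth]] = []
    for gi, tpl in enumerate(templates):
        for k in range(n_per_group):
            jm = float(np.exp(rng.normal(0.0, jitter_frac)))
            ja = float(np.exp(rng.normal(0.0, jitter_frac)))
            morph = MorphRecord(mass_mg=tpl.mass_mg * jm,
                                body_length_mm=tpl.body_length_mm,
                                planform_area_mm2=tpl.planform_area_mm2 * ja,
                                age_group=tpl.age_group)
            trial_seed = int(rng.integers(0, 2**31 - 1))
            cfg = default_sim_config(
                seed=trial_seed, trial_id=f"{tpl.age_group}_{k:02d}",
                noise_sigma_cm=noise_sigma_cm, duration=duration, morph=morph,
                aero=shared_aero)
            if stop_height_cm is not None:
                cfg.stop_height_m = stop_height_cm / 100.0
            out.append(simulate_glide(cfg))
    return out


# ---------------------------------------------------------------------------
# Linear pitch response (oscillation-estimator ground truth)
# ---------------------------------------------------------------------------

def pitch_step_response(t: np.ndarray, *, zeta: float, f_n_hz: float | None = None,
                        f_d_hz: float | None = None, amplitude_deg: float = 20.0,
                        beta_eq_deg: float = 0.0, onset_s: float = 0.0,
                        noise_sigma_deg: float = 0.0, seed: int = 0) -> np.ndarray:
    """Underdamped linear second-order pitch response sampled at times ``t``.

    beta(t) = beta_eq + A exp(-zeta omega_n tau) cos(omega_d tau) for
    tau = t - onset >= 0 and beta_eq before the onset, with
    omega_d = omega_n sqrt(1 - zeta^2).  Specify either the undamped natural
    frequency ``f_n_hz`` or the observed oscillation (damped) frequency
    ``f_d_hz``.  A nonzero ``onset_s`` places the ring-down inside the
    analysis window the way a glide-initiation transient sits inside the
    window centred on it.  Gaussian angle noise emulates a pitch series
    derived from noisy landmark tracks.
    """
    if not 0.0 <= zeta < 1.0:
        raise ValidationError("zeta must be in [0, 1) for an oscillatory response")
    if (f_n_hz is None) == (f_d_hz is None):
        raise ValidationError("specify exactly one of f_n_hz or f_d_hz")
    if f_n_hz is None:
        f_n_hz = f_d_hz / math.sqrt(1.0 - zeta ** 2)
    omega_n = 2 * math.pi * f_n_hz
    omega_d = omega_n * math.sqrt(1.0 - zeta ** 2)
    t = np.asarray(t, dtype=float)
    tau = np.clip(t - onset_s, 0.0, None)
    beta = beta_eq_deg + np.where(
        t >= onset_s,
        amplitude_deg * np.exp(-zeta * omega_n * tau) * np.cos(omega_d * tau),
        0.0)
    if noise_sigma_deg > 0:
        rng = np.random.default_rng(seed)
        beta = beta + rng.normal(0.0, noise_sigma_deg, t.shape)
    return beta


# ---------------------------------------------------------------------------
# Prescribed lift-to-drag ramp (decomposition-recovery ground truth)
# ---------------------------------------------------------------------------

def simulate_prescribed_ld_ramp(*, ld_start: float = 0.16, ld_end: float = 0.48,
                                ramp_start: float = 0.5, ramp_duration: float = 0.16,
                                a_drag: float = 8.8, duration: float = 1.2,
                                sample_rate: float = 50.0,
                                initial_velocity=(0.3, -2.3),
                                morph: MorphRecord | None = None,
                                g: float = GRAVITY, trial_id: str = "ld_ramp",
                                ) -> tuple[TrackedTrial, GroundTruth]:
    """Trajectory with a prescribed aerodynamic L/D ramp.

    The aerodynamic acceleration is prescribed directly: drag magnitude
    ``a_drag`` (m/s²) along -v_hat and lift ``LD(t) * a_drag`` perpendicular
    to the velocity, where LD(t) holds at ``ld_start``, ramps linearly to
    ``ld_end`` over ``ramp_duration`` seconds starting at ``ramp_start``,
    and holds thereafter.  This isolates the acceleration-decomposition
    stage: the recovered L/D series should reproduce the prescribed ramp.
    """
    if a_drag <= 0:
        raise ValidationError("a_drag must be > 0")
    if ramp_start + ramp_duration >= duration:
        raise ValidationError("ramp must end before the trial does")
    morph = morph or MorphRecord(mass_mg=22.7, body_length_mm=20.0,
                                 planform_area_mm2=66.1, age_group="0-DAH")

    def ld_of_t(t):
        s = np.clip((t - ramp_start) / ramp_duration, 0.0, 1.0)
        return ld_start + (ld_end - ld_start) * s

    def fun(t, y):
        x, z, vx, vz = y
        _, (ndx, ndz), (nlx, nlz) = _flow_frame(vx, vz)
        al = float(ld_of_t(t)) * a_drag
        return (vx, vz,
                a_drag * ndx + al * nlx,
                -g + a_drag * ndz + al * nlz)

    y0 = (0.0, 0.0, float(initial_velocity[0]), float(initial_velocity[1]))
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    sol = solve_ivp(fun, (0.0, duration), y0, method="DOP853",
                    rtol=1e-10, atol=1e-12, dense_output=True)
    if not sol.success:
        raise IntegrationError(f"prescribed-ramp integration failed: {sol.message}")
    states = sol.sol(t).T
    com, vel = states[:, 0:2], states[:, 2:4]

    theta = np.degrees(np.arctan2(-vel[:, 1], vel[:, 0]))
    nd = np.empty((n, 2))
    nl = np.empty((n, 2))
    for i in range(n):
        _, (ndx, ndz), (nlx, nlz) = _flow_frame(vel[i, 0], vel[i, 1])
        nd[i] = (ndx, ndz)
        nl[i] = (nlx, nlz)
    ld = ld_of_t(t)
    a_d = np.full(n, a_drag)
    a_l = ld * a_drag
    a_air = a_d[:, None] * nd + a_l[:, None] * nl

    head, abd = _landmarks_from_com(com, np.zeros(n), morph.body_length_m)
    trial = TrackedTrial(trial_id=trial_id, t=t, head_xy=head, abd_xy=abd, morph=morph,
                         meta={"prescribed_ld": True,
                               "ramp_end_time": ramp_start + ramp_duration})
    truth = GroundTruth(
        t=t, com_xy_m=com, vel_xy=vel, beta_deg=np.zeros(n), theta_deg=theta,
        alpha_deg=theta, a_air=a_air, a_drag=a_d, a_lift=a_l, ld_ratio=ld,
        n_drag=nd, n_lift=nl, switch_time=None, terminal_speed=math.nan,
        theta_star_deg=math.nan, u_star=math.nan,
        extras={"ramp_start": ramp_start, "ramp_end": ramp_start + ramp_duration},
    )
    return trial, truth
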