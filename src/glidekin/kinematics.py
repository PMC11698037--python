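"""Smoothing and kinematic series: CoM, velocity, glide angle, pitch, AoA.

The tracked head and abdomen coordinates are smoothed per coordinate with a
quintic smoothing spline whose sum of squared residuals is bounded by a
tolerance (cm²), the 2D analogue of the classic tolerance-based spline
smoothing used for digitised kinematic data.  All derivatives (velocity,
acceleration, jerk) are taken analytically from the fitted splines rather
than by re-differencing, so no additional noise is injected.

Angle conventions (degrees at the interface, radians internally):

* glide angle ``theta``: angle of the velocity vector below the horizontal,
  ``theta = atan2(-v_z, v_x)``; 90 deg is a pure vertical fall.  Values
  above 90 deg (backward drift) and below 0 (ascent) are preserved, not
  clamped.
* body pitch ``beta``: head-to-abdomen axis relative to horizontal,
  positive nose-up.
* angle of attack ``alpha = theta + beta`` exactly, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .config import PipelineConfig
from .exceptions import ValidationError
from .records import TrackedTrial

__all__ = ["SmoothedTrack", "KinematicSeries", "smooth_positions", "compute_com",
           "kinematic_series", "noise_matched_tolerance"]


def noise_matched_tolerance(n_samples: int, sigma_cm: float) -> float:
    """Spline residual budget matched to a known tracking-noise level.

    The expected sum of squared residuals of the true trajectory under
    i.i.d. Gaussian noise of standard deviation ``sigma_cm`` is
    ``n * sigma**2``; using it as the smoothing tolerance gives the
    classic discrepancy-principle fit.  A tolerance far below it forces
    the spline to chase noise, which second derivatives amplify.
    """
    if sigma_cm < 0:
        raise ValidationError("sigma_cm must be >= 0")
    return n_samples * sigma_cm ** 2

#: Minimum speed (cm/s) below which the glide angle is undefined.
SPEED_FLOOR_CM_S = 1e-6

#: Spline order: quintic, so derivatives up to jerk are smooth.
_SPLINE_ORDER = 5


@dataclass
class SmoothedTrack:
    """Quintic smoothing splines for the head and abdomen coordinates.

    Each entry is a ``UnivariateSpline`` over time (s) of one coordinate in
    cm.  Splines expose analytic derivatives of any order up to 4.
    """

    t: np.ndarray
    head_x: UnivariateSpline
    head_z: UnivariateSpline
    abd_x: UnivariateSpline
    abd_z: UnivariateSpline
    tolerance: float

    def _eval(self, spline: UnivariateSpline, t: np.ndarray, derivative: int) -> np.ndarray:
        return spline.derivative(derivative)(t) if derivative else spline(t)

    def com(self, t: np.ndarray, derivative: int = 0) -> np.ndarray:
        """CoM (midpoint of head and abdomen) or its derivative, (n, 2) cm-based."""
        x = 0.5 * (self._eval(self.head_x, t, derivative) + self._eval(self.abd_x, t, derivative))
        z = 0.5 * (self._eval(self.head_z, t, derivative) + self._eval(self.abd_z, t, derivative))
        return np.column_stack([x, z])


def smooth_positions(trial: TrackedTrial, tolerance: float | None = None) -> SmoothedTrack:
    """Fit quintic smoothing splines to all four landmark coordinates.

    ``tolerance`` (cm²) bounds the sum of squared residuals of each
    coordinate's fit; ``0`` yields an interpolating spline.  Defaults to the
    pipeline default of 0.5 cm².
    """
    tol = 0.5 if tolerance is None else tolerance
    if tol < 0:
        raise ValidationError("smoothing tolerance must be >= 0")
    n = trial.n_samples
    if n <= _SPLINE_ORDER:
        raise ValidationError(f"quintic spline needs more than {_SPLINE_ORDER} samples, got {n}")

    def fit(y):
        return UnivariateSpline(trial.t, y, k=_SPLINE_ORDER, s=tol)

    return SmoothedTrack(
        t=trial.t,
        head_x=fit(trial.head_xy[:, 0]), head_z=fit(trial.head_xy[:, 1]),
        abd_x=fit(trial.abd_xy[:, 0]), abd_z=fit(trial.abd_xy[:, 1]),
        tolerance=tol,
    )


def compute_com(track: SmoothedTrack, t: np.ndarray | None = None,
                derivative: int = 0) -> np.ndarray:
    """CoM track (cm) from smoothed landmarks: midpoint of head and abdomen.

    Derivatives are inherited linearly from the landmark splines.
    """
    tt = track.t if t is None else np.asarray(t, dtype=float)
    return track.com(tt, derivative)


@dataclass
class KinematicSeries:
    """Per-sample kinematics of one trial.

    Positions cm, velocities cm/s, accelerations cm/s²; angles in degrees.
    ``descent_speed_uz = -v_z`` is positive downward.  ``valid`` flags the
    samples away from the spline edge region.
    """

    trial_id: str
    t: np.ndarray
    com_xy: np.ndarray
    vel_xy: np.ndarray
    acc_xy: np.ndarray
    speed_u: np.ndarray
    descent_speed_uz: np.ndarray
    glide_angle_theta: np.ndarray
    body_pitch_beta: np.ndarray
    aoa_alpha: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dt_nominal(self) -> float:
        return float(np.median(np.diff(self.t)))


def kinematic_series(trial: TrackedTrial, cfg: PipelineConfig | None = None,
                     track: SmoothedTrack | None = None) -> KinematicSeries:
    """Full kinematic series of a trial from its smoothed landmark tracks.

    Velocity and acceleration come from the spline's analytic first and
    second derivatives.  The glide angle is undefined (NaN) wherever the
    speed falls below ``SPEED_FLOOR_CM_S``.
    """
    cfg = cfg or PipelineConfig()
    if track is None:
        track = smooth_positions(trial, cfg.smoothing_tolerance)
    t = trial.t
    com = track.com(t)
    vel = track.com(t, 1)
    acc = track.com(t, 2)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    uz = -vel[:, 1]

    theta = np.degrees(np.arctan2(-vel[:, 1], vel[:, 0]))
    theta = np.where(speed < SPEED_FLOOR_CM_S, np.nan, theta)

    head = np.column_stack([track.head_x(t), track.head_z(t)])
    abd = np.column_stack([track.abd_x(t), track.abd_z(t)])
    beta = np.degrees(np.arctan2(head[:, 1] - abd[:, 1], head[:, 0] - abd[:, 0]))
    alpha = theta + beta

    valid = np.ones(t.size, dtype=bool)
    k = cfg.edge_samples
    if k > 0:
        valid[:k] = False
        valid[-k:] = False

    return KinematicSeries(
        trial_id=trial.trial_id, t=t, com_xy=com, vel_xy=vel, acc_xy=acc,
        speed_u=speed, descent_speed_uz=uz, glide_angle_theta=theta,
        body_pitch_beta=beta, aoa_alpha=alpha, valid=valid,
        meta={"smoothing_tolerance": track.tolerance, **trial.meta},
    )
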