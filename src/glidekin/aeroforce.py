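"""Lift/drag decomposition of the CoM acceleration.

Working in accelerations rather than forces makes trials of different mass
directly comparable and lets the lift-to-drag ratio be computed without
knowing mass (it cancels).  The total CoM acceleration is the vector sum of
the gravitational and aerodynamic accelerations,

.. math:: \\mathbf{a}_{tot} = \\mathbf{g} + \\mathbf{a}_{air},

so :math:`\\mathbf{a}_{air} = \\mathbf{a}_{tot} - \\mathbf{g}`.  Drag is the
projection of :math:`\\mathbf{a}_{air}` onto the unit vector opposing the
velocity, lift the projection onto its perpendicular:

.. math::

    a_D = \\mathbf{a}_{air} \\cdot \\hat{n}_D, \\qquad
    a_L = \\mathbf{a}_{air} \\cdot \\hat{n}_L,

with :math:`\\hat{n}_D = -\\hat{v}` and :math:`\\hat{n}_L` chosen with
non-negative vertical component during descent, so lift that supports
weight is positive.  All quantities here are SI (m/s², m/s³).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .kinematics import KinematicSeries, SmoothedTrack

__all__ = ["AeroSeries", "aero_acceleration", "decompose_lift_drag",
           "vertical_jerk", "aero_series"]

logger = logging.getLogger(__name__)

#: Minimum speed (m/s) for a defined flow direction.
SPEED_FLOOR_M_S = 1e-6


@dataclass
class AeroSeries:
    """Aerodynamic acceleration of one trial and its drag/lift split (SI)."""

    trial_id: str
    t: np.ndarray
    a_tot: np.ndarray        # (n, 2) m/s², includes gravity
    a_air: np.ndarray        # (n, 2) m/s², aerodynamic only
    a_drag: np.ndarray       # m/s², projection on n_D
    a_lift: np.ndarray       # m/s², projection on n_L
    n_drag: np.ndarray       # (n, 2) unit vectors
    n_lift: np.ndarray       # (n, 2) unit vectors
    ld_ratio: np.ndarray     # a_L / a_D, NaN where a_D <= 0 or speed undefined
    jerk_z: np.ndarray       # m/s³, vertical jerk
    meta: dict = field(default_factory=dict)


def aero_acceleration(a_tot: np.ndarray, g: float = 9.81) -> np.ndarray:
    """Aerodynamic acceleration: total minus gravity ``(0, -g)`` (z-up frame)."""
    a_tot = np.atleast_2d(np.asarray(a_tot, dtype=float))
    a_air = a_tot.copy()
    a_air[:, 1] += g
    return a_air


def decompose_lift_drag(a_air: np.ndarray, vel: np.ndarray):
    """Project the aerodynamic acceleration onto drag and lift directions.

    Parameters are ``(n, 2)`` arrays in consistent units (aero acceleration
    and velocity; only the velocity *direction* is used).  Returns
    ``(a_D, a_L, n_D, n_L, ld_ratio)``.  Samples with near-zero speed yield
    NaN components; samples with ``a_D <= 0`` (possible under noise) yield
    NaN ``ld_ratio`` and are counted in the log.
    """
    a_air = np.atleast_2d(np.asarray(a_air, dtype=float))
    vel = np.atleast_2d(np.asarray(vel, dtype=float))
    n = a_air.shape[0]
    speed = np.hypot(vel[:, 0], vel[:, 1])
    ok = speed > SPEED_FLOOR_M_S

    n_d = np.full((n, 2), np.nan)
    n_l = np.full((n, 2), np.nan)
    vhat = vel[ok] / speed[ok, None]
    n_d[ok] = -vhat
    # +90 deg rotation of v_hat; flip where the vertical component is negative
    rot = np.column_stack([-vhat[:, 1], vhat[:, 0]])
    flip = rot[:, 1] < 0
    rot[flip] *= -1.0
    n_l[ok] = rot

    a_d = np.einsum("ij,ij->i", a_air, n_d)
    a_l = np.einsum("ij,ij->i", a_air, n_l)

    with np.errstate(divide="ignore", invalid="ignore"):
        ld = np.where(a_d > 0, a_l / a_d, np.nan)
    n_nonpos = int(np.sum(ok & ~(a_d > 0)))
    if n_nonpos:
        logger.info("L/D undefined at %d samples with non-positive drag", n_nonpos)
    n_slow = int(np.sum(~ok))
    if n_slow:
        logger.info("decomposition undefined at %d near-zero-speed samples", n_slow)
    return a_d, a_l, n_d, n_l, ld


def vertical_jerk(track: SmoothedTrack, t: np.ndarray) -> np.ndarray:
    """Vertical jerk (m/s³) from the spline's analytic third derivative."""
    jerk_cm = track.com(t, 3)[:, 1]
    return jerk_cm / 100.0


def aero_series(kin: KinematicSeries, track: SmoothedTrack,
                cfg: PipelineConfig | None = None) -> AeroSeries:
    """Full aerodynamic series of a trial from its kinematic series."""
    cfg = cfg or PipelineConfig()
    a_tot = kin.acc_xy / 100.0           # cm/s² -> m/s²
    vel = kin.vel_xy / 100.0
    a_air = aero_acceleration(a_tot, cfg.gravity_g)
    a_d, a_l, n_d, n_l, ld = decompose_lift_drag(a_air, vel)
    jerk = vertical_jerk(track, kin.t)
    return AeroSeries(trial_id=kin.trial_id, t=kin.t, a_tot=a_tot, a_air=a_air,
                      a_drag=a_d, a_lift=a_l, n_drag=n_d, n_lift=n_l,
                      ld_ratio=ld, jerk_z=jerk, meta=dict(kin.meta))
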