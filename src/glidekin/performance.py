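"""Glide-performance geometry, morphology scaling and cohort aggregation.

Covers the quantities that summarise how useful a glide is and how it
scales with size: wing loading and its allometry, the glide index of a
simplified J-shaped trajectory, the sub-canopy reach constraint, the
quasi-equilibrium terminal speed, steering-turn bookkeeping, Reynolds
number, and LOESS trend aggregation across trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .exceptions import ValidationError
from .records import (AIR_DENSITY, AIR_KINEMATIC_VISCOSITY, GRAVITY, MorphRecord)

__all__ = ["GlideGeometry", "TurnMetrics", "AllometryFit", "LoessTrend",
           "wing_loading", "glide_index", "max_horizontal_reach",
           "terminal_speed_estimate", "turn_metrics", "powerlaw_fit",
           "reynolds_number", "loess_aggregate", "mean_angular_rate"]


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def wing_loading(morph: MorphRecord, g: float = GRAVITY) -> float:
    """Wing loading of the body-leg system, p_b = m g / A, in N m^-2."""
    if g <= 0:
        raise ValidationError("g must be > 0")
    return morph.mass_kg * g / morph.planform_area_m2


def terminal_speed_estimate(morph: MorphRecord, c_d: float,
                            rho: float = AIR_DENSITY, g: float = GRAVITY) -> float:
    """Quasi-equilibrium terminal speed from m g = 0.5 rho u^2 C_D A, m/s."""
    if c_d <= 0 or rho <= 0 or g <= 0:
        raise ValidationError("c_d, rho and g must all be > 0")
    return math.sqrt(2 * morph.mass_kg * g / (rho * c_d * morph.planform_area_m2))


def reynolds_number(u: float, length: float, nu: float = AIR_KINEMATIC_VISCOSITY) -> float:
    """Reynolds number Re = u L / nu (SI inputs: m/s, m, m²/s)."""
    if u <= 0 or length <= 0 or nu <= 0:
        raise ValidationError("u, length and nu must all be > 0")
    return u * length / nu


# ---------------------------------------------------------------------------
# Glide geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlideGeometry:
    """Simplified J-shaped trajectory geometry (lengths in cm, theta in deg)."""

    d: float
    h0: float
    hg: float
    glide_index: float
    theta_deg: float | None = None
    h_max: float | None = None
    d_max: float | None = None


def glide_index(d: float, h0: float, hg: float) -> float:
    """Glide index of a J-shaped trajectory: d / (h0 + hg).

    ``d`` is the horizontal distance to the target, ``h0`` the pre-glide
    height loss and ``hg`` the height loss while gliding.  All lengths must
    share one unit.
    """
    if d < 0 or h0 < 0 or hg < 0:
        raise ValidationError("d, h0 and hg must be >= 0")
    total = h0 + hg
    if total <= 0:
        raise ValidationError("total descent h0 + hg must be > 0")
    return d / total


def max_horizontal_reach(h_max: float, h0: float, theta_deg: float,
                         *, literal_tan: bool = False) -> float:
    """Maximum horizontal reach under a canopy of height ``h_max``.

    With the glide angle ``theta`` measured from the *horizontal*, a glide
    that may descend at most ``h_max - h0`` reaches
    ``d_max = (h_max - h0) * cot(theta)``: steeper glides reach less, and
    the reach vanishes in the vertical-fall limit.  ``literal_tan=True``
    instead evaluates ``(h_max - h0) * tan(theta)``, the form appropriate
    when theta is measured from the vertical.
    """
    if h_max <= h0:
        raise ValidationError("h_max must exceed h0 (no room to glide)")
    if not 0.0 < theta_deg < 90.0:
        raise ValidationError("theta_deg must be in (0, 90)")
    th = math.radians(theta_deg)
    factor = math.tan(th) if literal_tan else 1.0 / math.tan(th)
    return (h_max - h0) * factor


def glide_geometry(d: float, h0: float, hg: float, *, theta_deg: float | None = None,
                   h_max: float | None = None) -> GlideGeometry:
    """Bundle the glide-index evaluation with the optional reach constraint."""
    gi = glide_index(d, h0, hg)
    d_max = None
    if theta_deg is not None and h_max is not None:
        d_max = max_horizontal_reach(h_max, h0, theta_deg)
    return GlideGeometry(d=d, h0=h0, hg=hg, glide_index=gi,
                         theta_deg=theta_deg, h_max=h_max, d_max=d_max)


# ---------------------------------------------------------------------------
# Steering turns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurnMetrics:
    """Timing and cost of a steering turn at constant angular speed."""

    turn_angle_deg: float
    angular_speed_deg_s: float
    duration_s: float
    vertical_speed_m_s: float | None = None
    height_loss_m: float | None = None


def turn_metrics(turn_angle_deg: float, angular_speed_deg_s: float,
                 vertical_speed_m_s: float | None = None) -> TurnMetrics:
    """Duration (and height cost) of a yaw steering turn.

    ``duration = angle / angular_speed``; if a vertical speed is given the
    height lost while turning is ``duration * vertical_speed``.
    """
    if angular_speed_deg_s <= 0:
        raise ValidationError("angular_speed_deg_s must be > 0")
    if turn_angle_deg < 0:
        raise ValidationError("turn_angle_deg must be >= 0")
    duration = turn_angle_deg / angular_speed_deg_s
    height = None
    if vertical_speed_m_s is not None:
        if vertical_speed_m_s < 0:
            raise ValidationError("vertical_speed_m_s must be >= 0")
        height = duration * vertical_speed_m_s
    return TurnMetrics(turn_angle_deg=turn_angle_deg,
                       angular_speed_deg_s=angular_speed_deg_s,
                       duration_s=duration, vertical_speed_m_s=vertical_speed_m_s,
                       height_loss_m=height)


def mean_angular_rate(angle_start_deg: float, angle_end_deg: float,
                      interval_s: float) -> float:
    """Mean angular rate |Δangle| / Δt over an interval, deg/s."""
    if interval_s <= 0:
        raise ValidationError("interval_s must be > 0")
    return abs(angle_end_deg - angle_start_deg) / interval_s


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AllometryFit:
    """Power-law fit y = a x^b via OLS on log10-log10 axes."""

    exponent: float
    exponent_se: float
    intercept_log10: float
    r_squared: float
    x_label: str = "x"
    y_label: str = "y"
    n: int = 0


def powerlaw_fit(x, y, x_label: str = "x", y_label: str = "y") -> AllometryFit:
    """Fit a power law by ordinary least squares on log10 axes.

    Requires at least three strictly positive points so the exponent's
    standard error is defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("power-law fit requires >= 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("power-law fit requires strictly positive values")
    X = sm.add_constant(np.log10(x))
    res = sm.OLS(np.log10(y), X).fit()
    return AllometryFit(exponent=float(res.params[1]), exponent_se=float(res.bse[1]),
                        intercept_log10=float(res.params[0]),
                        r_squared=float(res.rsquared),
                        x_label=x_label, y_label=y_label, n=int(x.size))


# ---------------------------------------------------------------------------
# LOESS trend aggregation
# ---------------------------------------------------------------------------

@dataclass
class LoessTrend:
    """Pooled LOESS trend with pointwise between-trial s.e.m."""

    grid: np.ndarray
    trend: np.ndarray
    sem: np.ndarray | None
    n_trials: int
    span: float


def loess_aggregate(trials, span: float = 0.5, n_grid: int = 100) -> LoessTrend:
    """Aggregate several (t, value) series into one LOESS trend.

    All points are pooled and fit with tricube-weighted local linear
    regression (LOWESS) using ``span`` as the fraction of points per local
    fit, evaluated on a common time grid covering the overlap of all trials.
    The pointwise s.e.m. comes from the between-trial spread of each trial
    interpolated onto the grid; it is ``None`` for a single trial.
    """
    if not 0.0 < span <= 1.0:
        raise ValidationError("span must be in (0, 1]")
    series = [(np.asarray(t, dtype=float), np.asarray(v, dtype=float))
              for t, v in trials]
    if len(series) < 1:
        raise ValidationError("at least one trial required")
    t_pool = np.concatenate([t for t, _ in series])
    v_pool = np.concatenate([v for _, v in series])
    ok = np.isfinite(t_pool) & np.isfinite(v_pool)
    t_pool, v_pool = t_pool[ok], v_pool[ok]
    lo = max(t.min() for t, _ in series)
    hi = min(t.max() for t, _ in series)
    if hi <= lo:
        raise ValidationError("trials have no overlapping time span")
    grid = np.linspace(lo, hi, n_grid)
    trend = sm.nonparametric.lowess(v_pool, t_pool, frac=span, xvals=grid)

    if len(series) >= 2:
        stack = np.vstack([np.interp(grid, t, v) for t, v in series])
        sem = stack.std(axis=0, ddof=1) / math.sqrt(len(series))
    else:
        sem = None
    return LoessTrend(grid=grid, trend=np.asarray(trend, dtype=float), sem=sem,
                      n_trials=len(series), span=span)
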