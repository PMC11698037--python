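"""Kinematic landmarks and phase segmentation of the J-shaped trajectory.

Two landmarks segment a trial:

* **terminal speed (TS)** — the first time the (smoothed) descent speed
  reaches a fixed fraction (default 95%) of its trial maximum ``uz_max``;
* **glide initiation (GI)** — the time of maximum horizontal acceleration,
  searched from the TS landmark onward by default, since glide initiation
  always follows the attainment of terminal descent speed.

Samples are then labelled ``pre-terminal``, ``parachuting``,
``initiation`` (a fixed-length nose-down window ending at GI) and
``gliding``.  Landmarks that cannot be detected are explicit ``None``; a
heavy individual may reach the floor before ever initiating a glide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import PipelineConfig
from .kinematics import KinematicSeries

__all__ = ["PhaseLandmarks", "terminal_speed_landmark", "glide_initiation_landmark",
           "segment_phases", "detect_landmarks"]

logger = logging.getLogger(__name__)

PHASE_PRE_TERMINAL = "pre-terminal"
PHASE_PARACHUTING = "parachuting"
PHASE_INITIATION = "initiation"
PHASE_GLIDING = "gliding"


@dataclass
class PhaseLandmarks:
    """Landmark times/magnitudes and per-phase summaries of one trial.

    Speeds in cm/s, heights in cm, accelerations in m/s², times in s.
    Missing landmarks are ``None``, never silently dropped.
    """

    trial_id: str
    uz_max: float | None = None
    t_uzmax: float | None = None
    t_terminal: float | None = None
    height_loss_at_terminal: float | None = None
    t_glide_init: float | None = None
    a_x_peak: float | None = None
    height_loss_at_glide_init: float | None = None
    landing: dict | None = None
    phase_labels: np.ndarray | None = None
    phase_summaries: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("phase_labels")
        return d


def _height_loss(kin: KinematicSeries, t: float) -> float:
    """Height lost (cm, positive) between the trial start and time ``t``."""
    z = np.interp(t, kin.t, kin.com_xy[:, 1])
    return float(kin.com_xy[0, 1] - z)


def terminal_speed_landmark(kin: KinematicSeries, fraction: float = 0.95):
    """Terminal-speed landmark: first crossing of ``fraction * uz_max``.

    Returns ``(uz_max, t_terminal, height_loss)`` or ``(None, None, None)``
    for an all-ascending trial.  Edge samples are excluded from the search.
    """
    uz = np.where(kin.valid, kin.descent_speed_uz, np.nan)
    if not np.any(np.nan_to_num(uz, nan=-np.inf) > 0):
        warnings.warn(f"trial {kin.trial_id!r}: descent speed never positive; "
                      "terminal-speed landmark undefined", stacklevel=2)
        return None, None, None
    i_max = int(np.nanargmax(uz))
    uz_max = float(uz[i_max])
    threshold = fraction * uz_max
    crossed = np.flatnonzero(np.nan_to_num(uz, nan=-np.inf) >= threshold)
    i_ts = int(crossed[0])
    t_ts = float(kin.t[i_ts])
    return uz_max, t_ts, _height_loss(kin, t_ts)


def glide_initiation_landmark(kin: KinematicSeries, search_start: float | None = None):
    """Glide-initiation landmark: time of maximum horizontal acceleration.

    The search runs over valid samples with ``t >= search_start`` (pass the
    terminal-speed time for the default behaviour, or ``None`` to search the
    whole trial).  Exact ties resolve to the earliest time.  If the
    horizontal acceleration never exceeds zero the landmark is ``None`` (no
    glide initiated).  Returns ``(t_gi, a_x_peak_m_s2, height_loss)``.
    """
    a_x = kin.acc_xy[:, 0] / 100.0  # cm/s² -> m/s²
    mask = kin.valid.copy()
    if search_start is not None:
        mask &= kin.t >= search_start
    if not np.any(mask):
        warnings.warn(f"trial {kin.trial_id!r}: empty glide-initiation search window",
                      stacklevel=2)
        return None, None, None
    a = np.where(mask, a_x, -np.inf)
    i_gi = int(np.argmax(a))  # argmax returns the first occurrence on ties
    if a[i_gi] <= 0:
        warnings.warn(f"trial {kin.trial_id!r}: horizontal acceleration never positive; "
                      "no glide initiation detected", stacklevel=2)
        return None, None, None
    t_gi = float(kin.t[i_gi])
    return t_gi, float(a[i_gi]), _height_loss(kin, t_gi)


def segment_phases(kin: KinematicSeries, landmarks: PhaseLandmarks,
                   cfg: PipelineConfig | None = None) -> PhaseLandmarks:
    """Label every sample with its phase and attach per-phase summaries.

    The initiation window spans ``[t_GI - w, t_GI]`` (``w`` = nose-down
    window length, default 0.16 s) but never reaches before the
    terminal-speed landmark.  Landing statistics are means over the trailing
    window (default 0.2 s).
    """
    cfg = cfg or PipelineConfig()
    t = kin.t
    labels = np.full(t.size, PHASE_PRE_TERMINAL, dtype=object)

    t_ts = landmarks.t_terminal
    t_gi = landmarks.t_glide_init
    if t_ts is not None:
        labels[t >= t_ts] = PHASE_PARACHUTING
    if t_gi is not None:
        w0 = t_gi - cfg.initiation_window_s
        if t_ts is not None and w0 < t_ts:
            logger.info("trial %r: initiation window truncated at the terminal-speed landmark",
                        kin.trial_id)
            w0 = t_ts
        labels[(t >= w0) & (t <= t_gi)] = PHASE_INITIATION
        labels[t > t_gi] = PHASE_GLIDING

    def _phase_stats(mask):
        if not np.any(mask):
            return None
        return {
            "mean_glide_angle_deg": float(np.nanmean(kin.glide_angle_theta[mask])),
            "mean_speed_cm_s": float(np.nanmean(kin.speed_u[mask])),
            "mean_pitch_deg": float(np.nanmean(kin.body_pitch_beta[mask])),
            "mean_aoa_deg": float(np.nanmean(kin.aoa_alpha[mask])),
            "duration_s": float(t[mask][-1] - t[mask][0]),
        }

    summaries = {phase: _phase_stats(labels == phase)
                 for phase in (PHASE_PRE_TERMINAL, PHASE_PARACHUTING,
                               PHASE_INITIATION, PHASE_GLIDING)}

    tail = t >= t[-1] - cfg.landing_window_s
    landing = _phase_stats(tail)
    if landing is not None:
        landing["t"] = float(t[-1])
        landing["x"] = float(kin.com_xy[-1, 0])
        landing["z"] = float(kin.com_xy[-1, 1])

    landmarks.phase_labels = labels
    landmarks.phase_summaries = summaries
    landmarks.landing = landing
    return landmarks


def detect_landmarks(kin: KinematicSeries, cfg: PipelineConfig | None = None,
                     *, search_from_terminal: bool = True) -> PhaseLandmarks:
    """Run both landmark detectors and the segmentation on one trial."""
    cfg = cfg or PipelineConfig()
    lm = PhaseLandmarks(trial_id=kin.trial_id)
    uz_max, t_ts, h_ts = terminal_speed_landmark(kin, cfg.terminal_fraction)
    lm.uz_max, lm.t_terminal, lm.height_loss_at_terminal = uz_max, t_ts, h_ts
    if uz_max is not None:
        uz = np.where(kin.valid, kin.descent_speed_uz, np.nan)
        lm.t_uzmax = float(kin.t[int(np.nanargmax(uz))])
    start = t_ts if search_from_terminal else None
    t_gi, ax_pk, h_gi = glide_initiation_landmark(kin, start)
    lm.t_glide_init, lm.a_x_peak, lm.height_loss_at_glide_init = t_gi, ax_pk, h_gi
    return segment_phases(kin, lm, cfg)
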