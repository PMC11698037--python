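"""End-to-end trial analysis and cohort aggregation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aeroforce import AeroSeries, aero_series
from .config import PipelineConfig
from .exceptions import InsufficientPeaksError, ValidationError
from .kinematics import KinematicSeries, kinematic_series, smooth_positions
from .oscillation import OscillationEstimate, XCorrResult, characterize_oscillation, \
    cross_correlation
from .phases import PhaseLandmarks, detect_landmarks
from .records import TrackedTrial

__all__ = ["TrialAnalysis", "analyze_trial", "cohort_summary"]

#: Half-width of the oscillation/cross-correlation window around glide
#: initiation, s (the damped oscillation spans roughly this interval).
OSC_HALF_WINDOW_S = 0.5


@dataclass
class TrialAnalysis:
    """All per-trial outputs of the pipeline."""

    trial: TrackedTrial
    kinematics: KinematicSeries
    aero: AeroSeries
    landmarks: PhaseLandmarks
    oscillation: OscillationEstimate | None = None
    xcorr: dict[tuple, XCorrResult] = field(default_factory=dict)

    @property
    def glide_index_measured(self) -> float | None:
        """Horizontal travel per unit descent over the whole trial."""
        com = self.kinematics.com_xy
        d = float(com[-1, 0] - com[0, 0])
        h = float(com[0, 1] - com[-1, 1])
        return d / h if h > 0 else None


def _oscillation_window(kin: KinematicSeries, landmarks: PhaseLandmarks):
    if landmarks.t_glide_init is None:
        return None
    lo = max(float(kin.t[0]), landmarks.t_glide_init - OSC_HALF_WINDOW_S)
    hi = min(float(kin.t[-1]), landmarks.t_glide_init + OSC_HALF_WINDOW_S)
    return (lo, hi)


def analyze_trial(trial: TrackedTrial, cfg: PipelineConfig | None = None) -> TrialAnalysis:
    """Run the full pipeline on one tracked trial.

    Stages: spline smoothing, kinematic series, lift/drag decomposition,
    landmark detection and phase segmentation, then — when a glide
    initiation landmark exists — pitch-oscillation statistics and
    cross-correlations in a window around it.  Oscillation statistics are
    ``None`` when the pitch series has too few peaks.
    """
    cfg = cfg or PipelineConfig()
    track = smooth_positions(trial, cfg.smoothing_tolerance)
    kin = kinematic_series(trial, cfg, track)
    aero = aero_series(kin, track, cfg)
    landmarks = detect_landmarks(kin, cfg)

    osc = None
    xcorr: dict[tuple, XCorrResult] = {}
    window = _oscillation_window(kin, landmarks)
    if window is not None:
        try:
            osc = characterize_oscillation(kin.t, kin.body_pitch_beta, window,
                                           prominence_deg=cfg.peak_prominence_deg)
        except (InsufficientPeaksError, ValidationError):
            osc = None
        # correlations over the transition itself: nose-down onset through
        # pitch settling (the pre-switch parachute stretch would dilute them)
        lo = max(float(kin.t[0]), landmarks.t_glide_init - cfg.initiation_window_s)
        hi = min(float(kin.t[-1]), landmarks.t_glide_init + OSC_HALF_WINDOW_S)
        m = (kin.t >= lo) & (kin.t <= hi) & kin.valid
        if np.sum(m) >= 8:
            dt = kin.dt_nominal
            beta = kin.body_pitch_beta[m]
            pitch_acc = np.gradient(np.gradient(beta, dt), dt)
            series = {
                "pitch_acc": pitch_acc,
                "aoa": kin.aoa_alpha[m],
                "theta": kin.glide_angle_theta[m],
                "beta": beta,
            }
            n_m = int(np.sum(m))
            max_lag = min(cfg.xcorr_max_lag_s, (n_m // 2 - 1) * dt)
            for a, b in (("pitch_acc", "aoa"), ("pitch_acc", "theta"), ("theta", "beta")):
                if np.nanstd(series[a]) == 0 or np.nanstd(series[b]) == 0:
                    continue  # flat series: correlation undefined
                xcorr[(a, b)] = cross_correlation(series[a], series[b], dt,
                                                  max_lag, labels=(a, b))
    return TrialAnalysis(trial=trial, kinematics=kin, aero=aero,
                         landmarks=landmarks, oscillation=osc, xcorr=xcorr)


def cohort_summary(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    """Per-age-group summary table of landmark and performance statistics.

    One row per age group with trial counts and group means (NaN-aware) of
    the maximum descent speed, landmark times and height losses, landing
    glide angle and speed, measured glide index, and wing loading.
    """
    if not analyses:
        raise ValidationError("no analyses to summarise")
    rows = []
    for a in analyses:
        lm = a.landmarks
        landing = lm.landing or {}
        rows.append({
            "age_group": a.trial.morph.age_group or "unknown",
            "trial_id": a.trial.trial_id,
            "uz_max_cm_s": lm.uz_max,
            "t_terminal_s": lm.t_terminal,
            "height_loss_terminal_cm": lm.height_loss_at_terminal,
            "t_glide_init_s": lm.t_glide_init,
            "height_loss_glide_init_cm": lm.height_loss_at_glide_init,
            "a_x_peak_m_s2": lm.a_x_peak,
            "landing_glide_angle_deg": landing.get("mean_glide_angle_deg"),
            "landing_speed_cm_s": landing.get("mean_speed_cm_s"),
            "glide_index": a.glide_index_measured,
            "wing_loading_n_m2": a.trial.morph.wing_loading,
        })
    df = pd.DataFrame(rows)
    grouped = df.drop(columns=["trial_id"]).groupby("age_group", sort=False)
    out = grouped.mean(numeric_only=True)
    out.insert(0, "n_trials", grouped.size())
    return out.reset_index()
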