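"""File formats: trial CSV + metadata YAML, result CSV/JSON, config YAML.

On-disk conventions follow the reporting units of the source data: trial
coordinates in cm, mass in mg, body length in mm, area in mm².  Numeric
outputs are written with 17 significant digits so every reader/writer pair
round-trips losslessly at double precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aeroforce import AeroSeries
from .exceptions import FormatError, ValidationError
from .kinematics import KinematicSeries
from .phases import PhaseLandmarks
from .records import MorphRecord, TrackedTrial
from .simulate import (AeroModel, GroundTruth, PostureState, SimConfig)

__all__ = ["read_trial", "write_trial", "write_results", "read_landmarks",
           "read_kinematics_csv", "write_ground_truth", "read_ground_truth",
           "sim_config_to_dict", "sim_config_from_dict", "read_sim_config",
           "write_sim_config"]

TRIAL_COLUMNS = ["t_s", "head_x_cm", "head_z_cm", "abd_x_cm", "abd_z_cm"]
FLOAT_FMT = "%.17g"


def _meta_path_for(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".meta.yaml")


def read_trial(csv_path, meta_path=None) -> TrackedTrial:
    """Read one tracked trial from a CSV plus its metadata YAML.

    The CSV must carry the columns ``t_s, head_x_cm, head_z_cm, abd_x_cm,
    abd_z_cm``; the metadata file supplies ``mass_mg``, ``length_mm``,
    ``area_mm2`` and optionally ``age_group``, ``fps_video`` and ``notes``.
    If ``meta_path`` is omitted, ``<trial>.meta.yaml`` next to the CSV is
    used.
    """
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path_for(csv_path)
    if not meta_path.exists():
        raise FormatError(f"metadata file not found: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in ("mass_mg", "length_mm", "area_mm2"):
        if key not in meta:
            raise FormatError(f"metadata {meta_path} is missing required field {key!r}")
    morph = MorphRecord(mass_mg=float(meta["mass_mg"]),
                        body_length_mm=float(meta["length_mm"]),
                        planform_area_mm2=float(meta["area_mm2"]),
                        age_group=str(meta.get("age_group", "")))

    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial CSV {csv_path} is missing column(s): {', '.join(missing)}")
    if len(df) < TrackedTrial.MIN_SAMPLES:
        raise ValidationError(
            f"trial CSV {csv_path}: length >= {TrackedTrial.MIN_SAMPLES} samples required, "
            f"got {len(df)}")
    trial = TrackedTrial(
        trial_id=str(meta.get("trial_id", csv_path.stem)),
        t=df["t_s"].to_numpy(),
        head_xy=df[["head_x_cm", "head_z_cm"]].to_numpy(),
        abd_xy=df[["abd_x_cm", "abd_z_cm"]].to_numpy(),
        morph=morph,
        fps_video=float(meta["fps_video"]) if "fps_video" in meta else None,
        notes=str(meta.get("notes", "")),
    )
    return trial


def write_trial(trial: TrackedTrial, out_dir) -> tuple[Path, Path]:
    """Write a trial CSV and its metadata YAML; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{trial.trial_id}.csv"
    df = pd.DataFrame({
        "t_s": trial.t,
        "head_x_cm": trial.head_xy[:, 0], "head_z_cm": trial.head_xy[:, 1],
        "abd_x_cm": trial.abd_xy[:, 0], "abd_z_cm": trial.abd_xy[:, 1],
    })
    df.to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = {
        "trial_id": trial.trial_id,
        "mass_mg": trial.morph.mass_mg,
        "length_mm": trial.morph.body_length_mm,
        "area_mm2": trial.morph.planform_area_mm2,
        "age_group": trial.morph.age_group,
        "notes": trial.notes,
    }
    if trial.fps_video is not None:
        meta["fps_video"] = trial.fps_video
    meta_path = _meta_path_for(csv_path)
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return csv_path, meta_path


# ---------------------------------------------------------------------------
# Result files
# ---------------------------------------------------------------------------

def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_results(kin: KinematicSeries, aero: AeroSeries, landmarks: PhaseLandmarks,
                  out_dir) -> dict[str, Path]:
    """Write the per-trial kinematics CSV, aero CSV and landmarks JSON.

    Files are keyed by the trial id; missing landmarks appear as explicit
    JSON nulls.  Returns a mapping of file kind to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tid = kin.trial_id

    kin_path = out_dir / f"{tid}_kinematics.csv"
    pd.DataFrame({
        "t_s": kin.t,
        "com_x_cm": kin.com_xy[:, 0], "com_z_cm": kin.com_xy[:, 1],
        "vel_x_cm_s": kin.vel_xy[:, 0], "vel_z_cm_s": kin.vel_xy[:, 1],
        "acc_x_cm_s2": kin.acc_xy[:, 0], "acc_z_cm_s2": kin.acc_xy[:, 1],
        "speed_cm_s": kin.speed_u, "descent_speed_cm_s": kin.descent_speed_uz,
        "glide_angle_deg": kin.glide_angle_theta,
        "body_pitch_deg": kin.body_pitch_beta, "aoa_deg": kin.aoa_alpha,
        "valid": kin.valid.astype(int),
    }).to_csv(kin_path, index=False, float_format=FLOAT_FMT)

    aero_path = out_dir / f"{tid}_aero.csv"
    pd.DataFrame({
        "t_s": aero.t,
        "a_air_x_m_s2": aero.a_air[:, 0], "a_air_z_m_s2": aero.a_air[:, 1],
        "a_drag_m_s2": aero.a_drag, "a_lift_m_s2": aero.a_lift,
        "ld_ratio": aero.ld_ratio, "jerk_z_m_s3": aero.jerk_z,
    }).to_csv(aero_path, index=False, float_format=FLOAT_FMT)

    lm_path = out_dir / f"{tid}_landmarks.json"
    payload = _json_safe(landmarks.to_dict())
    if landmarks.phase_labels is not None:
        payload["phase_labels"] = list(map(str, landmarks.phase_labels))
    with open(lm_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"kinematics": kin_path, "aero": aero_path, "landmarks": lm_path}


def read_kinematics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_landmarks(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Ground truth and simulator configuration
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    payload = _json_safe(dataclasses.asdict(truth))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def sim_config_to_dict(cfg: SimConfig) -> dict:
    return {
        "morph": {"mass_mg": cfg.morph.mass_mg, "length_mm": cfg.morph.body_length_mm,
                  "area_mm2": cfg.morph.planform_area_mm2,
                  "age_group": cfg.morph.age_group},
        "aero": {"cd0": cfg.aero.cd0, "cd1": cfg.aero.cd1, "cl1": cfg.aero.cl1,
                 "lift_scale": cfg.aero.lift_scale},
        "parachute": dataclasses.asdict(cfg.parachute),
        "glide": dataclasses.asdict(cfg.glide),
        "pitch_inertia_I": cfg.pitch_inertia_I,
        "air_density": cfg.air_density,
        "gravity": cfg.gravity,
        "switch_trigger": list(cfg.switch_trigger),
        "switch_ramp_s": cfg.switch_ramp_s,
        "stop_height_m": cfg.stop_height_m,
        "initial_state": list(cfg.initial_state),
        "duration": cfg.duration,
        "sample_rate": cfg.sample_rate,
        "noise_sigma_cm": cfg.noise_sigma_cm,
        "seed": cfg.seed,
        "trial_id": cfg.trial_id,
    }


def sim_config_from_dict(d: dict) -> SimConfig:
    try:
        morph = MorphRecord(mass_mg=d["morph"]["mass_mg"],
                            body_length_mm=d["morph"]["length_mm"],
                            planform_area_mm2=d["morph"]["area_mm2"],
                            age_group=d["morph"].get("age_group", ""))
        aero = AeroModel(**d["aero"])
        parachute = PostureState(**d["parachute"])
        glide = PostureState(**d["glide"])
    except KeyError as exc:
        raise FormatError(f"simulator config is missing field {exc}") from exc
    kwargs = {k: d[k] for k in ("pitch_inertia_I", "air_density", "gravity",
                                "duration", "sample_rate", "noise_sigma_cm",
                                "seed", "trial_id", "switch_ramp_s",
                                "stop_height_m") if k in d}
    if "switch_trigger" in d:
        kwargs["switch_trigger"] = tuple(d["switch_trigger"])
    if "initial_state" in d:
        kwargs["initial_state"] = tuple(d["initial_state"])
    return SimConfig(morph=morph, aero=aero, parachute=parachute, glide=glide, **kwargs)


def write_sim_config(cfg: SimConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(sim_config_to_dict(cfg), fh, sort_keys=True)
    return path


def read_sim_config(path) -> SimConfig:
    with open(path) as fh:
        return sim_config_from_dict(yaml.safe_load(fh) or {})
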