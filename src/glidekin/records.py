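"""Core domain records: per-individual morphometrics and tracked trials.

Coordinate convention used throughout the package: the lateral (vertical)
plane with ``x`` horizontal, positive toward the landing target, and ``z``
vertical, positive up.  Heights lost during a fall are therefore reported as
positive numbers even though ``z`` itself decreases.

Units at the I/O boundary follow the conventions of the source data:
positions in cm, mass in mg, body length in mm, planform area in mm².
Physical computations convert to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError

#: Standard gravitational acceleration, m s^-2.
GRAVITY = 9.81

#: Air density at ~25 degC lab conditions, kg m^-3.
AIR_DENSITY = 1.204

#: Kinematic viscosity of air at ~25 degC, m^2 s^-1.
AIR_KINEMATIC_VISCOSITY = 1.55e-5


@dataclass(frozen=True)
class MorphRecord:
    """Morphometrics of one individual (whole body-leg system).

    Parameters
    ----------
    mass_mg : float
        Body mass in milligrams.
    body_length_mm : float
        Head-to-abdomen-tip length in millimetres.
    planform_area_mm2 : float
        Projected (dorsal) planform area of the body-leg system in mm².
    age_group : str
        Age label, e.g. ``"0-DAH"`` (days after hatching).
    """

    mass_mg: float
    body_length_mm: float
    planform_area_mm2: float
    age_group: str = ""

    def __post_init__(self) -> None:
        for name in ("mass_mg", "body_length_mm", "planform_area_mm2"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {getattr(self, name)!r}")

    # SI accessors -------------------------------------------------------
    @property
    def mass_kg(self) -> float:
        return self.mass_mg * 1e-6

    @property
    def body_length_m(self) -> float:
        return self.body_length_mm * 1e-3

    @property
    def planform_area_m2(self) -> float:
        return self.planform_area_mm2 * 1e-6

    @property
    def wing_loading(self) -> float:
        """Wing loading p_b = m g / A of the body-leg system, N m^-2."""
        return self.mass_kg * GRAVITY / self.planform_area_m2


@dataclass
class TrackedTrial:
    """One digitised lateral-view trial: head and abdomen-tip tracks.

    ``t`` is in seconds (nominally 50 Hz), positions in cm in the x-right /
    z-up lateral plane.  ``head_xy`` and ``abd_xy`` are ``(n, 2)`` arrays of
    ``(x, z)`` pairs.
    """

    trial_id: str
    t: np.ndarray
    head_xy: np.ndarray
    abd_xy: np.ndarray
    morph: MorphRecord
    fps_video: float | None = None
    notes: str = ""
    meta: dict = field(default_factory=dict)

    MIN_SAMPLES = 10

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.head_xy = np.asarray(self.head_xy, dtype=float)
        self.abd_xy = np.asarray(self.abd_xy, dtype=float)
        n = self.t.size
        if n < self.MIN_SAMPLES:
            raise ValidationError(
                f"trial {self.trial_id!r}: length >= {self.MIN_SAMPLES} samples required, got {n}"
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError(f"trial {self.trial_id!r}: time vector must be strictly increasing")
        for name, arr in (("head_xy", self.head_xy), ("abd_xy", self.abd_xy)):
            if arr.shape != (n, 2):
                raise ValidationError(
                    f"trial {self.trial_id!r}: {name} must have shape ({n}, 2), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"trial {self.trial_id!r}: {name} contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt_nominal(self) -> float:
        """Median sampling interval, s."""
        return float(np.median(np.diff(self.t)))

    @property
    def com_xy(self) -> np.ndarray:
        """Raw (unsmoothed) CoM track: midpoint of head and abdomen, cm."""
        return 0.5 * (self.head_xy + self.abd_xy)

    def with_tracks(self, head_xy: np.ndarray, abd_xy: np.ndarray, **meta) -> "TrackedTrial":
        """Copy of this trial with replaced landmark tracks."""
        new = replace(self, head_xy=np.array(head_xy), abd_xy=np.array(abd_xy))
        new.meta = {**self.meta, **meta}
        return new
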