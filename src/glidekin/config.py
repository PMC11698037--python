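"""Pipeline configuration shared by the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

from .exceptions import ValidationError
from .records import AIR_DENSITY, GRAVITY


@dataclass
class PipelineConfig:
    """Tunable parameters of the trajectory-analysis pipeline.

    Attributes
    ----------
    smoothing_tolerance : float
        Residual-sum bound of the quintic smoothing spline, cm² per
        coordinate per trial.
    terminal_fraction : float
        Fraction of the trial's maximum descent speed used as the
        terminal-speed landmark threshold.
    gravity_g : float
        Gravitational acceleration, m s^-2.
    air_density_rho : float
        Air density, kg m^-3.
    peak_prominence_deg : float
        Minimum prominence of pitch-oscillation extrema, degrees.
    xcorr_max_lag_s : float
        Half-width of the cross-correlation lag scan, s.
    loess_span : float
        LOESS span (fraction of pooled points per local fit).
    initiation_window_s : float
        Length of the nose-down glide-initiation window preceding peak
        horizontal acceleration, s.
    landing_window_s : float
        Length of the trailing window used for landing-phase statistics, s.
    edge_samples : int
        Number of samples flagged at each end of a trial (spline edge
        effects) and excluded from landmark searches.
    seed : int
        Seed for any stochastic step run under this configuration.
    """

    smoothing_tolerance: float = 0.5
    terminal_fraction: float = 0.95
    gravity_g: float = GRAVITY
    air_density_rho: float = AIR_DENSITY
    peak_prominence_deg: float = 1.0
    xcorr_max_lag_s: float = 0.5
    loess_span: float = 0.5
    initiation_window_s: float = 0.16
    landing_window_s: float = 0.2
    edge_samples: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.terminal_fraction < 1.0:
            raise ValidationError(f"terminal_fraction must be in (0, 1), got {self.terminal_fraction}")
        if self.smoothing_tolerance < 0:
            raise ValidationError("smoothing_tolerance must be >= 0")
        for name in ("gravity_g", "air_density_rho", "peak_prominence_deg",
                     "xcorr_max_lag_s", "initiation_window_s", "landing_window_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValidationError(f"loess_span must be in (0, 1], got {self.loess_span}")
        if self.edge_samples < 0:
            raise ValidationError("edge_samples must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
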