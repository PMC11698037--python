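"""Damped pitch-oscillation statistics at glide initiation.

The posture switch that initiates a glide excites an underdamped pitch
oscillation.  Three estimators characterise it:

* **log decrement** — peaks of the pitch series about its settled baseline;
  the decrement ``delta`` is the mean log ratio of successive full-cycle
  amplitudes and the damping ratio is
  ``zeta = delta / sqrt(4 pi^2 + delta^2)``.  Growing oscillations yield a
  negative decrement and hence a negative ``zeta``, which is reported
  as-is (flagged, not clamped).
* **FFT peak frequency** — Hann window, 4x zero padding, spectrum argmax
  above a low-frequency cut.  The spectrum peak of an underdamped response
  sits at the damped frequency; the undamped natural frequency
  ``f_n = f_peak / sqrt(1 - zeta^2)`` is also reported when a damping ratio
  is available.
* **cross-correlation** — per-lag Pearson coefficients between kinematic
  series (e.g. pitch acceleration vs AoA), normalised on the overlap so the
  coefficient stays in [-1, 1] at every lag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .exceptions import InsufficientPeaksError, ValidationError

__all__ = ["OscillationEstimate", "XCorrResult", "find_pitch_peaks",
           "damping_ratio_logdec", "natural_frequency_fft", "undamped_frequency",
           "cross_correlation", "characterize_oscillation"]

#: Fraction of the window tail used as the equilibrium baseline.
BASELINE_TAIL_FRACTION = 0.2

#: Low-frequency cut for the FFT peak search, Hz.
FFT_LOW_CUT_HZ = 0.5

#: Zero-padding factor for the FFT.
FFT_PAD_FACTOR = 4


@dataclass
class OscillationEstimate:
    """Damped-oscillation statistics of one pitch series."""

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray       # signed, degrees about baseline
    log_decrement: float
    damping_ratio: float
    pairing_mode: str                 # "full-cycle" | "half-cycle"
    baseline_deg: float
    spectrum_peak_hz: float | None
    natural_frequency_hz: float | None
    window: tuple


@dataclass
class XCorrResult:
    """Cross-correlation of two series over integer-sample lags."""

    labels: tuple
    lags_s: np.ndarray
    coefficients: np.ndarray
    best_lag_s: float | None
    coefficient_at_best_lag: float | None
    meta: dict = field(default_factory=dict)


def _slice_window(t, y, window):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, y = t[m], y[m]
    return t, y


def _baseline(y: np.ndarray) -> float:
    """Equilibrium baseline: mean of the final tail of the window."""
    k = max(1, int(round(BASELINE_TAIL_FRACTION * y.size)))
    return float(np.mean(y[-k:]))


def find_pitch_peaks(t, beta_deg, window=None, prominence_deg: float = 1.0,
                     smooth_cutoff_hz: float | None = 10.0):
    """Alternating extrema of the pitch series about its settled baseline.

    The series is first low-pass filtered (zero-phase second-order
    Butterworth at ``smooth_cutoff_hz``; ``None`` disables), which sits well
    above the few-Hz pitch oscillation but suppresses sample-to-sample
    digitisation noise that would otherwise generate spurious extrema.
    Local maxima and minima of ``beta - baseline`` with at least
    ``prominence_deg`` prominence are merged in time order; consecutive
    extrema of the same kind are collapsed to the more extreme one, so
    maxima and minima strictly alternate.  Returns
    ``(times, signed_deviations, baseline)``.

    Raises ``InsufficientPeaksError`` with fewer than two extrema (no
    damping ratio can be formed).
    """
    if prominence_deg <= 0:
        raise ValidationError("prominence_deg must be > 0")
    t, y = _slice_window(t, beta_deg, window)
    if t.size < 4:
        raise InsufficientPeaksError("window too short for peak finding")
    if smooth_cutoff_hz is not None and t.size > 15:
        fs = 1.0 / float(np.median(np.diff(t)))
        if 0 < smooth_cutoff_hz < 0.5 * fs:
            b, a = butter(2, smooth_cutoff_hz, fs=fs)
            y = filtfilt(b, a, y)
    base = _baseline(y)
    dev = y - base
    hi, _ = find_peaks(dev, prominence=prominence_deg)
    lo, _ = find_peaks(-dev, prominence=prominence_deg)
    idx = np.concatenate([hi, lo])
    kind = np.concatenate([np.ones(hi.size, dtype=int), -np.ones(lo.size, dtype=int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    if idx.size < 2:
        raise InsufficientPeaksError(
            f"found {idx.size} oscillation extrema; at least 2 required")
    # enforce max/min alternation: of consecutive same-kind extrema keep the
    # more extreme in that kind's direction
    keep: list[int] = []
    kinds: list[int] = []
    for i, k in zip(idx, kind):
        if kinds and kinds[-1] == k:
            if k * dev[i] > k * dev[keep[-1]]:
                keep[-1] = i
        else:
            keep.append(i)
            kinds.append(k)
    if len(keep) < 2:
        raise InsufficientPeaksError("fewer than 2 alternating extrema")
    keep = np.array(keep)
    return t[keep], dev[keep], base


def swing_amplitudes(signed_deviations, floor_frac: float = 0.0) -> np.ndarray:
    """Half-cycle amplitudes from successive alternating extrema.

    Each entry is half the absolute difference of two successive extrema —
    the amplitude of that half swing.  Measuring swings rather than
    deviations from a fixed baseline cancels any slow drift of the
    oscillation's equilibrium (the gliding equilibrium pitch drifts while
    the glide angle is still shallowing), and on an ideal damped sinusoid
    the exponential decay factors out exactly.

    With ``floor_frac > 0``, only the contiguous run of swings containing
    the largest swing and staying at or above ``floor_frac`` times it is
    kept — residual noise wiggles after the oscillation has settled form
    near-constant-amplitude swings that would otherwise dilute the
    decrement toward zero.
    """
    dev = np.asarray(signed_deviations, dtype=float)
    if dev.size < 2:
        raise InsufficientPeaksError("need >= 2 extrema to form a swing")
    swings = 0.5 * np.abs(np.diff(dev))
    if floor_frac > 0 and swings.size:
        keep = swings >= floor_frac * swings.max()
        i = int(np.argmax(swings))
        lo = i
        while lo > 0 and keep[lo - 1]:
            lo -= 1
        hi = i
        while hi + 1 < swings.size and keep[hi + 1]:
            hi += 1
        swings = swings[lo:hi + 1]
    return swings


def damping_ratio_logdec(amplitudes, mode: str = "full-cycle"):
    """Damping ratio from the logarithmic decrement of oscillation amplitudes.

    ``amplitudes`` are positive magnitudes in time order, one per cycle in
    ``"full-cycle"`` mode (the decrement is the mean of
    ``ln(A_i / A_{i+1})``) or one per half cycle in ``"half-cycle"`` mode
    (the decrement is twice that mean).  Returns ``(delta, zeta)`` with
    ``zeta = delta / sqrt(4 pi^2 + delta^2)``; a growing oscillation yields
    a negative decrement and a negative zeta, reported as-is.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(amps <= 0) or not np.all(np.isfinite(amps)):
        raise ValidationError("amplitudes must be positive and finite")
    if amps.size < 2:
        raise InsufficientPeaksError("log decrement needs >= 2 amplitudes")
    if mode == "full-cycle":
        delta = float(np.mean(np.log(amps[:-1] / amps[1:])))
    elif mode == "half-cycle":
        delta = float(2.0 * np.mean(np.log(amps[:-1] / amps[1:])))
    else:
        raise ValidationError(f"unknown pairing mode {mode!r}")
    zeta = delta / math.sqrt(4 * math.pi ** 2 + delta ** 2)
    return delta, zeta


def natural_frequency_fft(t, beta_deg, window=None, *, low_cut_hz: float = FFT_LOW_CUT_HZ,
                          pad_factor: int = FFT_PAD_FACTOR, taper: str | None = "hann"):
    """Spectrum-peak frequency of the pitch series (Hz).

    The series is baseline-removed, tapered (Hann by default; ``None`` for
    a plain rectangular window) and zero-padded ``pad_factor`` times before
    the FFT; the returned frequency is the spectrum argmax above
    ``low_cut_hz``.  For an underdamped response this is the damped
    oscillation frequency.  The estimator expects the oscillation to lie
    within the analysis window (the pipeline centres the window on glide
    initiation); a transient confined to the very edge of a long window is
    suppressed by the taper.  Returns ``None`` (with a warning) if no
    spectral peak exists above the cut.
    """
    t, y = _slice_window(t, beta_deg, window)
    if t.size < 4:
        raise ValidationError("window too short for an FFT")
    dt = float(np.median(np.diff(t)))
    fs = 1.0 / dt
    n_pad = pad_factor * t.size
    bin_width = fs / n_pad
    if bin_width > low_cut_hz:
        raise ValidationError(
            f"window too short: padded bin width {bin_width:.3f} Hz exceeds "
            f"the {low_cut_hz} Hz low cut")
    dev = y - np.mean(y)
    if taper == "hann":
        dev = dev * np.hanning(y.size)
    elif taper is not None:
        raise ValidationError(f"unknown taper {taper!r}")
    spec = np.abs(np.fft.rfft(dev, n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=dt)
    band = freqs >= low_cut_hz
    if not np.any(band) or np.all(spec[band] == 0):
        warnings.warn("no spectral peak above the low cut; frequency undefined",
                      stacklevel=2)
        return None
    i = np.argmax(np.where(band, spec, -np.inf))
    return float(freqs[i])


def undamped_frequency(f_peak_hz: float, zeta: float) -> float:
    """Undamped natural frequency from the spectrum peak: f_d / sqrt(1-zeta^2)."""
    if not -1.0 < zeta < 1.0:
        raise ValidationError("zeta must lie in (-1, 1)")
    return f_peak_hz / math.sqrt(1.0 - zeta ** 2)


def cross_correlation(x, y, dt: float, max_lag_s: float = 0.5,
                      labels: tuple = ("x", "y")) -> XCorrResult:
    """Pearson cross-correlation over integer-sample lags within ±max_lag.

    A positive best lag means the second series lags the first.  Each lag's
    coefficient is the Pearson correlation of the overlapping segments, so
    it is always in [-1, 1].  Zero-variance overlap yields a NaN coefficient
    at that lag; if all lags are undefined the result carries ``None``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and equal length")
    n = x.size
    max_k = int(round(max_lag_s / dt))
    if max_k >= n // 2:
        raise ValidationError("max_lag must be less than half the window")
    lags = np.arange(-max_k, max_k + 1)
    coeffs = np.full(lags.size, np.nan)
    for j, k in enumerate(lags):
        if k >= 0:
            xa, ya = x[: n - k], y[k:]
        else:
            xa, ya = x[-k:], y[: n + k]
        if np.std(xa) == 0 or np.std(ya) == 0:
            continue
        coeffs[j] = float(np.corrcoef(xa, ya)[0, 1])
    if np.all(np.isnan(coeffs)):
        warnings.warn("zero-variance input: cross-correlation undefined", stacklevel=2)
        best_lag, best = None, None
    else:
        i = int(np.nanargmax(np.abs(coeffs)))
        best_lag, best = float(lags[i] * dt), float(coeffs[i])
    return XCorrResult(labels=labels, lags_s=lags * dt, coefficients=coeffs,
                       best_lag_s=best_lag, coefficient_at_best_lag=best)


def characterize_oscillation(t, beta_deg, window=None, *, prominence_deg: float = 1.0
                             ) -> OscillationEstimate:
    """Full oscillation characterisation: peaks, log decrement, FFT frequency.

    The damping ratio comes from half-cycle swing amplitudes (see
    ``swing_amplitudes``), which needs at least three alternating extrema.
    """
    times, devs, base = find_pitch_peaks(t, beta_deg, window, prominence_deg)
    swings = swing_amplitudes(devs, floor_frac=0.1)
    if swings.size < 2:
        raise InsufficientPeaksError(
            "need >= 3 alternating extrema for a swing-ratio log decrement")
    delta, zeta = damping_ratio_logdec(swings, "half-cycle")
    pairing_mode = "half-cycle-swing"
    f_peak = natural_frequency_fft(t, beta_deg, window)
    f_n = None
    if f_peak is not None and -1.0 < zeta < 1.0:
        f_n = undamped_frequency(f_peak, zeta)
    tt, _ = _slice_window(t, beta_deg, window)
    return OscillationEstimate(
        peak_times=times, peak_amplitudes=devs, log_decrement=delta,
        damping_ratio=zeta, pairing_mode=pairing_mode, baseline_deg=base,
        spectrum_peak_hz=f_peak, natural_frequency_hz=f_n,
        window=(float(tt[0]), float(tt[-1])),
    )
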