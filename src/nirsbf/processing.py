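"""Skin-blood-flow removal by short-separation regression.

The short (1 cm) channel sees only skin; the long (3 cm) channel sees skin
plus cortex.  During a rest window the cortical contribution is constant, so
the long-channel optical density y is an affine function of the short-channel
optical density x: y = alpha * x + beta.  Fitting (alpha, beta) by ordinary
least squares on the rest window and taking the residual of the long channel
removes the skin contribution -- including cardiac pulsation, which shares the
skin path -- leaving the cerebral hemoglobin change rescaled by the brain
path length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .hemodynamics import OpticalSeries, OpticsParams
from .pulse import HRSeries

__all__ = [
    "ODSeries",
    "CalibrationModel",
    "BrainConcSeries",
    "optical_density",
    "calibrate_rest",
    "extract_brain",
    "cbf_feedback_signal",
]


@dataclass
class ODSeries:
    """Baseline-referenced optical densities of the two channels.

    ``x`` = -ln(I_1cm / ref_1cm), ``y`` = -ln(I_3cm / ref_3cm).
    """

    time_s: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.time_s)
        if not (len(self.x) == n and len(self.y) == n):
            raise ValueError("ODSeries arrays must share one length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("optical densities must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "x": self.x, "y": self.y})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass(frozen=True)
class CalibrationModel:
    """Rest-window regression line y = alpha * x + beta."""

    alpha: float
    beta: float
    rest_window: Tuple[float, float]
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if not self.rest_window[1] > self.rest_window[0]:
            raise ValueError("rest_window must be non-empty")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"alpha": self.alpha, "beta": self.beta,
                       "rest_window": list(self.rest_window),
                       "n_points": self.n_points,
                       "r_squared": self.r_squared}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["alpha"], d["beta"], tuple(d["rest_window"]),
                   d["n_points"], d["r_squared"])


@dataclass
class BrainConcSeries:
    """Estimated cerebral hemoglobin change, on the same grid as its input."""

    time_s: np.ndarray
    c_brain_hat: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.c_brain_hat = np.asarray(self.c_brain_hat, dtype=float)
        if len(self.time_s) != len(self.c_brain_hat):
            raise ValueError("BrainConcSeries arrays must share one length")
        if not np.isfinite(self.c_brain_hat).all():
            raise ValueError("c_brain_hat must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s,
                             "c_brain_hat": self.c_brain_hat})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def optical_density(series: OpticalSeries,
                    baseline="first-10s") -> ODSeries:
    """Convert intensities to baseline-referenced optical densities.

    ``baseline`` is either the string ``"first-10s"`` (reference = mean
    intensity over the first 10 s, the default a deployed device would use)
    or an explicit pair ``(ref_1cm, ref_3cm)``.
    """
    if np.any(series.I_1cm <= 0) or np.any(series.I_3cm <= 0):
        raise ValueError("intensities must be positive")
    if isinstance(baseline, str):
        if baseline != "first-10s":
            raise ValueError(f"unknown baseline mode {baseline!r}")
        k = max(1, min(len(series.time_s), int(round(10.0 * series.fs))))
        ref1 = float(np.mean(series.I_1cm[:k]))
        ref2 = float(np.mean(series.I_3cm[:k]))
    else:
        ref1, ref2 = float(baseline[0]), float(baseline[1])
        if ref1 <= 0 or ref2 <= 0:
            raise ValueError("baseline intensities must be positive")
    x = -np.log(series.I_1cm / ref1)
    y = -np.log(series.I_3cm / ref2)
    return ODSeries(time_s=series.time_s, x=x, y=y, fs=series.fs)


def calibrate_rest(od: ODSeries,
                   rest_window: Tuple[float, float] = (0.0, 30.0)
                   ) -> CalibrationModel:
    """Fit the skin-removal regression y = alpha*x + beta on a rest window.

    Requires >= 10 samples inside the window and non-degenerate variance in
    x (some spontaneous skin fluctuation or pulsation must be present for
    the slope to be identifiable).
    """
    t0, t1 = float(rest_window[0]), float(rest_window[1])
    mask = (od.time_s >= t0) & (od.time_s <= t1)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(
            f"rest window [{t0:g}, {t1:g}] s contains {n} samples; >= 10 required")
    x = od.x[mask]
    y = od.y[mask]
    if np.var(x) <= 0:
        raise ValueError("degenerate rest window: zero variance in x")
    alpha, beta = np.polyfit(x, y, 1)
    resid = y - (alpha * x + beta)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationModel(alpha=float(alpha), beta=float(beta),
                            rest_window=(t0, t1), n_points=n, r_squared=r2)


def extract_brain(od: ODSeries, calib: CalibrationModel,
                  optics: OpticsParams) -> BrainConcSeries:
    """Remove the skin contribution from the long channel.

    ``c_brain_hat(t) = (y(t) - alpha x(t) - beta) / (epsilon l_brain_3cm)``:
    the regression residual rescaled to concentration units.  Because beta
    absorbs the (constant) resting cortical level, the estimate is the
    cerebral hemoglobin change relative to the rest window.
    """
    resid = od.y - calib.alpha * od.x - calib.beta
    c_hat = resid / (optics.epsilon * optics.l_brain_3cm)
    return BrainConcSeries(time_s=od.time_s, c_brain_hat=c_hat, fs=od.fs)


def _ibi_at_samples(time_s: np.ndarray, hr: HRSeries) -> np.ndarray:
    """Inter-beat interval (s) at each sample: step function of the most
    recent beat's rate, the first value extended backwards."""
    ibi_beats = 60.0 / hr.hr_per_min
    k = np.searchsorted(hr.t_s, time_s, side="right") - 1
    k = np.clip(k, 0, len(ibi_beats) - 1)
    return ibi_beats[k]


def cbf_feedback_signal(brain: BrainConcSeries, hr: HRSeries | None,
                        smooth_beats: int = 0) -> BrainConcSeries:
    """Cardiac-cycle smoothing of the extracted brain signal.

    The displayed feedback cue is the brain estimate averaged over a centred
    window spanning ``smooth_beats`` current inter-beat intervals, so cardiac
    residue at the pulse period is strongly attenuated.  ``smooth_beats = 0``
    returns the input unchanged.
    """
    if smooth_beats < 0:
        raise ValueError("smooth_beats must be >= 0")
    if smooth_beats == 0:
        return BrainConcSeries(time_s=brain.time_s.copy(),
                               c_brain_hat=brain.c_brain_hat.copy(),
                               fs=brain.fs)
    if hr is None or len(hr.hr_per_min) == 0:
        raise ValueError("smoothing requires a non-empty heart-rate series")
    v = brain.c_brain_hat
    n = len(v)
    ibi = _ibi_at_samples(brain.time_s, hr)
    w = np.maximum(1, np.round(smooth_beats * ibi * brain.fs).astype(int))
    idx = np.arange(n)
    lo = np.clip(idx - (w - 1) // 2, 0, n)
    hi = np.clip(idx + w // 2, 0, n - 1)
    cs = np.concatenate([[0.0], np.cumsum(v)])
    out = (cs[hi + 1] - cs[lo]) / (hi + 1 - lo)
    return BrainConcSeries(time_s=brain.time_s.copy(), c_brain_hat=out,
                           fs=brain.fs)
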