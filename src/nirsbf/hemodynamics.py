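"""Synthetic subject physiology and two-photodiode optics.

The simulator emulates what a wearable single-channel NIRS probe sees on the
forehead: a short (1 cm) source--detector channel dominated by scalp/skin
blood, and a long (3 cm) channel sampling both skin and cortex.  Hemoglobin
concentrations are tracked as *changes* relative to a resting baseline
(standard ΔHb convention for a single isosbestic wavelength, where only total
hemoglobin is resolvable), in arbitrary µM-equivalent units.

A subject voluntarily drives the cortical concentration (and, more weakly,
heart rate) up or down; both relax toward an effort-dependent set-point with
a first-order time constant.  Cardiac pulsation lives in the skin compartment
and is what the downstream pulse detector works on.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HR_MIN",
    "HR_MAX",
    "EFFORT_COMMANDS",
    "SubjectModel",
    "OpticsParams",
    "GroundTruthSeries",
    "OpticalSeries",
    "make_subject",
    "simulate_truth",
    "render_optics",
    "invert_intensities",
    "pulse_waveform",
    "PhysioStepper",
]

#: Physiological pulse-rate standard used for beat validation, in beats/min.
HR_MIN = 48.0
HR_MAX = 180.0

#: Voluntary regulation commands understood by the simulator.
EFFORT_COMMANDS = ("raise", "lower", "rest")

# Spectral content of spontaneous skin-flow fluctuations: Mayer waves
# (~0.1 Hz) plus a respiratory component (~0.25 Hz).
_MAYER_HZ = 0.1
_RESP_HZ = 0.25


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class SubjectModel:
    """Parameters of a simulated trainee.

    Attributes
    ----------
    baseline_hr : float
        Resting heart rate, beats/min; must lie within the device's pulse
        standard [48, 180].
    hr_variability_sd : float
        Stationary SD of spontaneous heart-rate fluctuations, beats/min.
    skin_fluctuation_amp : float
        Amplitude of spontaneous skin hemoglobin fluctuations
        (µM-equivalent).
    brain_response_gain : float
        Cortical concentration change produced by sustained full effort
        (µM-equivalent per unit effort).
    hr_response_gain : float
        Heart-rate change produced by sustained full effort, beats/min.
    response_time_constant : float
        First-order relaxation time constant of the voluntary response, s.
    control_skill : float
        Probability-like ability in [0, 1] to apply the correct effort at
        each control opportunity during closed-loop training.
    seed : int
        Seed for the subject's endogenous randomness (fluctuation phases,
        heart-rate noise).
    """

    baseline_hr: float = 70.0
    hr_variability_sd: float = 2.0
    skin_fluctuation_amp: float = 0.2
    brain_response_gain: float = 1.0
    hr_response_gain: float = 12.0
    response_time_constant: float = 5.0
    control_skill: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(HR_MIN <= self.baseline_hr <= HR_MAX, "baseline_hr",
                 f"must be within [{HR_MIN:g}, {HR_MAX:g}] beats/min, "
                 f"got {self.baseline_hr!r}")
        _require(self.hr_variability_sd >= 0, "hr_variability_sd",
                 "must be non-negative")
        _require(self.skin_fluctuation_amp >= 0, "skin_fluctuation_amp",
                 "must be non-negative")
        _require(self.response_time_constant > 0, "response_time_constant",
                 "must be positive")
        _require(0.0 <= self.control_skill <= 1.0, "control_skill",
                 f"must be within [0, 1], got {self.control_skill!r}")


@dataclass(frozen=True)
class OpticsParams:
    """Optical model of the 1 LED / 2 PD probe at the 810 nm isosbestic point.

    A single extinction coefficient suffices because oxy- and deoxyhemoglobin
    absorb equally at the isosbestic wavelength; units are arbitrary but
    consistent with the µM-equivalent concentrations.
    """

    epsilon: float = 1.0          # extinction coefficient
    l_1cm: float = 1.0            # effective path length, 1 cm PD (skin)
    l_skin_3cm: float = 1.2       # effective skin path length, 3 cm PD
    l_brain_3cm: float = 0.8      # effective brain path length, 3 cm PD
    I0_1cm: float = 1.0           # source intensity seen by 1 cm PD
    I0_3cm: float = 1.0           # source intensity seen by 3 cm PD
    noise_sd: float = 0.005       # relative (multiplicative) intensity noise
    pulse_amp: float = 0.3        # cardiac pulsation amplitude on c_skin
    fs: float = 10.0              # sampling rate, Hz (device default)

    def __post_init__(self) -> None:
        for name in ("epsilon", "l_1cm", "l_skin_3cm", "l_brain_3cm",
                     "I0_1cm", "I0_3cm", "fs"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        _require(self.pulse_amp >= 0, "pulse_amp", "must be non-negative")


def _as_float_array(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class GroundTruthSeries:
    """Simulated physiology on a uniform grid, the oracle for every test.

    ``c_skin``/``c_brain`` are hemoglobin concentration changes relative to
    rest; ``hr_true`` is the instantaneous heart rate; ``beat_times`` are the
    (off-grid) times of cardiac cycle onsets, strictly increasing.
    """

    time_s: np.ndarray
    c_skin: np.ndarray
    c_brain: np.ndarray
    hr_true: np.ndarray
    beat_times: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.c_skin = _as_float_array(self.c_skin, "c_skin")
        self.c_brain = _as_float_array(self.c_brain, "c_brain")
        self.hr_true = _as_float_array(self.hr_true, "hr_true")
        self.beat_times = _as_float_array(self.beat_times, "beat_times")
        n = len(self.time_s)
        if not (len(self.c_skin) == len(self.c_brain) == len(self.hr_true) == n):
            raise ValueError("GroundTruthSeries arrays must share one length")
        if not (np.isfinite(self.c_skin).all() and np.isfinite(self.c_brain).all()):
            raise ValueError("concentrations must be finite")
        if len(self.beat_times) > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat_times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        """Grid columns only; beat times are carried by the JSON form."""
        return pd.DataFrame({
            "time_s": self.time_s, "c_skin": self.c_skin,
            "c_brain": self.c_brain, "hr_true": self.hr_true,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def to_json(self, path) -> None:
        payload = {
            "fs": self.fs,
            "time_s": self.time_s.tolist(),
            "c_skin": self.c_skin.tolist(),
            "c_brain": self.c_brain.tolist(),
            "hr_true": self.hr_true.tolist(),
            "beat_times": self.beat_times.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruthSeries":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["time_s"], d["c_skin"], d["c_brain"], d["hr_true"],
                   d["beat_times"], d["fs"])


@dataclass
class OpticalSeries:
    """Sampled photodiode intensities of the two channels."""

    time_s: np.ndarray
    I_1cm: np.ndarray
    I_3cm: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.time_s = _as_float_array(self.time_s, "time_s")
        self.I_1cm = _as_float_array(self.I_1cm, "I_1cm")
        self.I_3cm = _as_float_array(self.I_3cm, "I_3cm")
        n = len(self.time_s)
        if not (len(self.I_1cm) == n and len(self.I_3cm) == n):
            raise ValueError("OpticalSeries arrays must share one length")
        if np.any(self.I_1cm <= 0) or np.any(self.I_3cm <= 0):
            raise ValueError("intensities must be positive")
        if n > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0 / self.fs, rtol=0, atol=1e-6):
                raise ValueError("time_s must be uniformly sampled at fs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s, "I_1cm": self.I_1cm, "I_3cm": self.I_3cm,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "OpticalSeries":
        df = pd.read_csv(path)
        for col in ("time_s", "I_1cm", "I_3cm"):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r} in {path}")
        t = df["time_s"].to_numpy(float)
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 10.0
        return cls(t, df["I_1cm"].to_numpy(float), df["I_3cm"].to_numpy(float), fs)

    def to_json(self, path) -> None:
        payload = {"fs": self.fs, "time_s": self.time_s.tolist(),
                   "I_1cm": self.I_1cm.tolist(), "I_3cm": self.I_3cm.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "OpticalSeries":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["time_s"], d["I_1cm"], d["I_3cm"], d["fs"])


def make_subject(config: Mapping | None = None, seed: int = 0) -> SubjectModel:
    """Build a validated :class:`SubjectModel` from a parameter mapping.

    Unknown keys raise; ``seed`` is set only through the argument so that
    the caller's randomness contract is explicit.  Deterministic for a fixed
    ``(config, seed)``.
    """
    config = dict(config or {})
    if "seed" in config:
        raise ValueError("seed: set via the seed argument, not the config")
    known = {f for f in SubjectModel.__dataclass_fields__ if f != "seed"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown subject parameter(s): {sorted(unknown)}")
    return SubjectModel(**config, seed=int(seed))


class PhysioStepper:
    """Incremental physiology integrator shared by the batch simulator and
    the closed-loop game engine.

    State advances sample by sample at ``fs``; effort ``u`` in [-1, 1] is
    held constant over each :meth:`step_block` call.  Cardiac phase is
    integrated continuously so beat times fall between grid samples.
    """

    def __init__(self, subject: SubjectModel, fs: float,
                 rng: np.random.Generator | None = None) -> None:
        if fs <= 0:
            raise ValueError("fs must be positive")
        self.subject = subject
        self.fs = float(fs)
        self.dt = 1.0 / self.fs
        self.rng = rng if rng is not None else np.random.default_rng(subject.seed)
        self.t = 0.0
        self.c_dev = 0.0        # brain concentration deviation
        self.hr_dev = 0.0       # effort-driven HR deviation
        self.hr_noise = 0.0     # OU heart-rate noise
        self.skin_walk = 0.0    # OU skin fluctuation component
        self.phase = 0.0        # cardiac phase, beats
        self._decay = math.exp(-self.dt / subject.response_time_constant)
        self._rho_hr = math.exp(-self.dt / 10.0)     # HR noise correlation time 10 s
        self._rho_skin = math.exp(-self.dt / 20.0)   # skin walk correlation time 20 s
        self._phi1, self._phi2 = self.rng.uniform(0.0, 2.0 * math.pi, 2)

    def step_block(self, n: int, u: float):
        """Advance ``n`` samples under constant effort ``u``.

        Returns ``(t, c_skin, c_brain, hr, theta, beats)`` where ``theta`` is
        the cardiac phase fraction in [0, 1) at each sample and ``beats`` the
        list of interpolated beat times inside the block.
        """
        s = self.subject
        u = float(np.clip(u, -1.0, 1.0))
        t_arr = self.t + np.arange(n) * self.dt
        c_skin = np.empty(n)
        c_brain = np.empty(n)
        hr = np.empty(n)
        theta = np.empty(n)
        beats: list[float] = []
        c_target = s.brain_response_gain * u
        hr_target = s.hr_response_gain * u
        sd_hr = s.hr_variability_sd * math.sqrt(1.0 - self._rho_hr ** 2)
        sd_skin = 0.3 * s.skin_fluctuation_amp * math.sqrt(1.0 - self._rho_skin ** 2)
        z = self.rng.standard_normal((n, 2))
        for k in range(n):
            tk = t_arr[k]
            c_skin[k] = (s.skin_fluctuation_amp
                         * (math.sin(2 * math.pi * _MAYER_HZ * tk + self._phi1)
                            + 0.5 * math.sin(2 * math.pi * _RESP_HZ * tk + self._phi2))
                         + self.skin_walk)
            c_brain[k] = self.c_dev
            hr_k = s.baseline_hr + self.hr_dev + self.hr_noise
            hr_k = min(max(hr_k, HR_MIN), HR_MAX)
            hr[k] = hr_k
            theta[k] = self.phase % 1.0
            # advance state to the next sample
            self.c_dev = c_target + (self.c_dev - c_target) * self._decay
            self.hr_dev = hr_target + (self.hr_dev - hr_target) * self._decay
            self.hr_noise = self._rho_hr * self.hr_noise + sd_hr * z[k, 0]
            self.skin_walk = self._rho_skin * self.skin_walk + sd_skin * z[k, 1]
            p_next = self.phase + hr_k / 60.0 * self.dt
            kc = math.floor(p_next)
            if kc > math.floor(self.phase) and p_next > self.phase:
                beats.append(tk + (kc - self.phase) / (p_next - self.phase) * self.dt)
            self.phase = p_next
        self.t += n * self.dt
        return t_arr, c_skin, c_brain, hr, theta, beats


def _validate_schedule(effort: Sequence[tuple[str, float]], duration_s: float) -> None:
    if not effort:
        raise ValueError("empty effort schedule")
    total = 0.0
    for cmd, dur in effort:
        if cmd not in EFFORT_COMMANDS:
            raise ValueError(f"unknown effort command {cmd!r}; "
                             f"expected one of {EFFORT_COMMANDS}")
        if dur <= 0:
            raise ValueError("effort segment durations must be positive")
        total += dur
    if total + 1e-9 < duration_s:
        raise ValueError(f"effort schedule covers {total:g} s "
                         f"but duration_s is {duration_s:g} s")


_EFFORT_U = {"raise": 1.0, "lower": -1.0, "rest": 0.0}


def simulate_truth(subject: SubjectModel, duration_s: float,
                   effort: Sequence[tuple[str, float]],
                   fs: float = 10.0) -> GroundTruthSeries:
    """Simulate ground-truth physiology under a piecewise-constant effort
    schedule ``[(command, duration_s), ...]`` covering ``[0, duration_s)``.

    Cortical concentration and heart rate relax toward effort-dependent
    set-points with the subject's time constant; beat times are continuous
    crossings of the integrated cardiac phase, so at a constant heart rate
    ``h`` successive beat spacings equal ``60 / h`` exactly.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    _validate_schedule(effort, duration_s)
    n_total = int(round(duration_s * fs))
    stepper = PhysioStepper(subject, fs)
    # per-sample command, then grouped into constant-effort blocks
    bounds = np.cumsum([0.0] + [dur for _, dur in effort])
    sample_t = np.arange(n_total) / fs
    seg_idx = np.clip(np.searchsorted(bounds, sample_t, side="right") - 1,
                      0, len(effort) - 1)
    parts = []
    beats: list[float] = []
    start = 0
    while start < n_total:
        stop = start
        while stop < n_total and seg_idx[stop] == seg_idx[start]:
            stop += 1
        u = _EFFORT_U[effort[seg_idx[start]][0]]
        t, csk, cbr, hr, _theta, b = stepper.step_block(stop - start, u)
        parts.append((t, csk, cbr, hr))
        beats.extend(b)
        start = stop
    time_s = np.concatenate([p[0] for p in parts])
    return GroundTruthSeries(
        time_s=time_s,
        c_skin=np.concatenate([p[1] for p in parts]),
        c_brain=np.concatenate([p[2] for p in parts]),
        hr_true=np.concatenate([p[3] for p in parts]),
        beat_times=np.array(beats),
        fs=fs,
    )


def pulse_waveform(theta) -> np.ndarray:
    """Cardiac volume-pulse shape on phase in [0, 1).

    The waveform is zero at the beat onset and approaches it with a finite
    slope on both sides -- the sharp "foot" where the steep diastolic descent
    meets the systolic upstroke -- so the per-beat minimum stays detectable
    above sensor noise at a 10 Hz grid.  The mild phase warp skews the peak
    toward early systole.
    """
    th = np.mod(np.asarray(theta, dtype=float), 1.0)
    return np.abs(np.sin(np.pi * th ** 0.9))


def _cardiac_phase(time_s: np.ndarray, beat_times: np.ndarray,
                   hr_true: np.ndarray, fs: float) -> np.ndarray:
    """Phase fraction in [0, 1) at each grid sample, anchored to beat times
    (linear between beats, extrapolated with the edge intervals)."""
    if len(beat_times) < 2:
        # fall back to direct integration of the instantaneous rate
        return np.mod(np.cumsum(hr_true / 60.0) / fs, 1.0)
    idx = np.empty_like(time_s)
    k = np.searchsorted(beat_times, time_s, side="right") - 1
    first_ibi = beat_times[1] - beat_times[0]
    last_ibi = beat_times[-1] - beat_times[-2]
    before = k < 0
    after = k >= len(beat_times) - 1
    mid = ~(before | after)
    idx[before] = (time_s[before] - beat_times[0]) / first_ibi
    idx[after] = (len(beat_times) - 1
                  + (time_s[after] - beat_times[-1]) / last_ibi)
    km = k[mid]
    idx[mid] = km + ((time_s[mid] - beat_times[km])
                     / (beat_times[km + 1] - beat_times[km]))
    return np.mod(idx, 1.0)


def beer_lambert_intensities(c_skin_total: np.ndarray, c_brain: np.ndarray,
                             optics: OpticsParams,
                             rng: np.random.Generator | None = None):
    """Map concentrations to the two detected intensities.

    Noiseless: ``I_1cm = I0_1cm exp(-eps c_skin l_1cm)`` and
    ``I_3cm = I0_3cm exp(-eps (c_skin l_skin_3cm + c_brain l_brain_3cm))``.
    Noise is multiplicative log-normal with relative SD ``noise_sd`` (keeps
    intensities strictly positive by construction).
    """
    o = optics
    I1 = o.I0_1cm * np.exp(-o.epsilon * c_skin_total * o.l_1cm)
    I3 = o.I0_3cm * np.exp(-o.epsilon * (c_skin_total * o.l_skin_3cm
                                         + c_brain * o.l_brain_3cm))
    if o.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        n = len(I1)
        I1 = I1 * np.exp(rng.normal(0.0, o.noise_sd, n))
        I3 = I3 * np.exp(rng.normal(0.0, o.noise_sd, n))
    return I1, I3


def render_optics(truth: GroundTruthSeries, optics: OpticsParams,
                  seed: int = 0) -> OpticalSeries:
    """Render ground truth into photodiode intensities.

    Cardiac pulsation is injected as an additive oscillation on the skin
    compartment, phased to ``truth.beat_times`` so the pulse trough coincides
    with each beat onset.  Bit-identical for fixed inputs and seed.
    """
    rng = np.random.default_rng(seed)
    theta = _cardiac_phase(truth.time_s, truth.beat_times, truth.hr_true,
                           truth.fs)
    c_skin_total = truth.c_skin + optics.pulse_amp * pulse_waveform(theta)
    I1, I3 = beer_lambert_intensities(c_skin_total, truth.c_brain, optics, rng)
    return OpticalSeries(time_s=truth.time_s, I_1cm=I1, I_3cm=I3, fs=truth.fs)


def invert_intensities(series: OpticalSeries, optics: OpticsParams):
    """Exact algebraic inversion of the two-channel forward model.

    Returns ``(c_skin_total, c_brain)``; with zero noise this recovers the
    rendered concentrations to floating-point accuracy and serves as the
    independent oracle for the regression-based extraction.
    """
    o = optics
    od1 = -np.log(series.I_1cm / o.I0_1cm)
    od3 = -np.log(series.I_3cm / o.I0_3cm)
    c_skin = od1 / (o.epsilon * o.l_1cm)
    c_brain = (od3 / o.epsilon - c_skin * o.l_skin_3cm) / o.l_brain_3cm
    return c_skin, c_brain
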