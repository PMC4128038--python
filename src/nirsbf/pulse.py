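"""Pulse-wave beat detection and per-beat heart rate.

The device reads heart rate off the short (1 cm) channel, where the cardiac
volume pulse dominates.  A beat fiducial is the local minimum of the blood
stream level (the diastolic trough, where the waveform changes fastest): a
sample is a candidate when it is the strict minimum of the five most recent
samples, read as a centred window, so a candidate is emitted two samples
after it occurs.  Candidate-to-candidate intervals outside the physiological
pulse standard (48-180 beats/min) are discarded for noise rejection and the
previously accepted beat/rate is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .hemodynamics import HR_MAX, HR_MIN

__all__ = [
    "BeatSeries",
    "HRSeries",
    "detect_minima",
    "validate_beats",
    "heart_rate",
    "OnlinePulseTracker",
]

#: Allowed inter-beat interval range in seconds, from the 48-180 /min standard.
IBI_MIN = 60.0 / HR_MAX
IBI_MAX = 60.0 / HR_MIN


@dataclass
class BeatSeries:
    """Beat candidates with their accept/reject flags.

    ``beat_times`` (the accepted candidates) are strictly increasing and all
    consecutive accepted intervals lie within [60/180, 60/48] s except the
    gaps created by rejected runs.
    """

    candidate_times: np.ndarray
    accepted: np.ndarray
    hr_bounds: Tuple[float, float] = (HR_MIN, HR_MAX)

    def __post_init__(self) -> None:
        self.candidate_times = np.asarray(self.candidate_times, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if len(self.candidate_times) != len(self.accepted):
            raise ValueError("candidate_times and accepted must share length")
        if len(self.candidate_times) > 1 and not np.all(
                np.diff(self.candidate_times) > 0):
            raise ValueError("candidate_times must be strictly increasing")

    @property
    def beat_times(self) -> np.ndarray:
        return self.candidate_times[self.accepted]

    @property
    def rejected_count(self) -> int:
        return int((~self.accepted).sum())

    def to_frame(self) -> pd.DataFrame:
        hrs = heart_rate(self)
        hr_col = np.full(len(self.candidate_times), np.nan)
        acc_idx = np.flatnonzero(self.accepted)
        for bi, hv in zip(hrs.beat_index, hrs.hr_per_min):
            hr_col[acc_idx[bi]] = hv
        return pd.DataFrame({
            "beat_time_s": self.candidate_times,
            "accepted": self.accepted,
            "hr_per_min": hr_col,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass
class HRSeries:
    """Per-beat heart rate: for accepted beat i > 0,
    ``hr_per_s = 1 / (t_i - t_{i-1})`` and ``hr_per_min = 60 x hr_per_s``.
    No value exists for the first beat."""

    beat_index: np.ndarray = field(default_factory=lambda: np.array([], int))
    t_s: np.ndarray = field(default_factory=lambda: np.array([]))
    hr_per_s: np.ndarray = field(default_factory=lambda: np.array([]))
    hr_per_min: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.beat_index = np.asarray(self.beat_index, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.hr_per_s = np.asarray(self.hr_per_s, dtype=float)
        self.hr_per_min = np.asarray(self.hr_per_min, dtype=float)
        n = len(self.beat_index)
        if not (len(self.t_s) == len(self.hr_per_s) == len(self.hr_per_min) == n):
            raise ValueError("HRSeries arrays must share one length")
        if n and self.beat_index.min() < 1:
            raise ValueError("heart rate is defined only for beat_index > 0")

    def __len__(self) -> int:
        return len(self.beat_index)


def detect_minima(signal, fs: float, t0: float = 0.0) -> np.ndarray:
    """Emit candidate beat times from a skin-flow signal sampled at ``fs``.

    Sample j is a candidate when it is the *strict* minimum of the 5-sample
    window {j-2, ..., j+2}; strictness breaks ties on flat signals, and the
    centred reading gives the detector an exact two-sample latency.  Fewer
    than 5 samples yields an empty result with a warning.
    """
    v = np.asarray(signal, dtype=float)
    if v.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if len(v) < 5:
        warnings.warn("fewer than 5 samples; no minima can be detected",
                      stacklevel=2)
        return np.array([])
    c = v[2:-2]
    is_min = ((c < v[:-4]) & (c < v[1:-3]) & (c < v[3:-1]) & (c < v[4:]))
    idx = np.flatnonzero(is_min) + 2
    return t0 + idx / fs


def validate_beats(candidates,
                   hr_bounds: Tuple[float, float] = (HR_MIN, HR_MAX)
                   ) -> BeatSeries:
    """Apply the interval-range noise-rejection rule to sorted candidates.

    The first candidate is accepted unconditionally as t_0.  Each later
    candidate is accepted iff its interval from the last *accepted* beat lies
    within the pulse standard; otherwise it is discarded (the beat clock and
    displayed rate keep their previous values).
    """
    t = np.asarray(candidates, dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("candidates must be sorted strictly increasing")
    lo, hi = 60.0 / hr_bounds[1], 60.0 / hr_bounds[0]
    accepted = np.zeros(len(t), dtype=bool)
    last = None
    for i, ti in enumerate(t):
        if last is None:
            accepted[i] = True
            last = ti
        else:
            ibi = ti - last
            if lo <= ibi <= hi:
                accepted[i] = True
                last = ti
    return BeatSeries(candidate_times=t, accepted=accepted, hr_bounds=hr_bounds)


def heart_rate(beats: BeatSeries) -> HRSeries:
    """Per-beat heart rate from accepted beats; empty if fewer than 2."""
    t = beats.beat_times
    if len(t) < 2:
        return HRSeries()
    ibi = np.diff(t)
    return HRSeries(beat_index=np.arange(1, len(t)), t_s=t[1:],
                    hr_per_s=1.0 / ibi, hr_per_min=60.0 / ibi)


class OnlinePulseTracker:
    """Sample-by-sample variant of detect -> validate -> rate, as a real-time
    display would run it.  Produces results identical to the batch path on
    the same samples.

    ``push(t, value)`` returns the currently displayed heart rate in
    beats/min (``None`` until two beats have been accepted; the previous
    value is retained whenever a candidate is rejected).
    """

    def __init__(self, hr_bounds: Tuple[float, float] = (HR_MIN, HR_MAX)):
        self.hr_bounds = hr_bounds
        self._ibi_lo = 60.0 / hr_bounds[1]
        self._ibi_hi = 60.0 / hr_bounds[0]
        self._buf_v: list[float] = []
        self._buf_t: list[float] = []
        self._last_beat: float | None = None
        self.current_hr: float | None = None
        self.accepted_beats: list[float] = []
        self.rejected_count = 0

    def push(self, t: float, value: float) -> float | None:
        self._buf_v.append(float(value))
        self._buf_t.append(float(t))
        if len(self._buf_v) > 5:
            self._buf_v.pop(0)
            self._buf_t.pop(0)
        if len(self._buf_v) == 5:
            c = self._buf_v[2]
            if all(c < self._buf_v[j] for j in (0, 1, 3, 4)):
                self._candidate(self._buf_t[2])
        return self.current_hr

    def _candidate(self, tc: float) -> None:
        if self._last_beat is None:
            self.accepted_beats.append(tc)
            self._last_beat = tc
            return
        ibi = tc - self._last_beat
        if self._ibi_lo <= ibi <= self._ibi_hi:
            self.accepted_beats.append(tc)
            self._last_beat = tc
            self.current_hr = 60.0 / ibi
        else:
            self.rejected_count += 1
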