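"""The biofeedback training game.

One training *set* lasts at most 120 s: the trainee must hold the displayed
cue (their own cerebral-blood-flow estimate or heart rate) inside a target
band whose width shrinks with difficulty level.  Holding the band
continuously for 15 s ends the set successfully; an advice message appears
if the band has not been reached within the first 10 s.  Each set is scored
on [0, 100] from the remaining time and the total in-band time, a day is 10
sets, and the persistent user level is the decade of the average score over
the previous 100 sets (fewer than 100 sets counts as an average of 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hemodynamics import (OpticsParams, PhysioStepper, SubjectModel,
                           beer_lambert_intensities, pulse_waveform)
from .pulse import OnlinePulseTracker

__all__ = [
    "TargetBand",
    "SetState",
    "SetResult",
    "SessionLog",
    "band_for_level",
    "step_set",
    "finish_set",
    "score_set",
    "user_level",
    "run_session",
]


@dataclass(frozen=True)
class TargetBand:
    """The on-screen band ("blue line"); width encodes difficulty."""

    signal_kind: str          # "CBF" or "HR"
    lower: float
    upper: float
    level: int

    def __post_init__(self) -> None:
        if self.signal_kind not in ("CBF", "HR"):
            raise ValueError("signal_kind must be 'CBF' or 'HR'")
        if not self.lower < self.upper:
            raise ValueError("band lower bound must be below upper bound")
        if self.level < 1:
            raise ValueError("level must be >= 1")

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def band_for_level(level: int, signal_kind: str, baseline: float,
                   direction: str = "increase", base_width: float = 0.5,
                   offset: float = 0.6, width_decay: float = 0.9,
                   width_floor_frac: float = 0.3) -> TargetBand:
    """Target band for a difficulty level.

    The band is centred ``offset`` above (``direction="increase"``) or below
    (``"decrease"``) the subject's baseline; its width shrinks geometrically,
    ``base_width * width_decay**(level-1)``, floored at
    ``width_floor_frac * base_width`` so high levels stay playable.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    width = base_width * max(width_floor_frac, width_decay ** (level - 1))
    center = baseline + offset if direction == "increase" else baseline - offset
    return TargetBand(signal_kind=signal_kind, lower=center - width / 2,
                      upper=center + width / 2, level=level)


@dataclass
class SetState:
    """Running state of one training set.

    Timers are held as sample counts internally (``fs``) so the 15-s
    retention threshold is exact in grid units.
    """

    fs: float = 10.0
    elapsed_s: float = 0.0
    in_band_continuous_s: float = 0.0
    in_band_total_s: float = 0.0
    advice_shown: bool = False
    achieved: bool = False
    achieved_at_s: Optional[float] = None
    ever_in_band: bool = False
    _n_elapsed: int = 0
    _n_cont: int = 0
    _n_total: int = 0


def step_set(state: SetState, t: float, cue_value: float, band: TargetBand,
             retention_s: float = 15.0, advice_s: float = 10.0,
             set_limit_s: float = 120.0) -> SetState:
    """Advance the set state machine by one sample at time ``t`` (seconds
    since the set started).

    In-band samples accrue both the continuous and the total timer by 1/fs;
    an out-of-band sample resets the continuous timer.  The advice flag is
    latched at ``t >= advice_s`` if the cue has never entered the band, and
    the set is achieved the instant the continuous timer reaches
    ``retention_s``.  Stepping a finished set raises.
    """
    if state.achieved or state.elapsed_s >= set_limit_s:
        raise RuntimeError("cannot step a finished set")
    in_band = band.contains(cue_value)
    if in_band:
        state.ever_in_band = True
        state._n_cont += 1
        state._n_total += 1
    else:
        state._n_cont = 0
    if not state.ever_in_band and t >= advice_s:
        state.advice_shown = True
    state._n_elapsed += 1
    state.elapsed_s = state._n_elapsed / state.fs
    state.in_band_continuous_s = state._n_cont / state.fs
    state.in_band_total_s = state._n_total / state.fs
    if state.in_band_continuous_s >= retention_s:
        state.achieved = True
        state.achieved_at_s = state.elapsed_s
    return state


@dataclass(frozen=True)
class SetResult:
    """Outcome of one set; ``score`` is always within [0, 100]."""

    achieved: bool
    remaining_time_s: float
    maintain_time_s: float
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise ValueError("score must lie within [0, 100]")
        if self.achieved and self.maintain_time_s < 15.0 - 1e-9:
            raise ValueError("an achieved set must have >= 15 s in band")


def score_set(achieved: bool, remaining_time_s: float, maintain_time_s: float,
              set_limit_s: float = 120.0, retention_s: float = 15.0) -> float:
    """Score one set on [0, 100].

    Success:  ((remaining + 15) + (maintain - 15) * 0.5) / 120 * 100, where
    the half weight applies to the in-band time beyond the required 15 s --
    this reading makes an instant success score exactly 100.
    Failure:  (maintain * 0.5) / 120 * 100, which is strictly below 50 for
    any maintain time below the full set length.
    """
    if remaining_time_s < 0 or maintain_time_s < 0:
        raise ValueError("times must be non-negative")
    if achieved:
        if maintain_time_s < retention_s - 1e-9:
            raise ValueError("an achieved set must have maintain >= retention")
        raw = ((remaining_time_s + retention_s)
               + (maintain_time_s - retention_s) * 0.5) / set_limit_s * 100.0
    else:
        raw = (maintain_time_s * 0.5) / set_limit_s * 100.0
    return float(min(100.0, max(0.0, raw)))


def finish_set(state: SetState, set_limit_s: float = 120.0,
               retention_s: float = 15.0) -> SetResult:
    """Close out a set and score it."""
    if state.achieved:
        remaining = max(0.0, set_limit_s - float(state.achieved_at_s))
    else:
        remaining = 0.0
    maintain = state.in_band_total_s
    return SetResult(achieved=state.achieved, remaining_time_s=remaining,
                     maintain_time_s=maintain,
                     score=score_set(state.achieved, remaining, maintain,
                                     set_limit_s=set_limit_s,
                                     retention_s=retention_s))


def user_level(score_history: Sequence[float], window: int = 100,
               cap: int = 10) -> int:
    """Difficulty level from the rolling average of the last ``window`` sets.

    With fewer than ``window`` completed sets the average is taken as 0
    points.  Level = decade of the average + 1 (an average of 0-9 points maps
    to level 1), capped at ``cap``.
    """
    scores = list(score_history)
    for s in scores:
        if not 0.0 <= s <= 100.0:
            raise ValueError("scores must lie within [0, 100]")
    if len(scores) < window:
        avg = 0.0
    else:
        avg = float(np.mean(scores[-window:]))
    return min(cap, int(avg // 10) + 1)


@dataclass
class SessionLog:
    """One day of training: exactly ``sets_per_day`` set results plus the
    user level before and after the session."""

    date_index: int
    set_results: list
    user_level_before: int
    user_level_after: int
    seed: int
    signal_kind: str

    def __post_init__(self) -> None:
        if not self.set_results:
            raise ValueError("a session must contain at least one set")

    @property
    def scores(self) -> list:
        return [r.score for r in self.set_results]


def _interval_averaged_rate(beat_times, n_beats: int = 8) -> float | None:
    """Displayed heart-rate cue: rate over the span of the last ``n_beats``
    accepted beats (interval averaging suppresses the sampling-grid
    quantization of single inter-beat intervals at 10 Hz)."""
    if len(beat_times) < 2:
        return None
    tail = beat_times[-n_beats:]
    return 60.0 * (len(tail) - 1) / (tail[-1] - tail[0])


def _cue_target_effort(center: float, cue_baseline: float, cue_latest: float,
                       gain: float) -> float:
    """Feedforward-plus-proportional effort toward the band centre."""
    d_star = center - cue_baseline
    err = center - cue_latest
    return (d_star + 0.8 * err) / gain


def run_session(subject: SubjectModel, cfg, seed: int,
                score_history: Sequence[float] = (),
                date_index: int = 0) -> SessionLog:
    """Simulate one full closed-loop training day.

    The session opens with a rest period used to calibrate the skin-removal
    regression, then runs ``sets_per_day`` sets.  Effort is updated once per
    control interval (default 1 s, a human reaction time): with probability
    ``control_skill`` the subject steers the cue toward the band centre,
    otherwise attention lapses and the effort drops to rest.  Physiology,
    optics, signal extraction and the set state machine all run at ``fs``.
    Deterministic for a fixed (subject, cfg, seed).
    """
    # local imports avoid a cycle: processing imports pulse which is free of
    # game; config imports nothing from game
    from .processing import calibrate_rest, ODSeries

    optics: OpticsParams = cfg.optics
    fs = cfg.fs
    root = np.random.default_rng([int(seed) & 0x7FFFFFFF,
                                  int(subject.seed) & 0x7FFFFFFF])
    phys_rng, optics_rng, behav_rng = root.spawn(3)
    stepper = PhysioStepper(subject, fs, phys_rng)

    def render_block(n: int, u: float):
        t, csk, cbr, _hr, theta, _beats = stepper.step_block(n, u)
        c_skin_total = csk + optics.pulse_amp * pulse_waveform(theta)
        I1, I3 = beer_lambert_intensities(c_skin_total, cbr, optics, optics_rng)
        return t, I1, I3

    # --- calibration rest -------------------------------------------------
    n_rest = int(round(cfg.rest_s * fs))
    t_rest, I1_rest, I3_rest = render_block(n_rest, 0.0)
    k = max(1, min(n_rest, int(round(10.0 * fs))))
    ref1 = float(np.mean(I1_rest[:k]))
    ref3 = float(np.mean(I3_rest[:k]))
    x_rest = -np.log(I1_rest / ref1)
    y_rest = -np.log(I3_rest / ref3)
    od_rest = ODSeries(time_s=t_rest - t_rest[0], x=x_rest, y=y_rest, fs=fs)
    calib = calibrate_rest(od_rest, (0.0, cfg.rest_s))
    denom = optics.epsilon * optics.l_brain_3cm
    c_hat_rest = (y_rest - calib.alpha * x_rest - calib.beta) / denom

    kind = cfg.signal_kind
    if kind == "CBF":
        cue_baseline = float(np.mean(c_hat_rest))
        gain = subject.brain_response_gain
        band_kw = dict(base_width=cfg.cbf_band_base_width,
                       offset=cfg.cbf_band_offset)
    else:
        tracker_rest = OnlinePulseTracker(cfg.hr_bounds)
        for tt, xx in zip(t_rest, x_rest):
            tracker_rest.push(tt, xx)
        cue_baseline = _interval_averaged_rate(tracker_rest.accepted_beats)
        if cue_baseline is None:
            cue_baseline = subject.baseline_hr
        gain = subject.hr_response_gain
        band_kw = dict(base_width=cfg.hr_band_base_width,
                       offset=cfg.hr_band_offset)

    level = user_level(score_history, window=cfg.level_window,
                       cap=cfg.level_cap)
    band = band_for_level(level, kind, cue_baseline, direction=cfg.direction,
                          width_decay=cfg.width_decay,
                          width_floor_frac=cfg.width_floor_frac, **band_kw)

    n_ctrl = max(1, int(round(cfg.control_interval_s * fs)))
    n_set = int(round(cfg.set_limit_s * fs))
    results = []
    for _set_idx in range(cfg.sets_per_day):
        state = SetState(fs=fs)
        cue_latest = cue_baseline
        tracker = OnlinePulseTracker(cfg.hr_bounds) if kind == "HR" else None
        done = 0
        while done < n_set and not state.achieved:
            n = min(n_ctrl, n_set - done)
            if behav_rng.random() < subject.control_skill:
                u = _cue_target_effort(band.center, cue_baseline, cue_latest,
                                       gain) + behav_rng.normal(0.0, 0.05)
            else:
                u = 0.0
            t_blk, I1, I3 = render_block(n, u)
            x = -np.log(I1 / ref1)
            y = -np.log(I3 / ref3)
            c_hat = (y - calib.alpha * x - calib.beta) / denom
            for j in range(n):
                if kind == "CBF":
                    cue = float(c_hat[j])
                else:
                    tracker.push(t_blk[j], float(x[j]))
                    hr_now = _interval_averaged_rate(tracker.accepted_beats)
                    # before two beats have landed the display holds baseline
                    cue = hr_now if hr_now is not None else cue_baseline
                t_set = done / fs
                step_set(state, t_set, cue, band,
                         retention_s=cfg.retention_s, advice_s=cfg.advice_s,
                         set_limit_s=cfg.set_limit_s)
                cue_latest = cue
                done += 1
                if state.achieved:
                    break
        results.append(finish_set(state, set_limit_s=cfg.set_limit_s,
                                  retention_s=cfg.retention_s))
        # brief inter-set rest lets physiology relax toward baseline
        if cfg.inter_set_rest_s > 0:
            render_block(int(round(cfg.inter_set_rest_s * fs)), 0.0)

    new_history = list(score_history) + [r.score for r in results]
    return SessionLog(
        date_index=date_index,
        set_results=results,
        user_level_before=level,
        user_level_after=user_level(new_history, window=cfg.level_window,
                                    cap=cfg.level_cap),
        seed=int(seed),
        signal_kind=kind,
    )
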