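"""Run configuration: every engine, optics and subject parameter with the
device's constants as defaults (10 Hz sampling, 120-s sets, 15-s retention,
10-s advice, 10 sets/day, 48-180 /min pulse standard, 810 nm label)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Tuple

import yaml

from .hemodynamics import HR_MAX, HR_MIN, OpticsParams, make_subject

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # sampling & session structure
    fs: float = 10.0
    set_limit_s: float = 120.0
    retention_s: float = 15.0
    advice_s: float = 10.0
    sets_per_day: int = 10
    rest_s: float = 30.0
    inter_set_rest_s: float = 5.0
    control_interval_s: float = 1.0
    # pulse standard
    hr_bounds: Tuple[float, float] = (HR_MIN, HR_MAX)
    wavelength_nm: float = 810.0
    # feedback signal & target band
    signal_kind: str = "CBF"
    smooth_beats: int = 0
    direction: str = "increase"
    cbf_band_offset: float = 0.6
    cbf_band_base_width: float = 0.5
    hr_band_offset: float = 8.0
    hr_band_base_width: float = 10.0
    width_decay: float = 0.9
    width_floor_frac: float = 0.3
    # level rule
    level_window: int = 100
    level_cap: int = 10
    # nested parameter sets
    subject: dict = field(default_factory=dict)
    optics: OpticsParams = field(default_factory=OpticsParams)

    def __post_init__(self) -> None:
        if isinstance(self.optics, dict):
            self.optics = OpticsParams(**self.optics)
        if self.fs <= 0:
            raise ValueError("fs: must be positive")
        if self.set_limit_s <= 0:
            raise ValueError("set_limit_s: must be positive")
        if not 0 < self.retention_s <= self.set_limit_s:
            raise ValueError("retention_s: must be in (0, set_limit_s]")
        if self.advice_s < 0:
            raise ValueError("advice_s: must be non-negative")
        if self.sets_per_day < 1:
            raise ValueError("sets_per_day: must be >= 1")
        if self.rest_s <= 0:
            raise ValueError("rest_s: must be positive")
        if self.inter_set_rest_s < 0:
            raise ValueError("inter_set_rest_s: must be non-negative")
        if self.control_interval_s <= 0:
            raise ValueError("control_interval_s: must be positive")
        lo, hi = self.hr_bounds
        if not (HR_MIN <= lo < hi <= HR_MAX):
            raise ValueError(
                f"hr_bounds: must lie within the device pulse standard "
                f"[{HR_MIN:g}, {HR_MAX:g}] beats/min with lower < upper, "
                f"got {list(self.hr_bounds)}")
        self.hr_bounds = (float(lo), float(hi))
        if self.signal_kind not in ("CBF", "HR"):
            raise ValueError("signal_kind: must be 'CBF' or 'HR'")
        if self.smooth_beats < 0:
            raise ValueError("smooth_beats: must be >= 0")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction: must be 'increase' or 'decrease'")
        for name in ("cbf_band_base_width", "hr_band_base_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if not 0 < self.width_decay <= 1:
            raise ValueError("width_decay: must be in (0, 1]")
        if not 0 < self.width_floor_frac <= 1:
            raise ValueError("width_floor_frac: must be in (0, 1]")
        if self.level_window < 1:
            raise ValueError("level_window: must be >= 1")
        if self.level_cap < 1:
            raise ValueError("level_cap: must be >= 1")
        # validate subject overrides eagerly so a bad config fails at load
        make_subject(self.subject, seed=0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hr_bounds"] = list(self.hr_bounds)
        return d


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML config; an empty file yields all
    defaults and unknown keys are rejected by name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "hr_bounds" in raw:
        raw["hr_bounds"] = tuple(raw["hr_bounds"])
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
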