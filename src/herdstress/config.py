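"""Run configuration: schedules, QC thresholds, transforms.

All clock arithmetic is timezone-naive local time.  Every window is
half-open ``[start, end)`` and is stored internally as minutes from
midnight (so ``24:00`` is representable as 1440).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

PERIODS = ("B", "T1", "T2", "T3")

BEHAVIORS = (
    "lying",
    "standing_cubicle",
    "standing_walkway",
    "feeding",
    "locomotion",
    "other",
)

#: behaviors that qualify a cow as physically active for HRV windows
ACTIVE_BEHAVIORS = ("feeding", "locomotion")
#: behavior that qualifies a cow as resting
REST_BEHAVIOR = "lying"


class ConfigError(ValueError):
    """Invalid run configuration."""


def parse_clock(text: str) -> float:
    """Parse ``HH:MM`` into minutes from midnight. ``24:00`` is allowed."""
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ConfigError(f"bad clock time {text!r}, expected HH:MM")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= m < 60) or not (0 <= h <= 24) or (h == 24 and m != 0):
        raise ConfigError(f"bad clock time {text!r}")
    return float(h * 60 + m)


def format_clock(minutes: float) -> str:
    h, m = divmod(int(round(minutes)), 60)
    return f"{h:02d}:{m:02d}"


@dataclass(frozen=True)
class ClockWindow:
    """A half-open daily interval [start, end), in minutes from midnight."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= 1440):
            raise ConfigError(
                f"window [{self.start}, {self.end}) must satisfy "
                "0 <= start < end <= 1440 minutes"
            )

    @property
    def minutes(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def overlap(self, start: float, end: float) -> float:
        """Length (min) of the intersection with [start, end)."""
        return max(0.0, min(self.end, end) - max(self.start, start))

    @classmethod
    def from_clock(cls, start: str, end: str) -> "ClockWindow":
        return cls(parse_clock(start), parse_clock(end))


def _check_disjoint(windows: tuple[ClockWindow, ...], what: str) -> None:
    ws = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ws, ws[1:]):
        if b.start < a.end:
            raise ConfigError(
                f"{what} windows overlap: [{a.start},{a.end}) and [{b.start},{b.end})"
            )


@dataclass(frozen=True)
class ObservationSchedule:
    """The daily observation design.

    The three behavior windows (midnight-4 a.m., 10 a.m.-3 p.m.,
    7 p.m.-midnight) total 14 h.  HRV is sampled noon-3 p.m. for active
    cows and 9 p.m.-midnight for resting cows; robot-proximity windows
    come from 10 a.m.-3 p.m.
    """

    behavior_windows: tuple[ClockWindow, ...] = (
        ClockWindow(0, 240),
        ClockWindow(600, 900),
        ClockWindow(1140, 1440),
    )
    activity_window: ClockWindow = ClockWindow(720, 900)
    rest_window: ClockWindow = ClockWindow(1260, 1440)
    proximity_window: ClockWindow = ClockWindow(600, 900)

    def __post_init__(self) -> None:
        _check_disjoint(self.behavior_windows, "behavior")

    @property
    def total_observation_minutes(self) -> float:
        return sum(w.minutes for w in self.behavior_windows)


@dataclass(frozen=True)
class QCSettings:
    """Interbeat-interval QC thresholds.

    detection_threshold
        an interval deviating from its (corrected) predecessor by more
        than this fraction is flagged erroneous (default 0.20).
    max_error_rate
        windows at or above this flagged fraction are rejected (default 0.05).
    max_consecutive
        windows containing a run of this many flagged intervals are
        rejected (default 3, i.e. runs of 1-2 are tolerated).
    wide_factor / narrow_factor
        operational cut-offs classifying single over-wide intervals
        (missed beat) and double-narrow pairs (spurious beat) against
        the local median.
    median_window
        number of preceding unflagged intervals defining the local median.
    """

    detection_threshold: float = 0.20
    max_error_rate: float = 0.05
    max_consecutive: int = 3
    wide_factor: float = 1.75
    narrow_factor: float = 0.75
    median_window: int = 5

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_threshold < 1.0):
            raise ConfigError("detection_threshold must be in (0, 1)")
        if not (0.0 < self.max_error_rate < 1.0):
            raise ConfigError("max_error_rate must be in (0, 1)")
        if self.max_consecutive < 1:
            raise ConfigError("max_consecutive must be >= 1")


#: response -> variance-stabilising transform used before model fitting
DEFAULT_TRANSFORMS = {
    "rmssd_a": "double_log",
    "rmssd_r": "double_log",
    "rmssd": "double_log",
    "cortisol": "log",
    "standing_total": "sqrt",
    "standing_cubicle": "sqrt",
    "standing_walkway": "sqrt",
    "lying": "identity",
    "feeding": "identity",
    "locomotion": "identity",
    "other": "identity",
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 20130107
    n_farms: int = 3
    n_cows_per_farm: int = 12
    periods: tuple[str, ...] = PERIODS
    measurement_days: tuple[int, ...] = (2, 4)
    cortisol_days: tuple[int, ...] = (2, 3, 5)
    schedule: ObservationSchedule = field(default_factory=ObservationSchedule)
    qc: QCSettings = field(default_factory=QCSettings)
    transform_map: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))

    def __post_init__(self) -> None:
        if len(self.periods) != 4:
            raise ConfigError("exactly four ordered experimental periods required")
        if self.n_farms < 1 or self.n_cows_per_farm < 1:
            raise ConfigError("need at least one farm and one cow per farm")

    def transform_for(self, response: str) -> str:
        return self.transform_map.get(response, "identity")


def _window_from_yaml(obj) -> ClockWindow:
    return ClockWindow.from_clock(obj["start"], obj["end"])


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; absent keys keep defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    kwargs = {}
    for key in ("seed", "n_farms", "n_cows_per_farm"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "periods" in raw:
        kwargs["periods"] = tuple(raw["periods"])
    if "measurement_days" in raw:
        kwargs["measurement_days"] = tuple(int(d) for d in raw["measurement_days"])
    if "cortisol_days" in raw:
        kwargs["cortisol_days"] = tuple(int(d) for d in raw["cortisol_days"])
    if "schedule" in raw:
        s = raw["schedule"]
        sched_kwargs = {}
        if "behavior_windows" in s:
            sched_kwargs["behavior_windows"] = tuple(
                _window_from_yaml(w) for w in s["behavior_windows"]
            )
        for key in ("activity_window", "rest_window", "proximity_window"):
            if key in s:
                sched_kwargs[key] = _window_from_yaml(s[key])
        kwargs["schedule"] = ObservationSchedule(**sched_kwargs)
    if "qc" in raw:
        kwargs["qc"] = QCSettings(**raw["qc"])
    if "transform_map" in raw:
        tm = dict(DEFAULT_TRANSFORMS)
        tm.update(raw["transform_map"])
        kwargs["transform_map"] = tm
    return replace(cfg, **kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    def win(w: ClockWindow):
        return {"start": format_clock(w.start), "end": format_clock(w.end)}

    raw = {
        "seed": cfg.seed,
        "n_farms": cfg.n_farms,
        "n_cows_per_farm": cfg.n_cows_per_farm,
        "periods": list(cfg.periods),
        "measurement_days": list(cfg.measurement_days),
        "cortisol_days": list(cfg.cortisol_days),
        "schedule": {
            "behavior_windows": [win(w) for w in cfg.schedule.behavior_windows],
            "activity_window": win(cfg.schedule.activity_window),
            "rest_window": win(cfg.schedule.rest_window),
            "proximity_window": win(cfg.schedule.proximity_window),
        },
        "qc": {
            "detection_threshold": cfg.qc.detection_threshold,
            "max_error_rate": cfg.qc.max_error_rate,
            "max_consecutive": cfg.qc.max_consecutive,
            "wide_factor": cfg.qc.wide_factor,
            "narrow_factor": cfg.qc.narrow_factor,
            "median_window": cfg.qc.median_window,
        },
        "transform_map": dict(cfg.transform_map),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
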