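"""Time budgets over the 14-h daily observation schedule.

Occupancy per ethogram state is the summed intersection of behavior
events with the three observation windows, minus any overlap with
exclusion intervals (milking, measurement handling).  Events crossing
window boundaries are clipped, never dropped.  ``standing_total`` is
derived as cubicle + walkway standing.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import pandas as pd

from .config import BEHAVIORS, ClockWindow, ObservationSchedule


@dataclass(frozen=True)
class TimeBudget:
    """Minutes per behavior for one cow-day over the observed windows."""

    cow: str
    farm: str
    lying: float
    feeding: float
    standing_cubicle: float
    standing_walkway: float
    locomotion: float
    other: float

    @property
    def standing_total(self) -> float:
        return self.standing_cubicle + self.standing_walkway

    @property
    def observed_minutes(self) -> float:
        return (self.lying + self.feeding + self.standing_cubicle
                + self.standing_walkway + self.locomotion + self.other)

    def as_dict(self) -> dict:
        return {
            "cow": self.cow, "farm": self.farm,
            "lying": self.lying, "feeding": self.feeding,
            "standing_cubicle": self.standing_cubicle,
            "standing_walkway": self.standing_walkway,
            "standing_total": self.standing_total,
            "locomotion": self.locomotion, "other": self.other,
        }


def total_observation_minutes(schedule: ObservationSchedule) -> float:
    """Sum of the daily behavior-window durations (840 min = 14 h for
    the default midnight-4 a.m., 10 a.m.-3 p.m., 7 p.m.-midnight design)."""
    return schedule.total_observation_minutes


def _minutes_from_midnight(t: datetime, anchor: datetime) -> float:
    return (t - anchor).total_seconds() / 60.0


def _credited_minutes(start: float, end: float,
                      windows, exclusions) -> float:
    """Event [start, end) against schedule windows minus exclusions."""
    total = 0.0
    for w in windows:
        total += w.overlap(start, end)
        for ex in exclusions:
            a = max(w.start, ex.start)
            b = min(w.end, ex.end)
            if b > a:
                total -= max(0.0, min(b, end) - max(a, start))
    return total


def compute_time_budget(events: pd.DataFrame,
                        schedule: ObservationSchedule | None = None,
                        exclusions: tuple[ClockWindow, ...] = ()) -> TimeBudget:
    """Per-behavior occupancy (minutes) for one cow-day of events.

    Time inside an observation window not covered by any event is
    credited to ``other`` (the states are mutually exclusive and,
    with ``other``, exhaustive).
    """
    schedule = schedule or ObservationSchedule()
    minutes = {b: 0.0 for b in BEHAVIORS}
    if len(events):
        cows = events["cow"].unique()
        if len(cows) > 1:
            raise ValueError(f"expected events of a single cow-day, got cows {list(cows)}")
        d = events["start"].min()
        anchor = datetime(d.year, d.month, d.day)
        cow = str(cows[0])
        farm = str(events["farm"].iloc[0])
    else:
        anchor = datetime(1970, 1, 1)
        cow = farm = ""
    for _, ev in events.iterrows():
        s = _minutes_from_midnight(ev["start"].to_pydatetime(), anchor)
        e = _minutes_from_midnight(ev["end"].to_pydatetime(), anchor)
        minutes[ev["behavior"]] += _credited_minutes(s, e, schedule.behavior_windows,
                                                     exclusions)
    observable = sum(
        _credited_minutes(w.start, w.end, (w,), exclusions)
        for w in schedule.behavior_windows
    )
    accounted = sum(minutes.values())
    minutes["other"] += max(0.0, observable - accounted)
    return TimeBudget(
        cow=cow, farm=farm,
        lying=minutes["lying"], feeding=minutes["feeding"],
        standing_cubicle=minutes["standing_cubicle"],
        standing_walkway=minutes["standing_walkway"],
        locomotion=minutes["locomotion"], other=minutes["other"],
    )


def budgets_table(events: pd.DataFrame,
                  schedule: ObservationSchedule | None = None,
                  exclusions: tuple[ClockWindow, ...] = (),
                  keys=("farm", "cow", "period", "day")) -> pd.DataFrame:
    """Time-budget rows for every cow-day in a multi-cow event log.

    Grouping keys beyond cow/farm (period, day) must be present as
    event columns and are carried through to the output.
    """
    schedule = schedule or ObservationSchedule()
    rows = []
    present = [k for k in keys if k in events.columns]
    for key_vals, grp in events.groupby(list(present), sort=True):
        tb = compute_time_budget(grp, schedule, exclusions)
        row = dict(zip(present, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update({k: v for k, v in tb.as_dict().items() if k not in row})
        rows.append(row)
    return pd.DataFrame(rows)
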