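"""RMSSD computation and 5-min analysis-window selection.

Windows are time-defined: a window starting at t0 holds every interval
whose onset lies in [t0, t0 + 300 s).  Active-state windows come from
the noon-3 p.m. schedule block (behavior feeding or locomotion), rest
windows from 9 p.m.-midnight (lying).  Robot-proximity pairs are 5-min
windows centred on the per-pass distance minimum (near) and maximum
(far) within 10 a.m.-3 p.m., for cows lying throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .config import ACTIVE_BEHAVIORS, REST_BEHAVIOR, ClockWindow, ObservationSchedule, QCSettings
from .ibi import IBISeries
from .qc import QCReport, process_window

WINDOW_S = 300.0
#: minimum fraction of the 5-min span the IBI record must cover
MIN_COVERAGE = 0.90


class HRVError(ValueError):
    pass


def rmssd(intervals) -> float:
    """Root mean square of successive interbeat-interval differences (ms)."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise HRVError("RMSSD needs at least 2 intervals")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class AnalysisWindow:
    """A QC-accepted 5-min IBI excerpt with its RMSSD."""

    start: datetime
    state: str
    rmssd: float
    report: QCReport
    n_intervals: int


@dataclass(frozen=True)
class ProximityPair:
    cow: str
    farm: str
    near_rmssd: float
    far_rmssd: float
    near_time: datetime
    far_time: datetime


def _day_anchor(events: pd.DataFrame, series: IBISeries) -> datetime:
    """Midnight of the observation day."""
    if len(events):
        d = events["start"].min()
        return datetime(d.year, d.month, d.day)
    s = series.start
    return datetime(s.year, s.month, s.day)


def _clock_to_dt(anchor: datetime, minutes: float) -> datetime:
    return anchor + timedelta(minutes=minutes)


def behavior_spans(events: pd.DataFrame, behaviors,
                   window: ClockWindow, anchor: datetime) -> list[tuple[datetime, datetime]]:
    """Maximal continuous spans of the given behaviors, clipped to the
    schedule window.  Abutting qualifying events are merged."""
    w0 = _clock_to_dt(anchor, window.start)
    w1 = _clock_to_dt(anchor, window.end)
    sub = events[events["behavior"].isin(behaviors)].sort_values("start")
    spans: list[list[datetime]] = []
    for _, ev in sub.iterrows():
        s, e = ev["start"].to_pydatetime(), ev["end"].to_pydatetime()
        if spans and s <= spans[-1][1]:
            spans[-1][1] = max(spans[-1][1], e)
        else:
            spans.append([s, e])
    out = []
    for s, e in spans:
        s2, e2 = max(s, w0), min(e, w1)
        if e2 > s2:
            out.append((s2, e2))
    return out


def _window_qc(series: IBISeries, t0: datetime,
               qc: QCSettings) -> tuple[bool, float, QCReport | None, int]:
    sl = series.slice_time(t0, t0 + timedelta(seconds=WINDOW_S))
    if len(sl) < 2 or sl.duration_s < MIN_COVERAGE * WINDOW_S:
        return False, float("nan"), None, len(sl)
    corrected, _, report = process_window(sl, qc, window_id=t0.isoformat())
    if not report.accepted or len(corrected) < 2:
        return False, float("nan"), report, len(sl)
    return True, rmssd(corrected.intervals), report, len(corrected)


def select_state_window(series: IBISeries, events: pd.DataFrame, state: str,
                        schedule: ObservationSchedule | None = None,
                        qc: QCSettings | None = None,
                        step_s: float = 60.0) -> AnalysisWindow | None:
    """Earliest QC-accepted 5-min window of continuous state behavior.

    Returns ``None`` when no qualifying span exists or every candidate
    window fails QC: absence mirrors the study's missing-data mechanism
    and is a legitimate outcome, not an error.
    """
    schedule = schedule or ObservationSchedule()
    qc = qc or QCSettings()
    if state == "active":
        behaviors, window = ACTIVE_BEHAVIORS, schedule.activity_window
    elif state == "rest":
        behaviors, window = (REST_BEHAVIOR,), schedule.rest_window
    else:
        raise HRVError(f"unknown state {state!r}; expected 'active' or 'rest'")
    anchor = _day_anchor(events, series)
    for s, e in behavior_spans(events, behaviors, window, anchor):
        t0 = s
        while t0 + timedelta(seconds=WINDOW_S) <= e:
            ok, value, report, n = _window_qc(series, t0, qc)
            if ok:
                return AnalysisWindow(start=t0, state=state, rmssd=value,
                                      report=report, n_intervals=n)
            t0 = t0 + timedelta(seconds=step_s)
    return None


def _extremum_window(times: np.ndarray, dist: np.ndarray,
                     kind: str) -> tuple[datetime, datetime, datetime]:
    idx = int(np.argmin(dist) if kind == "min" else np.argmax(dist))
    t = pd.Timestamp(times[idx]).to_pydatetime()
    half = timedelta(seconds=WINDOW_S / 2)
    return t - half, t + half, t


def _covered(spans, t0: datetime, t1: datetime) -> bool:
    return any(s <= t0 and t1 <= e for s, e in spans)


def pair_proximity_windows(series: IBISeries, events: pd.DataFrame,
                           distance: pd.DataFrame,
                           schedule: ObservationSchedule | None = None,
                           qc: QCSettings | None = None) -> ProximityPair | None:
    """Near/far 5-min RMSSD pair for a lying cow, from the first robot
    route pass whose two extremum-centred windows both qualify.

    Each window must lie wholly inside the 10 a.m.-3 p.m. proximity
    block (an extremum closer than 2.5 min to the block boundary
    disqualifies its window), the cow must be lying throughout, and the
    window must pass IBI QC.  A far window overlapping the near window
    is taken from the next pass instead.
    """
    schedule = schedule or ObservationSchedule()
    qc = qc or QCSettings()
    anchor = _day_anchor(events, series)
    w0 = _clock_to_dt(anchor, schedule.proximity_window.start)
    w1 = _clock_to_dt(anchor, schedule.proximity_window.end)
    lying = behavior_spans(events, (REST_BEHAVIOR,), schedule.proximity_window, anchor)

    pass_ids = sorted(distance["pass_id"].unique())

    def qualify(t0: datetime, t1: datetime):
        if t0 < w0 or t1 > w1:
            return None
        if not _covered(lying, t0, t1):
            return None
        ok, value, _, _ = _window_qc(series, t0, qc)
        return value if ok else None

    def far_of(k: int):
        grp = distance[distance["pass_id"] == pass_ids[k]]
        return _extremum_window(grp["time"].to_numpy(), grp["distance_m"].to_numpy(), "max")

    for k, pid in enumerate(pass_ids):
        grp = distance[distance["pass_id"] == pid]
        times = grp["time"].to_numpy()
        dist = grp["distance_m"].to_numpy()
        n0, n1, t_near = _extremum_window(times, dist, "min")
        near_val = qualify(n0, n1)
        if near_val is None:
            continue
        f0, f1, t_far = far_of(k)
        if f0 < n1 and n0 < f1:  # overlap: shift far to the next pass
            if k + 1 >= len(pass_ids):
                continue
            f0, f1, t_far = far_of(k + 1)
        far_val = qualify(f0, f1)
        if far_val is None:
            continue
        return ProximityPair(cow=series.cow, farm=series.farm,
                             near_rmssd=near_val, far_rmssd=far_val,
                             near_time=t_near, far_time=t_far)
    return None
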