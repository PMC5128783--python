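"""Interbeat-interval series container and its plain-text file dialect.

The file dialect is deliberately simple: one header line
``cow,farm,session,ISO-start-timestamp`` followed by one interval
duration (milliseconds, positive) per line.  Vendor formats from
heart-rate monitors are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np


class IBIFormatError(ValueError):
    """Malformed interbeat-interval file."""


@dataclass(frozen=True)
class IBISeries:
    """Timestamped interbeat intervals (ms) for one cow-session.

    ``intervals[i]`` occupies the half-open time span
    ``[onset(i), onset(i) + intervals[i] ms)`` where
    ``onset(i) = start + sum(intervals[:i])``.
    """

    cow: str
    farm: str
    session: str
    start: datetime
    intervals: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        if arr.ndim != 1:
            raise IBIFormatError("intervals must be a 1-D sequence")
        if arr.size and not np.all(arr > 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise IBIFormatError(f"non-positive interval at position {bad}")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration_ms(self) -> float:
        return float(self.intervals.sum())

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    @property
    def end(self) -> datetime:
        return self.start + timedelta(milliseconds=self.duration_ms)

    def onsets_ms(self) -> np.ndarray:
        """Onset of each interval, ms since series start."""
        out = np.empty(len(self) + 1)
        out[0] = 0.0
        np.cumsum(self.intervals, out=out[1:])
        return out[:-1]

    def onset_times(self) -> list[datetime]:
        return [self.start + timedelta(milliseconds=float(t)) for t in self.onsets_ms()]

    def slice_time(self, t0: datetime, t1: datetime) -> "IBISeries":
        """All intervals whose onset lies in ``[t0, t1)``."""
        onsets = self.onsets_ms()
        a = (t0 - self.start).total_seconds() * 1000.0
        b = (t1 - self.start).total_seconds() * 1000.0
        mask = (onsets >= a) & (onsets < b)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return replace(self, start=t0, intervals=np.empty(0))
        new_start = self.start + timedelta(milliseconds=float(onsets[idx[0]]))
        return replace(self, start=new_start, intervals=self.intervals[idx])

    def with_intervals(self, intervals) -> "IBISeries":
        return replace(self, intervals=np.asarray(intervals, dtype=float))


def read_ibi_file(path) -> IBISeries:
    """Read the plain-text IBI dialect.

    Raises :class:`IBIFormatError` naming the offending line for
    non-positive or non-numeric intervals, a missing header, or an
    empty interval body.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise IBIFormatError(f"{path}: missing header line")
        parts = [p.strip() for p in header.split(",")]
        if len(parts) != 4:
            raise IBIFormatError(
                f"{path}: header must be 'cow,farm,session,start', got {header.strip()!r}"
            )
        cow, farm, session, start_txt = parts
        try:
            start = datetime.fromisoformat(start_txt)
        except ValueError as exc:
            raise IBIFormatError(f"{path}: bad start timestamp {start_txt!r}") from exc
        values = []
        for lineno, line in enumerate(fh, start=2):
            text = line.strip()
            if not text:
                continue
            try:
                v = float(text)
            except ValueError as exc:
                raise IBIFormatError(
                    f"{path}:{lineno}: non-numeric interval {text!r}"
                ) from exc
            if v <= 0:
                raise IBIFormatError(f"{path}:{lineno}: non-positive interval {v}")
            values.append(v)
    if not values:
        raise IBIFormatError(f"{path}: no intervals")
    return IBISeries(cow=cow, farm=farm, session=session, start=start,
                     intervals=np.array(values))


def write_ibi_file(series: IBISeries, path) -> None:
    if len(series) == 0:
        raise IBIFormatError("refusing to write a series with no intervals")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{series.cow},{series.farm},{series.session},"
                 f"{series.start.isoformat()}\n")
        for v in series.intervals:
            fh.write(f"{v:.6f}\n")
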