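"""CSV readers/writers for behavior logs, distances, cortisol and records.

All tables are UTF-8, comma-separated, with a header row.  Timestamps
are timezone-naive ISO 8601.
"""

from __future__ import annotations

import pandas as pd

from .config import BEHAVIORS


class TableFormatError(ValueError):
    """Malformed tabular input."""


BEHAVIOR_COLUMNS = ["cow", "farm", "behavior", "start", "end"]
DISTANCE_COLUMNS = ["cow", "farm", "day_key", "time", "distance_m", "pass_id"]
CORTISOL_COLUMNS = ["cow", "farm", "period", "day", "concentration"]
RMSSD_COLUMNS = ["farm", "cow", "period", "day", "state", "rmssd", "window_start"]
PROXIMITY_COLUMNS = ["farm", "cow", "period", "day",
                     "near_rmssd", "far_rmssd", "near_time", "far_time"]
BUDGET_COLUMNS = ["farm", "cow", "period", "day", "lying", "feeding",
                  "standing_cubicle", "standing_walkway", "standing_total",
                  "locomotion", "other"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")


def read_behavior_csv(path) -> pd.DataFrame:
    """Read a behavior event log.

    Events are validated: behavior labels must belong to the ethogram,
    every event must have ``end > start``, and events of one cow must
    not overlap (ethogram states are mutually exclusive).
    Returns events sorted by cow then start time.
    """
    df = pd.read_csv(path)
    _require_columns(df, BEHAVIOR_COLUMNS, path)
    bad = sorted(set(df["behavior"]) - set(BEHAVIORS))
    if bad:
        raise TableFormatError(
            f"{path}: unknown behavior label(s) {bad}; allowed: {list(BEHAVIORS)}"
        )
    df = df.copy()
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    if (df["end"] <= df["start"]).any():
        row = df.index[df["end"] <= df["start"]][0]
        raise TableFormatError(f"{path}: event at row {row} has end <= start")
    df = df.sort_values(["cow", "start"], kind="stable").reset_index(drop=True)
    for cow, grp in df.groupby("cow", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        overlap = starts[1:] < ends[:-1]
        if overlap.any():
            i = int(overlap.argmax())
            a, b = grp.iloc[i], grp.iloc[i + 1]
            raise TableFormatError(
                f"{path}: overlapping events for cow {cow}: "
                f"{a['behavior']} [{a['start']}, {a['end']}) and "
                f"{b['behavior']} [{b['start']}, {b['end']})"
            )
    return df


def write_behavior_csv(df: pd.DataFrame, path) -> None:
    cols = BEHAVIOR_COLUMNS + [c for c in ("period", "day") if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_distance_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DISTANCE_COLUMNS, path)
    df = df.copy()
    df["time"] = pd.to_datetime(df["time"])
    return df.sort_values(["cow", "time"], kind="stable").reset_index(drop=True)


def write_distance_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=DISTANCE_COLUMNS)


def read_cortisol_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CORTISOL_COLUMNS, path)
    if (df["concentration"] <= 0).any():
        row = df.index[df["concentration"] <= 0][0]
        raise TableFormatError(f"{path}: non-positive concentration at row {row}")
    return df


def write_cortisol_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=CORTISOL_COLUMNS)


def read_rmssd_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RMSSD_COLUMNS, path)
    return df


def write_rmssd_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=RMSSD_COLUMNS)


def read_proximity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PROXIMITY_COLUMNS, path)
    return df


def write_proximity_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PROXIMITY_COLUMNS)


def read_budget_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, BUDGET_COLUMNS, path)
    return df


def write_budget_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=BUDGET_COLUMNS)
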