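"""Interbeat-interval artifact QC.

Detection follows the sequential 20% rule: an interval is erroneous if
it deviates from the *corrected* value of its predecessor by more than
the detection threshold.  Flagged intervals are classified into the
five-type artifact taxonomy

1. a single deviating interval (outlier),
2./3. a wide-then-narrow (or narrow-then-wide) consecutive pair from a
      shifted beat boundary,
4. a single markedly over-wide interval (missed beat),
5. two successive over-narrow intervals (spurious beat),

and corrected accordingly: interpolate (1), merge-and-halve (2/3),
split in two (4), merge (5).  Five-minute windows are accepted only
when the corrected error rate is below 5% and no run of three or more
consecutive flagged intervals occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import QCSettings
from .ibi import IBISeries

NO_TYPE = 0
UNTYPED = -1


class QCError(ValueError):
    """Inconsistent annotation or invalid QC input."""


@dataclass
class ErrorAnnotation:
    """Per-interval artifact flags and classification.

    ``error_type[i]`` is 1-5 for typed flags, ``-1`` for flagged but
    untypable intervals (e.g. runs of three or more), and ``0`` where
    unflagged.  ``correction[i]`` names the correction applied by
    :func:`correct_series` (empty string where none).
    """

    flagged: np.ndarray
    error_type: np.ndarray = field(default=None)
    correction: list = field(default=None)

    def __post_init__(self):
        self.flagged = np.asarray(self.flagged, dtype=bool)
        n = self.flagged.size
        if self.error_type is None:
            self.error_type = np.zeros(n, dtype=int)
        if self.correction is None:
            self.correction = [""] * n
        if self.error_type.size != n or len(self.correction) != n:
            raise QCError("annotation arrays must share one length")
        if np.any((self.error_type != NO_TYPE) & ~self.flagged):
            raise QCError("error_type set on an unflagged interval")

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def flagged_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive flags as (start, stop) half-open."""
        runs = []
        f = self.flagged
        i = 0
        n = f.size
        while i < n:
            if f[i]:
                j = i
                while j < n and f[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
        return runs

    def max_run(self) -> int:
        return max((b - a for a, b in self.flagged_runs()), default=0)


@dataclass(frozen=True)
class QCReport:
    """Window-level QC verdict (computed from pre-correction flags)."""

    window_id: str
    n_total: int
    n_flagged: int
    max_consecutive: int
    accepted: bool

    @property
    def error_rate(self) -> float:
        return self.n_flagged / self.n_total if self.n_total else 0.0


def detect_errors(series: IBISeries, threshold: float = 0.20) -> ErrorAnnotation:
    """Flag intervals deviating >``threshold`` from the running reference.

    The reference is the corrected value of the predecessor: it only
    advances past unflagged intervals, so a single artifact does not
    cascade onto its normal successor.  Interval 0 is never flagged.
    """
    x = series.intervals
    n = x.size
    if n < 2:
        raise QCError("need at least 2 intervals to detect errors")
    flagged = np.zeros(n, dtype=bool)
    # fast path: indices violating the naive previous-raw-interval rule;
    # the sequential reference differs from x[i-1] only just after a flag,
    # so scanning can jump between naive candidates while no flag is open.
    naive = np.flatnonzero(np.abs(np.diff(x)) > threshold * x[:-1]) + 1
    r = x[0]
    i = 1
    ptr = 0
    while i < n:
        if not flagged[i - 1]:
            # reference == x[i-1]: jump to the next naive candidate
            while ptr < naive.size and naive[ptr] < i:
                ptr += 1
            if ptr == naive.size:
                break
            i = int(naive[ptr])
            r = x[i - 1]
        if abs(x[i] - r) > threshold * r:
            flagged[i] = True
            # reference stays at the last accepted value
        else:
            r = x[i]
        i += 1
    return ErrorAnnotation(flagged=flagged)


def _local_median(x: np.ndarray, flagged: np.ndarray, before: int,
                  window: int) -> float:
    """Median of the ``window`` most recent unflagged intervals before
    index ``before``; falls back to the series-wide unflagged median
    (then the plain series median) near the start."""
    idx = np.flatnonzero(~flagged[:before])
    if idx.size >= window:
        return float(np.median(x[idx[-window:]]))
    pool = np.flatnonzero(~flagged)
    if pool.size:
        return float(np.median(x[pool]))
    return float(np.median(x))


def classify_errors(series: IBISeries, annotation: ErrorAnnotation,
                    qc: QCSettings | None = None) -> ErrorAnnotation:
    """Assign error types 1-5 to flagged runs.

    Precedence per run: wide/narrow pair summing to twice the local
    median (types 2/3), double-narrow pair summing to the local median
    (type 5), single over-wide interval (type 4), any remaining single
    flag (type 1).  Runs of three or more flags stay untyped: such
    windows are rejected, not repaired.
    """
    qc = qc or QCSettings()
    x = series.intervals
    ann = ErrorAnnotation(flagged=annotation.flagged.copy())
    thr = qc.detection_threshold
    for a, b in ann.flagged_runs():
        m = _local_median(x, ann.flagged, a, qc.median_window)
        run_len = b - a
        if run_len >= 3 or run_len >= qc.max_consecutive:
            # corrections are only defined for runs of one or two
            ann.error_type[a:b] = UNTYPED
            continue
        if run_len == 2:
            s = x[a] + x[a + 1]
            wide_narrow = x[a] > m and x[a + 1] < m
            narrow_wide = x[a] < m and x[a + 1] > m
            if (wide_narrow or narrow_wide) and abs(s - 2 * m) <= thr * 2 * m:
                ann.error_type[a:b] = 2 if wide_narrow else 3
            elif (x[a] < qc.narrow_factor * m and x[a + 1] < qc.narrow_factor * m
                  and abs(s - m) <= thr * m):
                ann.error_type[a:b] = 5
            else:
                ann.error_type[a:b] = UNTYPED
        else:  # single flag
            if x[a] > qc.wide_factor * m:
                ann.error_type[a] = 4
            else:
                ann.error_type[a] = 1
    return ann


def correct_series(series: IBISeries, annotation: ErrorAnnotation,
                   qc: QCSettings | None = None,
                   window_id: str = "") -> tuple[IBISeries, QCReport]:
    """Apply per-type corrections and report window QC.

    Corrections: type 1 -> mean of the flanking unflagged intervals
    (two-point interpolation at the midpoint); types 2/3 -> both
    intervals replaced by half their sum; type 4 -> split into two
    equal halves; type 5 -> merged into one interval.  Flagged runs
    touching the series boundary are dropped (no flanking context).
    Untyped runs are left as-is; their window is rejected anyway.
    The report counts flags *before* correction.
    """
    qc = qc or QCSettings()
    x = series.intervals
    n = x.size
    flagged = annotation.flagged
    etype = annotation.error_type
    if np.any((etype != NO_TYPE) & ~flagged):
        raise QCError("annotation inconsistent: typed but not flagged")

    out: list[float] = []
    correction = [""] * n
    i = 0
    runs = {a: b for a, b in annotation.flagged_runs()}
    while i < n:
        if not flagged[i]:
            out.append(float(x[i]))
            i += 1
            continue
        b = runs[i]
        t = int(etype[i])
        at_boundary = i == 0 or b == n
        if at_boundary and t in (1, 2, 3, 4, 5):
            for k in range(i, b):
                correction[k] = "drop"
            i = b
            continue
        if t in (2, 3):
            half = (x[i] + x[i + 1]) / 2.0
            out.extend([half, half])
            correction[i] = correction[i + 1] = "merge_halve"
        elif t == 5:
            out.append(float(x[i] + x[i + 1]))
            correction[i] = correction[i + 1] = "merge"
        elif t == 4:
            out.extend([x[i] / 2.0, x[i] / 2.0])
            correction[i] = "split"
        elif t == 1:
            left = None
            for j in range(i - 1, -1, -1):
                if not flagged[j]:
                    left = float(x[j])
                    break
            right = None
            for j in range(b, n):
                if not flagged[j]:
                    right = float(x[j])
                    break
            if left is None or right is None:
                correction[i] = "drop"
            else:
                out.append((left + right) / 2.0)
                correction[i] = "interpolate"
        else:  # untyped: pass through unchanged
            out.extend(float(v) for v in x[i:b])
        i = b

    report = QCReport(
        window_id=window_id,
        n_total=n,
        n_flagged=annotation.n_flagged,
        max_consecutive=annotation.max_run(),
        accepted=_accepted(n, annotation.n_flagged, annotation.max_run(), qc),
    )
    corrected = series.with_intervals(np.array(out))
    annotation.correction = correction
    return corrected, report


def _accepted(n_total: int, n_flagged: int, max_run: int, qc: QCSettings) -> bool:
    if n_total == 0:
        return False
    rate = n_flagged / n_total
    return rate < qc.max_error_rate and max_run < qc.max_consecutive


def accept_window(report: QCReport, qc: QCSettings | None = None) -> bool:
    """Window passes QC iff corrected error rate < 5% and no run of
    three or more consecutive flagged intervals."""
    qc = qc or QCSettings()
    return _accepted(report.n_total, report.n_flagged, report.max_consecutive, qc)


def process_window(series: IBISeries, qc: QCSettings | None = None,
                   window_id: str = "") -> tuple[IBISeries, ErrorAnnotation, QCReport]:
    """detect -> classify -> correct, in one call."""
    qc = qc or QCSettings()
    ann = detect_errors(series, qc.detection_threshold)
    ann = classify_errors(series, ann, qc)
    corrected, report = correct_series(series, ann, qc, window_id=window_id)
    return corrected, ann, report
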