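"""Synthetic herd generator.

Emulates the study design the analysis assumes: 3 farms x 12 cows,
four experimental periods (baseline B, then T1-T3 with the robot
scraper operating), measurement days 2 and 4 per period (cortisol days
2, 3 and 5), a 14-h daily behavior observation schedule, and the
nested random-effect structure farm / cow-within-farm / cow-by-period.

Interbeat intervals are i.i.d. truncated Gaussian with sd
``true_rmssd / sqrt(2)`` so that the expected RMSSD equals the target;
behavior is an alternating-renewal (semi-Markov) bout process started
in its stationary law so that expected occupancy equals the latent
time budget exactly; cortisol samples are log-normal with median equal
to the latent concentration.  Artifact injection inverts the five-type
correction taxonomy and conserves total beat-train duration.

Period-mean defaults marked "invented" below are free parameters the
source results do not pin down; they are plausible same-order values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .config import PERIODS, ClockWindow, ObservationSchedule, RunConfig
from .ibi import IBISeries


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort-level truth

#: per-period true means; printed study means where available, the rest
#: invented (rmssd_a T2/T3; rmssd_r T3; lying T1; feeding T1/T3;
#: locomotion B/T2; cortisol T1).  Standing components are made
#: additive: the cubicle value is kept and the walkway value is the
#: standing-total remainder.
DEFAULT_PERIOD_MEANS: dict[str, dict[str, float]] = {
    "rmssd_a": {"B": 6.83, "T1": 6.01, "T2": 6.55, "T3": 6.65},
    "rmssd_r": {"B": 9.02, "T1": 8.20, "T2": 9.32, "T3": 9.10},
    "lying": {"B": 320.77, "T1": 335.00, "T2": 362.59, "T3": 365.79},
    "feeding": {"B": 123.83, "T1": 130.00, "T2": 147.28, "T3": 140.00},
    "standing_cubicle": {"B": 98.59, "T1": 95.92, "T2": 71.97, "T3": 90.95},
    "standing_walkway": {"B": 81.04, "T1": 91.18, "T2": 76.09, "T3": 54.91},
    "locomotion": {"B": 155.00, "T1": 164.83, "T2": 150.00, "T3": 144.59},
    "cortisol": {"B": 15.36, "T1": 15.50, "T2": 16.36, "T3": 16.33},
}


@dataclass(frozen=True)
class VarianceSpec:
    """Random-effect standard deviations for one response (raw scale).

    ``day_cv`` is the coefficient of variation of the multiplicative
    day-to-day residual making measurement day a non-degenerate
    replicate (default 5%).
    """

    farm_sd: float
    cow_sd: float
    cow_period_sd: float
    day_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("farm_sd", "cow_sd", "cow_period_sd", "day_cv"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


#: invented variance components (none are reported); scaled to give SEM
#: magnitudes of the order of the study figures' error bars.
DEFAULT_VARIANCES: dict[str, VarianceSpec] = {
    "rmssd_a": VarianceSpec(0.4, 0.9, 0.45),
    "rmssd_r": VarianceSpec(0.4, 0.9, 0.45),
    "lying": VarianceSpec(12.0, 30.0, 18.0),
    "feeding": VarianceSpec(8.0, 20.0, 12.0),
    "standing_cubicle": VarianceSpec(8.0, 20.0, 12.0),
    "standing_walkway": VarianceSpec(8.0, 20.0, 12.0),
    "locomotion": VarianceSpec(8.0, 20.0, 12.0),
    "cortisol": VarianceSpec(1.0, 2.0, 1.0, day_cv=0.2),
}

#: latent truths are floored at this fraction of the period mean
POSITIVE_FLOOR_FRAC = 0.05


@dataclass(frozen=True)
class CohortSpec:
    n_farms: int = 3
    cows_per_farm: int = 12
    periods: tuple[str, ...] = PERIODS
    period_means: dict = field(default_factory=lambda: {
        r: dict(v) for r, v in DEFAULT_PERIOD_MEANS.items()})
    variances: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCES))

    def __post_init__(self) -> None:
        if self.n_farms < 1 or self.cows_per_farm < 1:
            raise SimulationError("need >= 1 farm and >= 1 cow per farm")
        for resp, means in self.period_means.items():
            for p, m in means.items():
                if m <= 0:
                    raise SimulationError(f"period mean {resp}/{p} must be > 0")
        behaviors = ("lying", "feeding", "standing_cubicle",
                     "standing_walkway", "locomotion")
        for p in self.periods:
            total = sum(self.period_means[b][p] for b in behaviors
                        if b in self.period_means)
            if total > 840.0:
                raise SimulationError(
                    f"behavior means in period {p} sum to {total:.1f} > 840 min")


def gen_cohort(spec: CohortSpec, seed) -> pd.DataFrame:
    """Per-cow, per-period latent true values for every response.

    latent = period mean + farm effect + cow-within-farm effect +
    cow-by-period effect, each drawn independently with the spec's sds
    and floored at a small positive fraction of the period mean.
    Columns: farm, cow, period, response, latent.
    """
    rng = np.random.default_rng(seed)
    farms = [f"farm{f + 1}" for f in range(spec.n_farms)]
    cows = {f: [f"{f}_cow{c + 1:02d}" for c in range(spec.cows_per_farm)]
            for f in farms}
    rows = []
    for resp, means in spec.period_means.items():
        v = spec.variances.get(resp, VarianceSpec(0.0, 0.0, 0.0, 0.0))
        farm_eff = dict(zip(farms, rng.normal(0.0, v.farm_sd, len(farms))
                            if v.farm_sd else np.zeros(len(farms))))
        for f in farms:
            cow_eff = rng.normal(0.0, v.cow_sd, spec.cows_per_farm) \
                if v.cow_sd else np.zeros(spec.cows_per_farm)
            for ci, cow in enumerate(cows[f]):
                cp = rng.normal(0.0, v.cow_period_sd, len(spec.periods)) \
                    if v.cow_period_sd else np.zeros(len(spec.periods))
                for pi, p in enumerate(spec.periods):
                    mu = means[p]
                    latent = mu + farm_eff[f] + cow_eff[ci] + cp[pi]
                    latent = max(latent, POSITIVE_FLOOR_FRAC * mu)
                    rows.append((f, cow, p, resp, latent))
    return pd.DataFrame(rows, columns=["farm", "cow", "period", "response", "latent"])


def gen_records(cohort: pd.DataFrame, response: str, days, seed,
                day_cv: float | None = None,
                variances: dict | None = None) -> pd.DataFrame:
    """Observed values per cow-period-day: latent times a multiplicative
    Gaussian day residual with the response's day CV."""
    if day_cv is None:
        vs = (variances or DEFAULT_VARIANCES).get(response)
        day_cv = vs.day_cv if vs is not None else 0.05
    rng = np.random.default_rng(seed)
    sub = cohort[cohort["response"] == response]
    rows = []
    for _, r in sub.iterrows():
        for d in days:
            noise = 1.0 + day_cv * rng.standard_normal()
            value = max(r["latent"] * noise, POSITIVE_FLOOR_FRAC * r["latent"])
            rows.append((r["farm"], r["cow"], r["period"], d, value))
    return pd.DataFrame(rows, columns=["farm", "cow", "period", "day", "value"])


# ---------------------------------------------------------------------------
# interbeat intervals

def gen_ibi(true_rmssd: float, mean_ibi: float, duration_s: float, seed,
            cow: str = "cow", farm: str = "farm", session: str = "sim",
            start: datetime | None = None) -> IBISeries:
    """I.i.d. truncated-Gaussian interbeat intervals (ms).

    sd = true_rmssd / sqrt(2), so E[(x_{i+1} - x_i)^2] = true_rmssd^2
    and the long-run RMSSD equals ``true_rmssd``.  Intervals are
    truncated to (0.5, 1.5) x mean_ibi; cumulative duration reaches at
    least ``duration_s``.
    """
    if true_rmssd <= 0 or mean_ibi <= 0:
        raise SimulationError("true_rmssd and mean_ibi must be > 0")
    if duration_s < 300:
        raise SimulationError("duration must be >= 300 s (one analysis window)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = true_rmssd / math.sqrt(2.0)
    intervals = _draw_intervals(rng, mean_ibi, sd, duration_s * 1000.0)
    return IBISeries(cow=cow, farm=farm, session=session,
                     start=start or datetime(2013, 1, 7, 12, 0, 0),
                     intervals=intervals)


def _draw_intervals(rng: np.random.Generator, mean_ibi: float, sd: float,
                    duration_ms: float) -> np.ndarray:
    lo, hi = 0.5 * mean_ibi, 1.5 * mean_ibi
    chunks = []
    total = 0.0
    n_guess = max(16, int(duration_ms / mean_ibi * 1.05) + 8)
    while total < duration_ms:
        x = rng.normal(mean_ibi, sd, n_guess) if sd else np.full(n_guess, mean_ibi)
        bad = (x <= lo) | (x >= hi)
        while bad.any():  # resample outside the truncation band
            x[bad] = rng.normal(mean_ibi, sd, int(bad.sum()))
            bad = (x <= lo) | (x >= hi)
        chunks.append(x)
        total += float(x.sum())
        n_guess = max(16, int((duration_ms - total) / mean_ibi) + 8)
    arr = np.concatenate(chunks)
    cum = np.cumsum(arr)
    stop = int(np.searchsorted(cum, duration_ms)) + 1
    return arr[:stop]


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates are expected fractions of intervals affected per mechanism.

    The default total contamination of 2% sits below the 5% window QC
    threshold; :func:`stress_preset` (8%) sits above it to exercise
    window rejection.
    """

    outlier_rate: float = 0.005
    jitter_rate: float = 0.005
    missed_rate: float = 0.005
    spurious_rate: float = 0.005
    jitter_frac: float = 0.30

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "jitter_rate", "missed_rate",
                     "spurious_rate"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not (0.2 < self.jitter_frac < 0.5):
            raise SimulationError("jitter_frac must exceed the 20% detection "
                                  "threshold and stay below 0.5")

    @property
    def total_rate(self) -> float:
        return (self.outlier_rate + self.jitter_rate + self.missed_rate
                + self.spurious_rate)


def stress_preset() -> ArtifactSpec:
    """8% contamination: above the 5% window-rejection threshold."""
    return ArtifactSpec(outlier_rate=0.02, jitter_rate=0.02,
                        missed_rate=0.02, spurious_rate=0.02)


def _pick_sites(rng: np.random.Generator, n: int, counts: dict) -> list:
    """Uniform contamination sites with >= 3-interval separation,
    away from the series boundary."""
    total_events = sum(counts.values())
    if total_events == 0:
        return []
    candidates = np.arange(2, n - 3)
    if total_events * 3 > candidates.size:
        raise SimulationError(
            f"requested {total_events} contamination events exceed feasible "
            f"non-adjacent sites in a series of {n} intervals")
    order = rng.permutation(candidates)
    taken = np.zeros(n, dtype=bool)
    mechanisms = [m for m, k in counts.items() for _ in range(k)]
    rng.shuffle(mechanisms)
    sites = []
    for idx in order:
        if len(sites) == total_events:
            break
        lo, hi = max(0, idx - 3), min(n, idx + 4)
        if not taken[lo:hi].any():
            taken[idx] = True
            sites.append(int(idx))
    if len(sites) < total_events:
        raise SimulationError("could not place all contamination events "
                              "without adjacency conflicts")
    return sorted(zip(sites, mechanisms[:len(sites)]))


def inject_artifacts(series: IBISeries, spec: ArtifactSpec,
                     seed) -> tuple[IBISeries, list[tuple[int, str]]]:
    """Contaminate a clean series; returns (contaminated, ground truth).

    Ground truth lists ``(index_in_contaminated_series, mechanism)`` for
    every modified interval.  Every mechanism conserves the total
    beat-train duration: the single-outlier deficit is spread uniformly
    (sub-ms) over the unmodified intervals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = series.intervals
    n = x.size
    counts = {
        "missed_beat": rng.binomial(n, spec.missed_rate / 2.0),
        "spurious_beat": rng.binomial(n, spec.spurious_rate),
        "boundary_jitter": rng.binomial(n, spec.jitter_rate / 2.0),
        "single_outlier": rng.binomial(n, spec.outlier_rate),
    }
    events = dict(_pick_sites(rng, n, counts))
    out: list[float] = []
    truth: list[tuple[int, str]] = []
    modified: list[bool] = []
    outlier_deficit = 0.0
    i = 0
    while i < n:
        mech = events.get(i)
        if mech is None:
            out.append(float(x[i]))
            modified.append(False)
            i += 1
            continue
        if mech == "missed_beat":
            truth.append((len(out), mech))
            out.append(float(x[i] + x[i + 1]))
            modified.append(True)
            i += 2
        elif mech == "spurious_beat":
            u = rng.uniform(0.3, 0.7)
            truth.extend([(len(out), mech), (len(out) + 1, mech)])
            out.extend([float(u * x[i]), float((1 - u) * x[i])])
            modified.extend([True, True])
            i += 1
        elif mech == "boundary_jitter":
            delta = float(rng.choice([-1.0, 1.0]) * spec.jitter_frac * x[i])
            truth.extend([(len(out), mech), (len(out) + 1, mech)])
            out.extend([float(x[i] + delta), float(x[i + 1] - delta)])
            modified.extend([True, True])
            i += 2
        elif mech == "single_outlier":
            lo, hi = (1.35, 1.60) if rng.random() < 0.5 else (0.50, 0.70)
            factor = rng.uniform(lo, hi)
            truth.append((len(out), mech))
            out.append(float(factor * x[i]))
            modified.append(True)
            outlier_deficit += float((1.0 - factor) * x[i])
            i += 1
    arr = np.array(out)
    if outlier_deficit:
        free = ~np.array(modified)
        if free.any():
            arr[free] += outlier_deficit / free.sum()
    return series.with_intervals(arr), truth


# ---------------------------------------------------------------------------
# behavior

#: mean bout durations (min) per ethogram state
DEFAULT_BOUT_MEANS = {
    "lying": 40.0,
    "feeding": 20.0,
    "standing_cubicle": 10.0,
    "standing_walkway": 10.0,
    "locomotion": 2.0,
    "other": 5.0,
}


def gen_behavior_log(budgets: dict, schedule: ObservationSchedule | None,
                     seed, cow: str = "cow", farm: str = "farm",
                     day_date: date | None = None,
                     bout_means: dict | None = None) -> pd.DataFrame:
    """Alternating-renewal behavior bouts over the observation windows.

    ``budgets`` maps behaviors to expected minutes over the observed
    day (remainder is ``other``).  Bout durations are exponential with
    behavior-specific means; the state sequence starts in its
    stationary law, so expected occupancy equals the budget exactly.
    """
    schedule = schedule or ObservationSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bout_means = dict(DEFAULT_BOUT_MEANS, **(bout_means or {}))
    T = schedule.total_observation_minutes
    used = sum(budgets.values())
    if used > T + 1e-9:
        raise SimulationError(f"budgets sum to {used:.2f} > {T:.0f} observable min")
    occ = dict(budgets)
    occ["other"] = occ.get("other", 0.0) + (T - used)
    states = [b for b, m in occ.items() if m > 0]
    pi = np.array([occ[b] for b in states]) / T
    jump = np.array([occ[b] / bout_means[b] for b in states])
    jump = jump / jump.sum()

    # virtual stationary timeline on [0, T)
    segs: list[tuple[float, float, str]] = []
    t = 0.0
    state = states[rng.choice(len(states), p=pi)]
    while t < T:
        dwell = rng.exponential(bout_means[state])
        segs.append((t, min(t + dwell, T), state))
        t += dwell
        state = states[rng.choice(len(states), p=jump)]

    # map the virtual timeline onto the clock windows
    day_date = day_date or date(2013, 1, 7)
    anchor = datetime(day_date.year, day_date.month, day_date.day)
    offsets = []
    acc = 0.0
    for w in sorted(schedule.behavior_windows, key=lambda w: w.start):
        offsets.append((acc, acc + w.minutes, w.start))
        acc += w.minutes
    rows = []
    for a, b, st in segs:
        for v0, v1, clock0 in offsets:
            lo, hi = max(a, v0), min(b, v1)
            if hi > lo:
                s = anchor + timedelta(minutes=clock0 + (lo - v0))
                e = anchor + timedelta(minutes=clock0 + (hi - v0))
                rows.append((cow, farm, st, s, e))
    return pd.DataFrame(rows, columns=["cow", "farm", "behavior", "start", "end"])


# ---------------------------------------------------------------------------
# robot distance

def gen_robot_distance(schedule: ObservationSchedule | None, speed_m_per_min: float,
                       seed, cow: str = "cow", farm: str = "farm",
                       day_date: date | None = None,
                       cow_pos: tuple[float, float] | None = None,
                       pen: tuple[float, float] = (25.0, 10.0),
                       sample_s: float = 1.0) -> pd.DataFrame:
    """Robot-to-cow distance over the proximity window, 1-s sampling.

    The robot follows the rectangular pen perimeter at constant speed;
    the cow lies at a fixed interior position, so each full route pass
    has a unique distance minimum and maximum (the cow position is kept
    off the pen symmetry axes).  ``pass_id`` counts completed loops.
    """
    if speed_m_per_min <= 0:
        raise SimulationError("speed must be > 0")
    schedule = schedule or ObservationSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W, L = pen
    if cow_pos is None:
        # interior, jittered off the symmetry axes
        cow_pos = (W * rng.uniform(0.15, 0.45), L * rng.uniform(0.55, 0.85))
    perimeter = 2.0 * (W + L)
    window = schedule.proximity_window
    day_date = day_date or date(2013, 1, 7)
    anchor = datetime(day_date.year, day_date.month, day_date.day)
    t0 = anchor + timedelta(minutes=window.start)
    n = int(window.minutes * 60.0 / sample_s)
    tsec = np.arange(n) * sample_s
    offset = rng.uniform(0.0, perimeter)
    arc = (offset + speed_m_per_min * tsec / 60.0)
    pass_id = ((arc - offset) // perimeter).astype(int)
    s = np.mod(arc, perimeter)
    xr = np.empty(n)
    yr = np.empty(n)
    m1 = s < W
    m2 = (s >= W) & (s < W + L)
    m3 = (s >= W + L) & (s < 2 * W + L)
    m4 = s >= 2 * W + L
    xr[m1], yr[m1] = s[m1], 0.0
    xr[m2], yr[m2] = W, s[m2] - W
    xr[m3], yr[m3] = W - (s[m3] - W - L), L
    xr[m4], yr[m4] = 0.0, L - (s[m4] - 2 * W - L)
    dist = np.hypot(xr - cow_pos[0], yr - cow_pos[1])
    times = [t0 + timedelta(seconds=float(t)) for t in tsec]
    return pd.DataFrame({
        "cow": cow, "farm": farm, "day_key": day_date.isoformat(),
        "time": times, "distance_m": dist, "pass_id": pass_id,
    })


# ---------------------------------------------------------------------------
# cortisol

def gen_cortisol(latent: float, cv: float, seed, n_samples: int = 3) -> np.ndarray:
    """Log-normal 11,17-DOA samples with median ``latent`` and
    log-scale sd ``log(1 + cv)``."""
    if latent <= 0:
        raise SimulationError("latent concentration must be > 0")
    if cv < 0:
        raise SimulationError("cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = math.log1p(cv)
    return latent * np.exp(sigma * rng.standard_normal(n_samples))


# ---------------------------------------------------------------------------
# full study simulation

#: state-dependent mean interbeat interval (ms): shorter while active
MEAN_IBI = {"active": 750.0, "rest": 900.0}
#: robot working speed per farm (m/min)
ROBOT_SPEED = {"farm1": 4.0, "farm2": 4.0, "farm3": 5.5}


def _segments_from_events(events: pd.DataFrame, window: ClockWindow,
                          anchor: datetime) -> list[tuple[datetime, datetime, str]]:
    """Partition the window into rest (lying) and active segments."""
    w0 = anchor + timedelta(minutes=window.start)
    w1 = anchor + timedelta(minutes=window.end)
    segs = []
    lying = events[events["behavior"] == "lying"].sort_values("start")
    cursor = w0
    for _, ev in lying.iterrows():
        s = max(ev["start"].to_pydatetime(), w0)
        e = min(ev["end"].to_pydatetime(), w1)
        if e <= s:
            continue
        if s > cursor:
            segs.append((cursor, s, "active"))
        segs.append((s, e, "rest"))
        cursor = e
    if cursor < w1:
        segs.append((cursor, w1, "active"))
    return segs


def gen_day_session(events: pd.DataFrame, rmssd_active: float, rmssd_rest: float,
                    window: ClockWindow, rng, cow: str, farm: str,
                    session: str, anchor: datetime) -> IBISeries:
    """IBI series covering a schedule window, piecewise by behavior:
    lying segments use the rest RMSSD/mean, everything else the active
    parameters."""
    parts = []
    for s, e, state in _segments_from_events(events, window, anchor):
        dur_ms = (e - s).total_seconds() * 1000.0
        if dur_ms <= 0:
            continue
        target = rmssd_rest if state == "rest" else rmssd_active
        sd = target / math.sqrt(2.0)
        parts.append(_draw_intervals(rng, MEAN_IBI[state if state == "rest" else "active"],
                                     sd, dur_ms))
    intervals = np.concatenate(parts)
    start = anchor + timedelta(minutes=window.start)
    return IBISeries(cow=cow, farm=farm, session=session, start=start,
                     intervals=intervals)


def study_dates(periods=PERIODS, first: date = date(2013, 1, 7)) -> dict[str, date]:
    """Calendar anchor (day 1) of each experimental period; periods are
    a week apart with a skipped week before the last test period."""
    gaps = {0: 0, 1: 7, 2: 14, 3: 28}
    return {p: first + timedelta(days=gaps[i]) for i, p in enumerate(periods)}


def simulate_study(config: RunConfig, seed: int | None = None,
                   cohort_spec: CohortSpec | None = None,
                   artifacts: ArtifactSpec | None = None,
                   with_ibi: bool = True, with_distance: bool = True,
                   distance_sample_s: float = 5.0) -> dict:
    """Generate a full synthetic study in memory.

    Returns a dict with keys ``cohort`` (latent truth), ``behavior``
    (event log), ``ibi`` (list of IBISeries), ``distance``,
    ``cortisol`` and ``cow_positions``.
    """
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    keys = ("cohort", "behavior", "ibi", "distance", "cortisol")
    rngs = {k: np.random.default_rng(s)
            for k, s in zip(keys, root.spawn(len(keys)))}
    spec = cohort_spec or CohortSpec(n_farms=config.n_farms,
                                     cows_per_farm=config.n_cows_per_farm,
                                     periods=config.periods)
    art = artifacts or ArtifactSpec()
    cohort = gen_cohort(spec, rngs["cohort"])
    latent = cohort.set_index(["farm", "cow", "period", "response"])["latent"]
    anchors = study_dates(config.periods)
    sched = config.schedule

    behavior_rows = []
    ibi_series: list[IBISeries] = []
    distance_rows = []
    cortisol_rows = []
    cow_positions = {}
    behaviors = ("lying", "feeding", "standing_cubicle", "standing_walkway",
                 "locomotion")
    farms = sorted(cohort["farm"].unique())
    for farm in farms:
        cows = sorted(cohort.loc[cohort["farm"] == farm, "cow"].unique())
        for cow in cows:
            W, L = 25.0, 10.0
            cow_positions[(farm, cow)] = (W * rngs["distance"].uniform(0.15, 0.45),
                                          L * rngs["distance"].uniform(0.55, 0.85))
            for period in config.periods:
                day1 = anchors[period]
                budgets = {b: float(latent[(farm, cow, period, b)])
                           for b in behaviors if (farm, cow, period, b) in latent.index}
                # random cow effects can push the latent shares past the
                # observable day; rescale to leave some 'other' time
                cap = 0.97 * sched.total_observation_minutes
                total = sum(budgets.values())
                if total > cap:
                    budgets = {b: v * cap / total for b, v in budgets.items()}
                for day in config.measurement_days:
                    d = day1 + timedelta(days=day - 1)
                    events = gen_behavior_log(budgets, sched, rngs["behavior"],
                                              cow=cow, farm=farm, day_date=d)
                    events["period"] = period
                    events["day"] = day
                    behavior_rows.append(events)
                    anchor = datetime(d.year, d.month, d.day)
                    if with_ibi:
                        r_a = float(latent[(farm, cow, period, "rmssd_a")])
                        r_r = float(latent[(farm, cow, period, "rmssd_r")])
                        day_s = gen_day_session(events, r_a, r_r,
                                                sched.proximity_window,
                                                rngs["ibi"], cow, farm,
                                                f"{period}-d{day}-day", anchor)
                        sd = r_r / math.sqrt(2.0)
                        night_iv = _draw_intervals(
                            rngs["ibi"], MEAN_IBI["rest"], sd,
                            sched.rest_window.minutes * 60000.0)
                        night_s = IBISeries(
                            cow=cow, farm=farm, session=f"{period}-d{day}-night",
                            start=anchor + timedelta(minutes=sched.rest_window.start),
                            intervals=night_iv)
                        for s in (day_s, night_s):
                            contaminated, _ = inject_artifacts(s, art, rngs["ibi"])
                            ibi_series.append(contaminated)
                    if with_distance and period != config.periods[0]:
                        distance_rows.append(gen_robot_distance(
                            sched, ROBOT_SPEED.get(farm, 4.0), rngs["distance"],
                            cow=cow, farm=farm, day_date=d,
                            cow_pos=cow_positions[(farm, cow)],
                            sample_s=distance_sample_s))
                c_latent = float(latent[(farm, cow, period, "cortisol")])
                cv = spec.variances.get("cortisol", DEFAULT_VARIANCES["cortisol"]).day_cv
                values = gen_cortisol(c_latent, cv, rngs["cortisol"],
                                      n_samples=len(config.cortisol_days))
                for day, v in zip(config.cortisol_days, values):
                    cortisol_rows.append((cow, farm, period, day, float(v)))

    behavior = pd.concat(behavior_rows, ignore_index=True) if behavior_rows \
        else pd.DataFrame(columns=["cow", "farm", "behavior", "start", "end"])
    distance = pd.concat(distance_rows, ignore_index=True) if distance_rows \
        else pd.DataFrame(columns=["cow", "farm", "day_key", "time",
                                   "distance_m", "pass_id"])
    cortisol = pd.DataFrame(cortisol_rows,
                            columns=["cow", "farm", "period", "day", "concentration"])
    return {"cohort": cohort, "behavior": behavior, "ibi": ibi_series,
            "distance": distance, "cortisol": cortisol,
            "cow_positions": cow_positions}
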