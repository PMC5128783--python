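"""Period-contrast analyses: transform, REML fit, outlier pass, t-tests.

Responses are variance-stabilised before fitting (HRV double-log,
cortisol metabolites log, standing behaviors square-root, everything
else identity).  After an initial fit, observations whose standardized
marginal residuals fall outside the two-sided 99% band of the standard
normal (|z| > 2.576) are removed in a single pass and the model is
refitted once.  All six pairwise period contrasts are tested on the
transformed scale; per-period descriptive means and SEMs are reported
on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .config import PERIODS, RunConfig
from .lmm import OUTLIER_Z, Contrast, ModelError, VCMixedModel, VCMixedModelResults

TRANSFORMS = ("double_log", "log", "sqrt", "identity")


class TransformError(ValueError):
    pass


def apply_transform(values, kind: str) -> np.ndarray:
    """double_log = ln(ln(x)) (x > 1), log = ln(x) (x > 0),
    sqrt (x >= 0), identity."""
    x = np.asarray(values, dtype=float)
    if kind == "identity":
        return x.copy()
    if kind == "log":
        bad = np.flatnonzero(x <= 0)
        if bad.size:
            raise TransformError(
                f"log transform requires values > 0; observation {bad[0]} "
                f"is {x[bad[0]]!r}")
        return np.log(x)
    if kind == "double_log":
        bad = np.flatnonzero(x <= 1)
        if bad.size:
            raise TransformError(
                f"double log transform requires values > 1; observation "
                f"{bad[0]} is {x[bad[0]]!r}")
        return np.log(np.log(x))
    if kind == "sqrt":
        bad = np.flatnonzero(x < 0)
        if bad.size:
            raise TransformError(
                f"sqrt transform requires values >= 0; observation {bad[0]} "
                f"is {x[bad[0]]!r}")
        return np.sqrt(x)
    raise TransformError(f"unknown transform {kind!r}; expected one of {TRANSFORMS}")


@dataclass
class AnalysisResult:
    """Contrast table plus descriptives for one response."""

    response: str
    transform: str
    contrasts: list[Contrast]
    period_means: pd.DataFrame
    fit: VCMixedModelResults
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def contrast_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "contrast": c.name, "estimate": c.estimate, "se": c.se,
            "tstat": c.tstat, "df": c.df, "pvalue": c.pvalue,
        } for c in self.contrasts])

    def summary(self) -> str:
        lines = [f"Response: {self.response}  (transform: {self.transform}, "
                 f"n = {self.fit.nobs}, removed = {self.n_removed})",
                 "", self.period_means.to_string(index=False), ""]
        lines.append(self.contrast_table().to_string(index=False))
        return "\n".join(lines)


def fit_lmm(table: pd.DataFrame, response_col: str = "value",
            fixed: dict | None = None,
            interaction: tuple[str, str] | None = None) -> VCMixedModelResults:
    """REML fit with the study's random structure (farm, cow within
    farm, cow x period)."""
    fixed = fixed or {"period": [p for p in PERIODS if p in set(table["period"])]}
    model = VCMixedModel.from_dataframe(table, response_col, fixed,
                                        interaction=interaction)
    return model.fit()


def remove_outliers_refit(table: pd.DataFrame, response_col: str = "value",
                          fixed: dict | None = None,
                          interaction: tuple[str, str] | None = None,
                          z_crit: float = OUTLIER_Z,
                          ) -> tuple[VCMixedModelResults, pd.DataFrame, pd.DataFrame]:
    """Single-pass residual trim: fit, drop |z| > z_crit, refit once.

    Returns (refit results, retained table, removed rows).  Raises if
    removal would empty a period or farm level.
    """
    first = fit_lmm(table, response_col, fixed, interaction)
    z = first.standardized_residuals()
    keep = np.abs(z) <= z_crit
    removed = table.loc[~keep].copy()
    removed["std_resid"] = z[~keep]
    if keep.all():
        return first, table, removed
    kept = table.loc[keep]
    for col in ("period", "farm"):
        lost = set(table[col].unique()) - set(kept[col].unique())
        if lost:
            raise ModelError(f"outlier removal empties {col} level(s) {lost}")
    refit = fit_lmm(kept, response_col, fixed, interaction)
    return refit, kept, removed


def _period_descriptives(table: pd.DataFrame, periods) -> pd.DataFrame:
    rows = []
    for p in periods:
        vals = table.loc[table["period"] == p, "raw"].to_numpy()
        rows.append({
            "period": p, "n": vals.size,
            "mean": float(np.mean(vals)) if vals.size else np.nan,
            "sem": float(np.std(vals, ddof=1) / np.sqrt(vals.size))
            if vals.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def run_period_analysis(records: pd.DataFrame, response: str,
                        config: RunConfig | None = None,
                        value_col: str = "value") -> AnalysisResult:
    """Full treatment of one response: transform, fit, one outlier
    pass, refit, all six pairwise period contrasts plus raw-scale
    period means and SEMs."""
    config = config or RunConfig()
    periods = [p for p in config.periods if p in set(records["period"])]
    kind = config.transform_for(response)
    table = records.copy().reset_index(drop=True)
    table["raw"] = table[value_col].astype(float)
    table["value"] = apply_transform(table["raw"].to_numpy(), kind)
    fixed = {"period": periods}
    fit, kept, removed = remove_outliers_refit(table, "value", fixed)
    contrasts = [
        fit.contrast({"period": b}, {"period": a}, name=f"{a} vs {b}")
        for a, b in combinations(periods, 2)
    ]
    means = _period_descriptives(kept, periods)
    return AnalysisResult(response=response, transform=kind,
                          contrasts=contrasts, period_means=means,
                          fit=fit, removed=removed)


def run_proximity_analysis(pairs: pd.DataFrame,
                           config: RunConfig | None = None) -> AnalysisResult:
    """Near/far robot-position model for lying cows in the test periods.

    ``pairs`` has one row per cow-day with near_rmssd/far_rmssd; it is
    reshaped to one row per 5-min window with a position label.  The
    double-log model has position, period and their interaction as
    fixed effects and the standard random structure; the contrasts are
    near minus far within each test period.
    """
    config = config or RunConfig()
    rows = []
    for _, r in pairs.iterrows():
        for pos in ("near", "far"):
            rows.append({
                "farm": r["farm"], "cow": r["cow"], "period": r["period"],
                "day": r["day"], "position": pos,
                "raw": float(r[f"{pos}_rmssd"]),
            })
    table = pd.DataFrame(rows)
    periods = [p for p in config.periods if p in set(table["period"])]
    kind = config.transform_for("rmssd")
    table["value"] = apply_transform(table["raw"].to_numpy(), kind)
    fixed = {"position": ["far", "near"], "period": periods}
    fit, kept, removed = remove_outliers_refit(
        table, "value", fixed, interaction=("position", "period"))
    contrasts = [
        fit.contrast({"position": "near", "period": p},
                     {"position": "far", "period": p},
                     name=f"near vs far ({p})")
        for p in periods
    ]
    means = []
    for p in periods:
        for pos in ("far", "near"):
            vals = kept.loc[(kept["period"] == p) & (kept["position"] == pos),
                            "raw"].to_numpy()
            means.append({"period": p, "position": pos, "n": vals.size,
                          "mean": float(np.mean(vals)) if vals.size else np.nan,
                          "sem": float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                          if vals.size > 1 else np.nan})
    return AnalysisResult(response="rmssd_proximity", transform=kind,
                          contrasts=contrasts, period_means=pd.DataFrame(means),
                          fit=fit, removed=removed)
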