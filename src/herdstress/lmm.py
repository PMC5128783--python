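"""REML linear mixed-effects model with variance components.

The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma_e^2 I)

with independent random-intercept blocks (here: farm, cow within farm,
cow-by-period).  Estimation maximises the restricted likelihood with
the residual variance profiled out; variance components are
constrained non-negative.  Fixed-effect contrasts are tested with
t-statistics whose degrees of freedom come from the Satterthwaite
approximation: df = 2 (c' C c)^2 / Var[c' C c], where C is the
fixed-effect covariance as a function of the variance components and
the variance in the denominator is obtained by the delta method over
the inverse observed information of the restricted log-likelihood.

This mirrors the lme4 + lmerTest analysis route in spirit while being
self-contained; an independent implementation is used as a
cross-check in the test-suite, never as the engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats


class ModelError(ValueError):
    pass


OUTLIER_Z = 2.5758293035489004  # two-sided 99% point of the standard normal


# ---------------------------------------------------------------------------
# treatment-coded fixed-effect design

class FixedDesign:
    """Treatment (reference-level) coding for categorical factors with
    an optional all-pairs interaction between two factors."""

    def __init__(self, factors: dict[str, list], interaction: tuple[str, str] | None = None):
        self.factors = {k: list(v) for k, v in factors.items()}
        self.interaction = interaction
        self.terms: list[tuple[str, dict]] = [("Intercept", {})]
        for col, levels in self.factors.items():
            for lvl in levels[1:]:
                self.terms.append((f"{col}[{lvl}]", {col: lvl}))
        if interaction is not None:
            a, b = interaction
            for la in self.factors[a][1:]:
                for lb in self.factors[b][1:]:
                    self.terms.append((f"{a}[{la}]:{b}[{lb}]", {a: la, b: lb}))

    @property
    def names(self) -> list[str]:
        return [t[0] for t in self.terms]

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        X = np.ones((n, len(self.terms)))
        for j, (_, cond) in enumerate(self.terms):
            for col, lvl in cond.items():
                X[:, j] *= (data[col].to_numpy() == lvl)
        return X

    def row(self, levels: dict) -> np.ndarray:
        out = np.ones(len(self.terms))
        for j, (_, cond) in enumerate(self.terms):
            for col, lvl in cond.items():
                out[j] *= float(levels.get(col) == lvl)
        return out


def _indicator(labels) -> np.ndarray:
    labels = pd.Series(labels).astype(str)
    levels = sorted(labels.unique())
    Z = np.zeros((len(labels), len(levels)))
    index = {l: i for i, l in enumerate(levels)}
    for i, l in enumerate(labels):
        Z[i, index[l]] = 1.0
    return Z


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """A fixed-effect contrast with a Satterthwaite t-test."""

    name: str
    estimate: float
    se: float
    tstat: float
    df: float
    pvalue: float


class VCMixedModel:
    """Variance-components linear mixed model, REML.

    Parameters
    ----------
    endog : response vector.
    design : FixedDesign for the fixed effects.
    data : DataFrame holding the factor columns.
    vc_columns : mapping name -> grouping column for each random
        intercept block (e.g. farm, cow, cow_period).
    """

    def __init__(self, endog, design: FixedDesign, data: pd.DataFrame,
                 vc_columns: dict[str, str]):
        self.y = np.asarray(endog, dtype=float)
        self.design = design
        self.data = data.reset_index(drop=True)
        self.X = design.matrix(self.data)
        n, p = self.X.shape
        if n <= p:
            raise ModelError(f"n = {n} observations cannot identify {p} fixed effects")
        if np.linalg.matrix_rank(self.X) < p:
            raise ModelError("singular fixed-effect design")
        self.vc_names = list(vc_columns)
        self.Z = {k: _indicator(self.data[col]) for k, col in vc_columns.items()}
        for k, Zk in self.Z.items():
            if Zk.shape[1] < 2:
                raise ModelError(f"random effect {k!r} needs >= 2 levels")
        self.G = {k: Zk @ Zk.T for k, Zk in self.Z.items()}
        self.n, self.p = n, p

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       fixed: dict[str, list],
                       interaction: tuple[str, str] | None = None,
                       vc_columns: dict[str, str] | None = None) -> "VCMixedModel":
        """Build from a long table.

        ``fixed`` maps factor columns to their ordered levels (first =
        reference).  ``vc_columns`` defaults to the study's random
        structure: farm, cow within farm, cow x period (a ``cow_period``
        column is derived if absent).
        """
        data = data.reset_index(drop=True).copy()
        if vc_columns is None:
            if "cow_period" not in data.columns:
                data["cow_period"] = (data["cow"].astype(str) + ":"
                                      + data["period"].astype(str))
            vc_columns = {"farm": "farm", "cow": "cow", "cow_period": "cow_period"}
        design = FixedDesign(fixed, interaction)
        return cls(data[response], design, data, vc_columns)

    # -- restricted likelihood ---------------------------------------------

    def _profile(self, gamma: np.ndarray):
        """Profiled REML pieces at variance ratios gamma = sigma_k^2/sigma_e^2."""
        V0 = np.eye(self.n)
        for g, k in zip(gamma, self.vc_names):
            if g:
                V0 += g * self.G[k]
        c, low = linalg.cho_factor(V0, lower=True, check_finite=False)
        logdetV0 = 2.0 * float(np.sum(np.log(np.diag(c))))
        Xs = linalg.cho_solve((c, low), self.X, check_finite=False)
        ys = linalg.cho_solve((c, low), self.y, check_finite=False)
        XtVX = self.X.T @ Xs
        beta = np.linalg.solve(XtVX, self.X.T @ ys)
        r = self.y - self.X @ beta
        quad = float(r @ linalg.cho_solve((c, low), r, check_finite=False))
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            raise ModelError("X'V^-1X not positive definite")
        return beta, XtVX, quad, logdetV0, logdetXtVX

    def _neg2_profiled(self, gamma: np.ndarray) -> float:
        try:
            _, _, quad, ld0, ldx = self._profile(np.maximum(gamma, 0.0))
        except (np.linalg.LinAlgError, ModelError):
            return 1e12
        nmp = self.n - self.p
        return ld0 + ldx + nmp * np.log(quad / nmp)

    def reml_loglik(self, variances: np.ndarray) -> float:
        """Restricted log-likelihood at absolute variances
        (sigma_1^2 .. sigma_K^2, sigma_e^2), constants included."""
        *vcs, s2e = variances
        V = s2e * np.eye(self.n)
        for v, k in zip(vcs, self.vc_names):
            V += v * self.G[k]
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
        Xs = linalg.cho_solve((c, low), self.X, check_finite=False)
        ys = linalg.cho_solve((c, low), self.y, check_finite=False)
        XtVX = self.X.T @ Xs
        beta = np.linalg.solve(XtVX, self.X.T @ ys)
        r = self.y - self.X @ beta
        quad = float(r @ linalg.cho_solve((c, low), r, check_finite=False))
        _, logdetXtVX = np.linalg.slogdet(XtVX)
        nmp = self.n - self.p
        return -0.5 * (logdetV + logdetXtVX + quad + nmp * np.log(2.0 * np.pi))

    def fe_cov(self, variances: np.ndarray) -> np.ndarray:
        """Fixed-effect covariance (X'V(theta)^-1 X)^-1 at absolute
        variances."""
        *vcs, s2e = variances
        V = s2e * np.eye(self.n)
        for v, k in zip(vcs, self.vc_names):
            V += v * self.G[k]
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        Xs = linalg.cho_solve((c, low), self.X, check_finite=False)
        return np.linalg.inv(self.X.T @ Xs)

    # -- fitting -------------------------------------------------------------

    def fit(self, starts=None, tol: float = 1e-10) -> "VCMixedModelResults":
        """REML fit by bounded quasi-Newton over the variance ratios,
        multi-started from zero-ish and moment-scale points; the best
        optimum wins (deterministic given the data)."""
        K = len(self.vc_names)
        if starts is None:
            base = [np.full(K, 1e-4), np.full(K, 0.5), np.full(K, 2.0)]
            # crude moment start: share total variance equally
            starts = base
        best = None
        for g0 in starts:
            res = optimize.minimize(
                self._neg2_profiled, np.asarray(g0, dtype=float),
                method="L-BFGS-B", bounds=[(0.0, None)] * K,
                options={"ftol": tol, "gtol": 1e-9, "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ModelError("REML optimisation failed to converge")
        gamma = np.maximum(best.x, 0.0)
        beta, XtVX, quad, _, _ = self._profile(gamma)
        s2e = quad / (self.n - self.p)
        variances = np.append(gamma * s2e, s2e)
        return VCMixedModelResults(self, beta, variances, self.reml_loglik(variances))


class VCMixedModelResults:
    """REML estimates: fixed effects, variance components, contrasts.

    ``vcomp`` maps each random block (and ``"residual"``) to its
    estimated variance.  Boundary estimates (active non-negativity
    constraint) are reported as 0, never negative.
    """

    def __init__(self, model: VCMixedModel, beta: np.ndarray,
                 variances: np.ndarray, llf: float):
        self.model = model
        self.fe_params = pd.Series(beta, index=model.design.names)
        self.variances = variances
        self.vcomp = dict(zip(model.vc_names, variances[:-1]))
        self.scale = float(variances[-1])
        self.llf = float(llf)
        self._fecov = model.fe_cov(variances)
        self.bse = pd.Series(np.sqrt(np.diag(self._fecov)),
                             index=model.design.names)
        self._info_cache = None

    @property
    def nobs(self) -> int:
        return self.model.n

    # -- diagnostics ---------------------------------------------------------

    def marginal_residuals(self) -> np.ndarray:
        return self.model.y - self.model.X @ self.fe_params.to_numpy()

    def standardized_residuals(self) -> np.ndarray:
        """Marginal residuals scaled by the marginal sd of each
        observation, sqrt(diag(V-hat))."""
        *vcs, s2e = self.variances
        diag = np.full(self.model.n, s2e)
        for v, k in zip(vcs, self.model.vc_names):
            if v:
                diag += v * np.diag(self.model.G[k])
        return self.marginal_residuals() / np.sqrt(diag)

    # -- Satterthwaite contrasts ---------------------------------------------

    def _active_mask(self) -> np.ndarray:
        """Variance components treated as interior (off the zero
        boundary); the residual variance is always interior."""
        theta = self.variances
        tol = 1e-6 * max(theta[-1], 1e-12)
        mask = theta > tol
        mask[-1] = True
        return mask

    def _vc_information(self) -> tuple[np.ndarray, np.ndarray]:
        """Inverse observed information of the restricted
        log-likelihood over the interior variance components."""
        if self._info_cache is not None:
            return self._info_cache
        mask = self._active_mask()
        idx = np.flatnonzero(mask)
        theta = self.variances.copy()

        def ll(sub):
            t = theta.copy()
            t[idx] = sub
            return self.model.reml_loglik(t)

        sub0 = theta[idx]
        h = 1e-5 * np.maximum(np.abs(sub0), 1e-8)
        m = idx.size
        H = np.zeros((m, m))
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h[i]
                ej = np.zeros(m); ej[j] = h[j]
                if i == j:
                    f0 = ll(sub0)
                    fp = ll(sub0 + ei)
                    fm = ll(np.maximum(sub0 - ei, 0.0))
                    H[i, i] = (fp - 2 * f0 + fm) / (h[i] ** 2)
                else:
                    fpp = ll(sub0 + ei + ej)
                    fpm = ll(np.maximum(sub0 + ei - ej, 0.0))
                    fmp = ll(np.maximum(sub0 - ei + ej, 0.0))
                    fmm = ll(np.maximum(sub0 - ei - ej, 0.0))
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        info = -H
        try:
            W = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            W = np.linalg.pinv(info)
        self._info_cache = (idx, W)
        return self._info_cache

    def contrast(self, levels_a: dict, levels_b: dict,
                 name: str | None = None) -> Contrast:
        """Satterthwaite t-test of E[y | levels_a] - E[y | levels_b]
        on the model (transformed) scale."""
        c = self.model.design.row(levels_a) - self.model.design.row(levels_b)
        return self.contrast_vector(
            c, name or f"{levels_a} - {levels_b}")

    def contrast_vector(self, c: np.ndarray, name: str = "") -> Contrast:
        c = np.asarray(c, dtype=float)
        est = float(c @ self.fe_params.to_numpy())
        if not c.any():  # trivial contrast (a level against itself)
            return Contrast(name=name, estimate=0.0, se=0.0, tstat=0.0,
                            df=float(self.model.n - self.model.p), pvalue=1.0)
        theta = self.variances
        idx, W = self._vc_information()

        def A(sub):
            t = theta.copy()
            t[idx] = sub
            return float(c @ self.model.fe_cov(t) @ c)

        sub0 = theta[idx]
        a0 = A(sub0)
        if a0 <= 0:
            raise ModelError("non-positive contrast variance")
        h = 1e-5 * np.maximum(np.abs(sub0), 1e-8)
        grad = np.zeros(idx.size)
        for i in range(idx.size):
            e = np.zeros(idx.size); e[i] = h[i]
            grad[i] = (A(sub0 + e) - A(np.maximum(sub0 - e, 0.0))) / (2 * h[i])
        var_a = float(grad @ W @ grad)
        if var_a <= 0:
            df = float(self.model.n - self.model.p)
        else:
            df = 2.0 * a0 * a0 / var_a
            df = min(df, float(self.model.n - self.model.p))
        if df <= 0:
            raise ModelError(f"non-positive Satterthwaite df for contrast {name!r}")
        se = float(np.sqrt(a0))
        t = est / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        return Contrast(name=name, estimate=est, se=se, tstat=t, df=df,
                        pvalue=min(max(p, np.nextafter(0, 1)), 1.0))

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        lines = ["Variance-components mixed model (REML)",
                 f"  observations: {self.nobs}   REML log-likelihood: {self.llf:.4f}",
                 "", "  Fixed effects:"]
        for name in self.fe_params.index:
            lines.append(f"    {name:<28s} {self.fe_params[name]:>10.4f}"
                         f"  (SE {self.bse[name]:.4f})")
        lines.append("")
        lines.append("  Variance components:")
        for k, v in self.vcomp.items():
            note = "  (boundary)" if v <= 1e-6 * self.scale else ""
            lines.append(f"    {k:<28s} {v:>10.4f}{note}")
        lines.append(f"    {'residual':<28s} {self.scale:>10.4f}")
        return "\n".join(lines)
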