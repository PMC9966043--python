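"""Constrained linear mixed model (cLMM) for longitudinal trial outcomes.

The model: participant *i* in randomized group *g(i)* at site *s(i)* has an
observed visit sub-vector ``y_i`` (months 0/3/6, possibly incomplete) that
is multivariate normal with

    E[y_it] = mu0 + site_{s(i)} + delta[g(i), t],      delta[., baseline] = 0
    Cov[y_i] = Sigma[obs(i), obs(i)]

where the baseline mean ``mu0`` is *shared across groups* (justified by
randomization), ``delta[g, t]`` is group g's mean change from baseline at
visit t, site enters as reference-coded additive shifts, and ``Sigma`` is
an unstructured (or optionally compound-symmetric) T x T visit covariance
shared across groups.  Estimation is by REML with the fixed effects
profiled out; incomplete participants contribute their observed
sub-vectors, which handles MCAR/MAR missingness implicitly.

Inference on contrasts of the fixed effects uses Wald statistics with the
observed information and Satterthwaite-approximated degrees of freedom.

Usage::

    model = ConstrainedLMM(avg_table, outcome="al_mm")
    res = model.fit()
    res.group_difference("loading_dose", 6)   # WaldResult
    print(res.summary())
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .exceptions import ConvergenceWarning, RankError

__all__ = ["ConstrainedLMM", "CLMMResults", "WaldResult", "fit_clmm",
           "estimate_group_changes", "group_difference_in_change",
           "satterthwaite_df"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class WaldResult:
    """A Wald-type estimate with Satterthwaite df and 95% CI."""

    estimate: float
    se: float
    df: float
    statistic: float
    p: float
    ci_low: float
    ci_high: float

    def __str__(self):  # pragma: no cover - cosmetic
        return (f"{self.estimate:+.4f} (SE {self.se:.4f}, 95% CI "
                f"[{self.ci_low:+.4f}, {self.ci_high:+.4f}], df {self.df:.1f}, "
                f"p {self.p:.4g})")


def _chol_unstructured(theta: np.ndarray, t: int) -> np.ndarray:
    """Log-Cholesky parametrization: theta -> lower factor L, Sigma = L L'."""
    L = np.zeros((t, t))
    L[np.diag_indices(t)] = np.exp(theta[:t])
    if t > 1:
        L[np.tril_indices(t, -1)] = theta[t:]
    return L


def _theta_from_sigma(sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(sigma)
    t = sigma.shape[0]
    return np.concatenate([np.log(np.diag(L)), L[np.tril_indices(t, -1)]])


class ConstrainedLMM:
    """Baseline-constrained linear mixed model of one longitudinal outcome.

    Parameters
    ----------
    data : DataFrame
        Per-participant per-visit table (one averaged value per participant
        per visit) with columns ``pid``, ``month``, the group column, the
        site column, and `outcome`.
    outcome : str
        Column to model.
    visits : sequence of int, optional
        Ordered visit months; defaults to the sorted unique months.
    reference : str
        Reference group (placebo).
    constrain_baseline : bool
        Share the baseline mean across groups (the cLMM constraint).
    site_adjust : bool
        Add reference-coded additive site effects.
    covariance : {"unstructured", "cs"}
        Residual visit covariance structure, shared across groups.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, visits=None,
                 group_col: str = "arm", reference: str = "placebo",
                 subject_col: str = "pid", site_col: str = "site",
                 constrain_baseline: bool = True, site_adjust: bool = True,
                 covariance: str = "unstructured"):
        if covariance not in ("unstructured", "cs"):
            raise ValueError("covariance must be 'unstructured' or 'cs'")
        self.outcome = outcome
        self.constrain_baseline = constrain_baseline
        self.site_adjust = site_adjust
        self.covariance = covariance
        self.reference = reference

        df = data.dropna(subset=[outcome])
        self.visits = list(visits) if visits is not None else sorted(df["month"].unique())
        T = len(self.visits)
        if T < 1 or (constrain_baseline and T < 2):
            raise ValueError("need >=2 visits for the baseline constraint")
        df = df[df["month"].isin(self.visits)]

        groups = sorted(df[group_col].unique(), key=lambda g: (g != reference, str(g)))
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} not present")
        self.groups = groups

        wide = df.pivot_table(index=subject_col, columns="month",
                              values=outcome, aggfunc="mean")
        wide = wide.reindex(columns=self.visits)
        meta = df.drop_duplicates(subject_col).set_index(subject_col)
        meta = meta.loc[wide.index]
        self.subjects = wide.index.to_numpy()
        self.y = wide.to_numpy()                       # (n, T) with NaN
        self.group_idx = np.array([groups.index(g) for g in meta[group_col]])
        sites = sorted(meta[site_col].unique()) if site_adjust else []
        self.sites = sites

        # --- fixed-effect design: (n, T, q) ---
        names: list[str] = []
        blocks: list[np.ndarray] = []
        n, G = len(wide), len(groups)
        if constrain_baseline:
            names.append("mu0")
            blocks.append(np.ones((n, T, 1)))
        else:
            for gi, g in enumerate(groups):
                names.append(f"mu0[{g}]")
                col = np.zeros((n, T, 1))
                col[self.group_idx == gi] = 1.0
                blocks.append(col)
        if site_adjust and len(sites) > 1:
            site_idx = np.array([sites.index(s) for s in meta[site_col]])
            for si, s in enumerate(sites[1:], start=1):
                names.append(f"site[{s}]")
                col = np.zeros((n, T, 1))
                col[site_idx == si] = 1.0
                blocks.append(col)
        self._delta_index: dict[tuple, int] = {}
        for gi, g in enumerate(groups):
            for ti, v in enumerate(self.visits):
                if ti == 0 and (constrain_baseline or True):
                    continue  # delta at baseline is identically zero
                self._delta_index[(g, v)] = len(names)
                names.append(f"delta[{g},{v}]")
                col = np.zeros((n, T, 1))
                col[self.group_idx == gi, ti] = 1.0
                blocks.append(col)
        self.param_names = names
        self.X = np.concatenate(blocks, axis=2)        # (n, T, q)
        self.q = self.X.shape[2]
        if n < self.q:
            raise RankError(f"{n} participants for {self.q} fixed-effect parameters")

        # --- group participants by missingness pattern ---
        obs = ~np.isnan(self.y)
        keep = obs.any(axis=1)
        self._patterns = []
        self.n_used = int(keep.sum())
        self.n_obs = int(obs.sum())
        pat_keys = [tuple(np.flatnonzero(o)) for o in obs]
        for key in sorted(set(k for k, kp in zip(pat_keys, keep) if kp)):
            idx = np.array([i for i, k in enumerate(pat_keys) if k == key and keep[i]])
            vis = np.array(key)
            self._patterns.append({
                "visits": vis,
                "Y": self.y[np.ix_(idx, vis)],                    # (m, k)
                "X": self.X[np.ix_(idx, vis)],                    # (m, k, q)
            })
        self._T = T

    # ------------------------------------------------------------------ #
    @property
    def n_theta(self) -> int:
        T = self._T
        if self.covariance == "unstructured":
            return T * (T + 1) // 2
        return 1 if T == 1 else 2

    def sigma_from_theta(self, theta: np.ndarray) -> np.ndarray:
        T = self._T
        theta = np.asarray(theta, dtype=float)
        if self.covariance == "unstructured":
            L = _chol_unstructured(theta, T)
            return L @ L.T
        var = math.exp(2.0 * theta[0])
        if T == 1:
            return np.array([[var]])
        rho = 1.0 / (1.0 + math.exp(-theta[1]))
        return var * ((1.0 - rho) * np.eye(T) + rho * np.ones((T, T)))

    def theta_from_sigma(self, sigma: np.ndarray) -> np.ndarray:
        if self.covariance == "unstructured":
            return _theta_from_sigma(sigma)
        var = float(np.mean(np.diag(sigma)))
        if self._T == 1:
            return np.array([0.5 * math.log(var)])
        off = sigma[np.triu_indices(self._T, 1)]
        rho = float(np.clip(np.mean(off) / var, 1e-6, 1 - 1e-6))
        return np.array([0.5 * math.log(var), math.log(rho / (1 - rho))])

    def _assemble(self, sigma: np.ndarray):
        """Accumulate GLS sufficient statistics over missingness patterns."""
        q = self.q
        S_xx = np.zeros((q, q))
        S_xy = np.zeros(q)
        S_yy = 0.0
        logdet = 0.0
        for pat in self._patterns:
            vis = pat["visits"]
            V = sigma[np.ix_(vis, vis)]
            cf = cho_factor(V, lower=True)
            m = pat["Y"].shape[0]
            logdet += m * 2.0 * np.sum(np.log(np.diag(cf[0])))
            Vinv = cho_solve(cf, np.eye(len(vis)))
            X, Y = pat["X"], pat["Y"]
            S_xx += np.einsum("mkq,kl,mlr->qr", X, Vinv, X, optimize=True)
            S_xy += np.einsum("mkq,kl,ml->q", X, Vinv, Y, optimize=True)
            S_yy += float(np.einsum("mk,kl,ml->", Y, Vinv, Y, optimize=True))
        return S_xx, S_xy, S_yy, logdet

    def reml_loglik(self, theta: np.ndarray) -> float:
        """Profiled REML log-likelihood at covariance parameters `theta`."""
        try:
            sigma = self.sigma_from_theta(theta)
            S_xx, S_xy, S_yy, logdet = self._assemble(sigma)
            cf = cho_factor(S_xx, lower=True)
        except (np.linalg.LinAlgError, ValueError, OverflowError):
            return -np.inf
        b = cho_solve(cf, S_xy)
        quad = S_yy - float(S_xy @ b)
        logdet_sxx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return -0.5 * (logdet + quad + logdet_sxx + (self.n_obs - self.q) * _LOG2PI)

    def _neg_reml(self, theta):
        ll = self.reml_loglik(theta)
        return 1e12 if not np.isfinite(ll) else -ll

    def _start(self) -> np.ndarray:
        """OLS means, Sigma = covariance of OLS residuals on complete cases."""
        sigma0 = np.eye(self._T)
        S_xx, S_xy, _, _ = self._assemble(sigma0)
        b0 = np.linalg.lstsq(S_xx, S_xy, rcond=None)[0]
        resid = self.y - np.einsum("ntq,q->nt", self.X, b0)
        complete = ~np.isnan(resid).any(axis=1)
        if complete.sum() > self._T + 1:
            S = np.cov(resid[complete], rowvar=False, ddof=1)
            S = np.atleast_2d(S)
        else:
            v = np.nanvar(resid, axis=0, ddof=1)
            S = np.diag(np.where(np.isfinite(v) & (v > 0), v, 1.0))
        # ridge toward the diagonal if near-singular
        eps = 1e-8 * np.trace(S) / self._T
        S = S + eps * np.eye(self._T)
        return self.theta_from_sigma(S)

    def fit(self, maxiter: int = 500, restarts: int = 3) -> "CLMMResults":
        """Maximize the REML criterion; jittered restarts on failure."""
        theta0 = self._start()
        rng = np.random.default_rng(0)

        def ok(res):
            # line-search breakdown at the optimum is still convergence:
            # accept any terminal point with a numerically flat gradient
            return np.isfinite(res.fun) and (
                res.success or np.max(np.abs(res.jac)) < 1e-4)

        def polish(res):
            # derivative-free finish: L-BFGS-B line searches often break
            # down near the optimum at tight ftol; Nelder-Mead lands it
            fatol = 1e-9 * max(1.0, abs(res.fun))   # relative to criterion scale
            nm = optimize.minimize(self._neg_reml, res.x, method="Nelder-Mead",
                                   options={"fatol": fatol, "xatol": 1e-7,
                                            "maxiter": 2000})
            if np.isfinite(nm.fun) and nm.fun <= res.fun + 1e-10 and nm.success:
                nm.jac = np.zeros_like(res.x)
                return nm
            return res

        best = None
        for attempt in range(restarts):
            start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, theta0.shape)
            res = optimize.minimize(
                self._neg_reml, start, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
            )
            if not ok(res):
                res = polish(res)
            if best is None or res.fun < best.fun:
                best = res
            if ok(res):
                break
        converged = ok(best)
        if not converged:
            warnings.warn(f"cLMM optimizer did not converge: {best.message}",
                          ConvergenceWarning)
        theta = best.x
        sigma = self.sigma_from_theta(theta)
        S_xx, S_xy, _, _ = self._assemble(sigma)
        cf = cho_factor(S_xx, lower=True)
        b = cho_solve(cf, S_xy)
        vcov = cho_solve(cf, np.eye(self.q))
        return CLMMResults(self, b, vcov, sigma, theta, -best.fun, converged)


class CLMMResults:
    """REML estimates of a :class:`ConstrainedLMM` with Wald inference."""

    def __init__(self, model, params, fixed_vcov, sigma, theta, reml_loglik,
                 converged):
        self.model = model
        self.params = pd.Series(params, index=model.param_names)
        self.fixed_vcov = pd.DataFrame(fixed_vcov, index=model.param_names,
                                       columns=model.param_names)
        self.sigma = sigma
        self.theta = theta
        self.reml_loglik = reml_loglik
        self.converged = converged
        self.n_used = model.n_used
        self._theta_W = None  # cached inverse observed information

    # --- contrasts ---------------------------------------------------- #
    def _contrast(self, items) -> np.ndarray:
        c = np.zeros(len(self.params))
        for name, w in items:
            try:
                c[self.model.param_names.index(name)] += w
            except ValueError:
                raise KeyError(f"unknown fixed-effect parameter {name!r}") from None
        return c

    def delta(self, group, visit) -> float:
        """Point estimate of group `group`'s mean change from baseline."""
        if visit == self.model.visits[0]:
            return 0.0
        return float(self.params[f"delta[{group},{visit}]"])

    def group_change(self, group, visit) -> WaldResult:
        """Mean change from baseline for one group at one visit."""
        if visit == self.model.visits[0]:
            return WaldResult(0.0, 0.0, math.inf, math.nan, math.nan, 0.0, 0.0)
        c = self._contrast([(f"delta[{group},{visit}]", 1.0)])
        return self.wald(c)

    def group_difference(self, group, visit) -> WaldResult:
        """Difference in change from baseline: `group` minus the reference."""
        if group == self.model.reference:
            raise ValueError("contrast of the reference group with itself is zero")
        c = self._contrast([(f"delta[{group},{visit}]", 1.0),
                            (f"delta[{self.model.reference},{visit}]", -1.0)])
        return self.wald(c)

    def wald(self, c: np.ndarray, level: float = 0.95) -> WaldResult:
        """Wald inference for the linear contrast ``c'b``."""
        est = float(c @ self.params.to_numpy())
        var = float(c @ self.fixed_vcov.to_numpy() @ c)
        se = math.sqrt(max(var, 0.0))
        df = self.satterthwaite_df(c)
        stat = est / se if se > 0 else math.nan
        if math.isfinite(df):
            p = 2.0 * stats.t.sf(abs(stat), df) if se > 0 else math.nan
            tq = stats.t.ppf(0.5 + level / 2.0, df)
        else:
            p = 2.0 * stats.norm.sf(abs(stat)) if se > 0 else math.nan
            tq = stats.norm.ppf(0.5 + level / 2.0)
        return WaldResult(est, se, df, stat, p, est - tq * se, est + tq * se)

    def satterthwaite_df(self, c: np.ndarray, rel_step: float = 1e-4) -> float:
        """Satterthwaite degrees of freedom for the contrast ``c'b``.

        df = 2 V^2 / (g' W g) with V = Var(c'b), g the central-difference
        gradient of V in the covariance parameters, and W the inverse
        observed information of the REML criterion.
        """
        model = self.model
        theta = np.asarray(self.theta, dtype=float)
        k = len(theta)
        h = rel_step * np.maximum(1.0, np.abs(theta))

        def contrast_var(th):
            sigma = model.sigma_from_theta(th)
            S_xx, _, _, _ = self._safe_assemble(sigma)
            return float(c @ np.linalg.solve(S_xx, c))

        V = contrast_var(theta)
        g = np.zeros(k)
        for j in range(k):
            e = np.zeros(k); e[j] = h[j]
            g[j] = (contrast_var(theta + e) - contrast_var(theta - e)) / (2 * h[j])

        if self._theta_W is None:
            f = model._neg_reml
            H = np.zeros((k, k))
            f0 = f(theta)
            for i in range(k):
                ei = np.zeros(k); ei[i] = h[i]
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / (h[i] ** 2)
                for j in range(i + 1, k):
                    ej = np.zeros(k); ej[j] = h[j]
                    H[i, j] = H[j, i] = (
                        f(theta + ei + ej) - f(theta + ei - ej)
                        - f(theta - ei + ej) + f(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
            try:
                self._theta_W = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                self._theta_W = np.full((k, k), np.nan)
        denom = float(g @ self._theta_W @ g)
        if not np.isfinite(denom):
            denom = 0.0
        if denom <= 0 or not np.isfinite(denom):
            warnings.warn("singular information; Satterthwaite df set to "
                          "infinity (normal approximation)", ConvergenceWarning)
            return math.inf
        return 2.0 * V * V / denom

    def _safe_assemble(self, sigma):
        return self.model._assemble(sigma)

    # --- presentation -------------------------------------------------- #
    def table(self) -> pd.DataFrame:
        """Change-from-baseline table: placebo mean change per visit plus
        each active arm's difference from placebo (estimate, CI, p)."""
        rows = []
        m = self.model
        for visit in m.visits[1:]:
            w = self.group_change(m.reference, visit)
            rows.append({"outcome": m.outcome, "visit": visit,
                         "comparison": f"{m.reference} change",
                         "estimate": w.estimate, "se": w.se, "df": w.df,
                         "ci_low": w.ci_low, "ci_high": w.ci_high, "p": w.p})
            for g in m.groups:
                if g == m.reference:
                    continue
                w = self.group_difference(g, visit)
                rows.append({"outcome": m.outcome, "visit": visit,
                             "comparison": f"{g} - {m.reference}",
                             "estimate": w.estimate, "se": w.se, "df": w.df,
                             "ci_low": w.ci_low, "ci_high": w.ci_high, "p": w.p})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Constrained linear mixed model: {m.outcome}",
            f"  participants {self.n_used}, visits {m.visits}, "
            f"groups {m.groups} (ref {m.reference})",
            f"  covariance {m.covariance}, REML loglik {self.reml_loglik:.3f}, "
            f"converged {self.converged}",
            "",
            self.table().to_string(index=False, float_format=lambda x: f"{x: .4f}"),
            "",
            "Residual visit covariance Sigma:",
            np.array2string(self.sigma, precision=5),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
# spec-surface functional wrappers

def fit_clmm(data: pd.DataFrame, outcome: str, **kwargs) -> CLMMResults:
    """Fit the baseline-constrained mixed model; see :class:`ConstrainedLMM`."""
    return ConstrainedLMM(data, outcome, **kwargs).fit()


def estimate_group_changes(fit: CLMMResults, group, visit) -> WaldResult:
    return fit.group_change(group, visit)


def group_difference_in_change(fit: CLMMResults, group, visit) -> WaldResult:
    return fit.group_difference(group, visit)


def satterthwaite_df(fit: CLMMResults, contrast: np.ndarray) -> float:
    return fit.satterthwaite_df(np.asarray(contrast, dtype=float))
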