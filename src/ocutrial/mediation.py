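"""Multi-mediator decomposition of a randomized treatment effect.

The total effect of each active arm on the change in spherical equivalent
(delta_T, D) is decomposed by the product-of-coefficients method into a
direct effect delta_D and effects mediated by each intermediate outcome
(axial length, lens power, choroidal thickness):

    delta_m[g] = beta[m, g] * gamma[m]
    delta_I[g] = sum_m delta_m[g]
    delta_T[g] = delta_D[g] + delta_I[g]

where beta[m, g] comes from the least-squares fit of mediator-change on
group, and gamma[m] and delta_D[g] from the least-squares fit of the
outcome change on group plus all mediator changes, all on the same
complete-case set.  With ordinary least squares throughout, delta_T[g]
equals the arm coefficient of the simple regression of the outcome change
on group *exactly* (nested-regression algebra), so the decomposition is
additive to machine precision.

The joint covariance of all regression coefficients is the sandwich of
the stacked estimating equations of the four fits, which retains the
beta-gamma covariances across models; inference on products and sums uses
the delta method with a normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clmm import WaldResult
from .exceptions import CollinearityError
from .reporting import fdr_adjust

__all__ = ["MediationModel", "MediationResults", "MediatorContrast",
           "fit_mediation", "mediated_effect", "percent_of_total",
           "product_se"]


def mediated_effect(beta: float, gamma: float) -> float:
    """Effect mediated through one intermediate outcome: beta * gamma (D)."""
    return beta * gamma


def percent_of_total(delta_m: float, delta_t: float) -> float:
    """Mediated (or direct) effect as a percentage of the total effect.

    May exceed 100 or be negative; undefined (NaN) when the total is zero.
    """
    if delta_t == 0:
        return math.nan
    return 100.0 * (delta_m / delta_t)


def product_se(beta: float, gamma: float, var_beta: float, var_gamma: float,
               cov: float = 0.0) -> float:
    """Delta-method standard error of the product beta*gamma.

    With independent estimates (cov=0) this is the Sobel formula
    sqrt(beta^2 var_gamma + gamma^2 var_beta).
    """
    v = beta * beta * var_gamma + gamma * gamma * var_beta + 2.0 * beta * gamma * cov
    return math.sqrt(max(v, 0.0))


@dataclass(frozen=True)
class MediatorContrast:
    """Between-arm difference of one decomposition component."""

    effect: str
    arm_a: str
    arm_b: str
    estimate: float
    se: float
    statistic: float
    p: float
    ci_low: float
    ci_high: float


class MediationModel:
    """Product-of-coefficients mediation model on a change-score table.

    Parameters
    ----------
    data : DataFrame
        One row per participant with the group column and change scores.
    dependent : str
        Outcome-change column (delta SE, D).
    mediators : sequence of str
        Mediator-change columns (ordered; order does not affect effects).
    reference : str
        Reference group (placebo).
    complete_case : bool
        Restrict to rows complete on dependent and all mediators.
    """

    def __init__(self, data: pd.DataFrame, dependent: str = "d_se_d",
                 mediators: Sequence[str] = ("d_al_mm", "d_lp_d", "d_cht_mm"),
                 group_col: str = "arm", reference: str = "placebo",
                 complete_case: bool = True):
        mediators = list(mediators)
        if not mediators or dependent in mediators:
            raise ValueError("mediators must be non-empty and distinct from the dependent")
        cols = [dependent] + mediators
        df = data.copy()
        if complete_case:
            df = df.dropna(subset=cols)
        self.data = df.reset_index(drop=True)
        self.dependent = dependent
        self.mediators = mediators
        self.group_col = group_col
        self.reference = reference
        groups = sorted(df[group_col].unique(), key=str)
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} not present")
        self.arms = [g for g in groups if g != reference]
        self.n = len(self.data)

        M = self.data[mediators].to_numpy()
        cond = np.linalg.cond(np.column_stack([np.ones(self.n), M]))
        if cond > 1e10:
            corr = np.corrcoef(M, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
            raise CollinearityError(
                f"mediators too collinear (condition number {cond:.3g}); "
                f"worst pair: {mediators[i]!r} and {mediators[j]!r}"
            )

    # ------------------------------------------------------------------ #
    def fit(self) -> "MediationResults":
        df = self.data
        n = self.n
        dummies = np.column_stack(
            [(df[self.group_col] == a).to_numpy(float) for a in self.arms])
        M = df[self.mediators].to_numpy()
        y = df[self.dependent].to_numpy()

        # model 0: outcome ~ 1 + arm + mediators  (delta_D and gamma)
        Z0 = np.column_stack([np.ones(n), dummies, M])
        # models 1..K: mediator_m ~ 1 + arm  (beta)
        Zm = np.column_stack([np.ones(n), dummies])

        designs = [Z0] + [Zm] * len(self.mediators)
        targets = [y] + [M[:, j] for j in range(len(self.mediators))]
        coefs, resids, offsets = [], [], []
        off = 0
        for Z, t in zip(designs, targets):
            b, *_ = np.linalg.lstsq(Z, t, rcond=None)
            coefs.append(b)
            resids.append(t - Z @ b)
            offsets.append(off)
            off += Z.shape[1]
        phi = np.concatenate(coefs)

        # stacked-estimating-equation sandwich vcov
        p_tot = off
        A = np.zeros((p_tot, p_tot))
        psi = np.zeros((n, p_tot))
        for (Z, e, o) in zip(designs, resids, offsets):
            k = Z.shape[1]
            A[o:o + k, o:o + k] = Z.T @ Z
            psi[:, o:o + k] = Z * e[:, None]
        B = psi.T @ psi
        Ainv = np.linalg.inv(A)
        vcov = Ainv @ B @ Ainv

        # parameter index bookkeeping
        idx: Dict[str, int] = {}
        for ai, a in enumerate(self.arms):
            idx[f"direct[{a}]"] = 1 + ai
        for mi, m in enumerate(self.mediators):
            idx[f"gamma[{m}]"] = 1 + len(self.arms) + mi
        for mi, m in enumerate(self.mediators):
            o = offsets[1 + mi]
            for ai, a in enumerate(self.arms):
                idx[f"beta[{m},{a}]"] = o + 1 + ai

        # reference total-effect regression (identity check / diagnostics)
        bt, *_ = np.linalg.lstsq(Zm, y, rcond=None)
        total_reg = {a: float(bt[1 + ai]) for ai, a in enumerate(self.arms)}

        return MediationResults(self, phi, vcov, idx, total_reg)


class MediationResults:
    """Fitted decomposition with delta-method inference."""

    def __init__(self, model: MediationModel, phi, vcov, idx, total_reg):
        self.model = model
        self.phi = phi
        self.vcov = vcov
        self._idx = idx
        self.total_regression = total_reg
        self.n = model.n

    # --- coefficient access -------------------------------------------- #
    def beta(self, mediator: str, arm: str) -> float:
        return float(self.phi[self._idx[f"beta[{mediator},{arm}]"]])

    def gamma(self, mediator: str) -> float:
        return float(self.phi[self._idx[f"gamma[{mediator}]"]])

    # --- effects as (estimate, gradient) pairs -------------------------- #
    def _effect(self, effect: str, arm: str):
        """Return (estimate, gradient wrt the stacked coefficient vector)."""
        g = np.zeros(len(self.phi))
        if effect == "direct":
            k = self._idx[f"direct[{arm}]"]
            g[k] = 1.0
            return float(self.phi[k]), g
        if effect in self.model.mediators:
            kb = self._idx[f"beta[{effect},{arm}]"]
            kg = self._idx[f"gamma[{effect}]"]
            b, c = float(self.phi[kb]), float(self.phi[kg])
            g[kb] = c
            g[kg] = b
            return b * c, g
        if effect == "indirect":
            est = 0.0
            for m in self.model.mediators:
                e, gm = self._effect(m, arm)
                est += e
                g += gm
            return est, g
        if effect == "total":
            e1, g1 = self._effect("direct", arm)
            e2, g2 = self._effect("indirect", arm)
            return e1 + e2, g1 + g2
        raise KeyError(f"unknown effect {effect!r}")

    def estimate(self, effect: str, arm: str) -> float:
        return self._effect(effect, arm)[0]

    def wald(self, effect: str, arm: str, level: float = 0.95) -> WaldResult:
        """Normal-approximation Wald inference for one decomposition component."""
        est, g = self._effect(effect, arm)
        var = float(g @ self.vcov @ g)
        se = math.sqrt(max(var, 0.0))
        z = est / se if se > 0 else math.nan
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else math.nan
        q = stats.norm.ppf(0.5 + level / 2.0)
        return WaldResult(est, se, math.inf, z, p, est - q * se, est + q * se)

    def contrast(self, effect: str, arm_a: str, arm_b: str,
                 level: float = 0.95) -> MediatorContrast:
        """Between-arm difference of a component: arm_b minus arm_a."""
        ea, ga = self._effect(effect, arm_a)
        eb, gb = self._effect(effect, arm_b)
        est = eb - ea
        g = gb - ga
        var = float(g @ self.vcov @ g)
        se = math.sqrt(max(var, 0.0))
        if arm_a == arm_b:
            import warnings
            warnings.warn("contrast of an arm with itself is identically zero")
            return MediatorContrast(effect, arm_a, arm_b, 0.0, 0.0,
                                    math.nan, math.nan, 0.0, 0.0)
        z = est / se if se > 0 else math.nan
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else math.nan
        q = stats.norm.ppf(0.5 + level / 2.0)
        return MediatorContrast(effect, arm_a, arm_b, est, se, z, p,
                                est - q * se, est + q * se)

    # --- presentation --------------------------------------------------- #
    def effect_table(self, fdr: bool = False) -> pd.DataFrame:
        """Decomposition table per active arm, with between-arm differences
        when there are exactly two active arms.

        Rows: direct, indirect, each mediator, total.  Percentages are of
        each arm's total effect and sum to 100 exactly (direct + mediated).
        """
        effects = ["direct", "indirect"] + list(self.model.mediators) + ["total"]
        rows = []
        pair = self.model.arms if len(self.model.arms) == 2 else None
        for eff in effects:
            row = {"effect": eff}
            for arm in self.model.arms:
                w = self.wald(eff, arm)
                tot = self.estimate("total", arm)
                row[f"estimate[{arm}]"] = w.estimate
                row[f"ci_low[{arm}]"] = w.ci_low
                row[f"ci_high[{arm}]"] = w.ci_high
                row[f"pct[{arm}]"] = percent_of_total(w.estimate, tot)
            if pair:
                ct = self.contrast(eff, pair[0], pair[1])
                row.update({"diff": ct.estimate, "diff_ci_low": ct.ci_low,
                            "diff_ci_high": ct.ci_high, "diff_p": ct.p})
            rows.append(row)
        out = pd.DataFrame(rows)
        if fdr and pair:
            # sums of other components are excluded from the FDR family
            mask = ~out["effect"].isin(["indirect", "total"])
            adj = np.full(len(out), np.nan)
            adj[mask.to_numpy()] = fdr_adjust(out.loc[mask, "diff_p"].to_numpy())
            out["diff_adj_p"] = adj
        return out

    def summary(self) -> str:
        lines = [
            f"Mediation decomposition of {self.model.dependent} "
            f"(n = {self.n} complete cases)",
            f"  mediators: {self.model.mediators}; arms vs "
            f"{self.model.reference!r}: {self.model.arms}",
            "",
            self.effect_table().to_string(index=False,
                                          float_format=lambda x: f"{x: .4f}"),
        ]
        return "\n".join(lines)


def fit_mediation(data: pd.DataFrame, **kwargs) -> MediationResults:
    """Fit the multi-mediator decomposition; see :class:`MediationModel`."""
    return MediationModel(data, **kwargs).fit()
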