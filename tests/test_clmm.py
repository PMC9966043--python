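"""Tests of the baseline-constrained linear mixed model.

Oracles: a brute-force REML evaluation composed from scipy's generic
multivariate-normal log-density, and textbook closed forms (per-cell means
on balanced complete data, one-sample REML, pooled two-sample t).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ocutrial.clmm import ConstrainedLMM, fit_clmm
from ocutrial.exceptions import RankError
from ocutrial.simulate import SimulationConfig, simulate_trial
from ocutrial import biometry


def long_table(y, groups, months, sites=None):
    """Assemble a per-participant per-visit long table from a wide array."""
    n, t = y.shape
    rows = []
    for i in range(n):
        for j in range(t):
            if np.isnan(y[i, j]):
                continue
            rows.append({"pid": f"S{i:03d}", "site": 1 if sites is None else sites[i],
                         "arm": groups[i], "month": months[j], "y": y[i, j]})
    return pd.DataFrame(rows)


def reml_oracle(model, theta):
    """Independent REML criterion: per-subject MVN log-densities at the
    profiled GLS mean, plus the -0.5 log|X'V^-1X| adjustment."""
    sigma = model.sigma_from_theta(theta)
    Xs, ys, Vs = [], [], []
    for i in range(len(model.subjects)):
        obs = np.flatnonzero(~np.isnan(model.y[i]))
        if obs.size == 0:
            continue
        Xs.append(model.X[i][obs])
        ys.append(model.y[i][obs])
        Vs.append(sigma[np.ix_(obs, obs)])
    q = model.q
    S_xx = sum(X.T @ np.linalg.inv(V) @ X for X, V in zip(Xs, Vs))
    S_xy = sum(X.T @ np.linalg.inv(V) @ y for X, y, V in zip(Xs, ys, Vs))
    b = np.linalg.solve(S_xx, S_xy)
    ll = sum(stats.multivariate_normal.logpdf(y, X @ b, V)
             for X, y, V in zip(Xs, ys, Vs))
    return ll + 0.5 * q * np.log(2 * np.pi) - 0.5 * np.linalg.slogdet(S_xx)[1]


@pytest.fixture(scope="module")
def al_fit(medium_trial_avg):
    return ConstrainedLMM(medium_trial_avg, "al_mm").fit()


class TestREMLCriterion:
    def test_matches_brute_force_oracle(self):
        """Profiled REML log-likelihood equals an independently composed
        multivariate-normal evaluation on 50 random incomplete datasets."""
        rng = np.random.default_rng(1)
        for rep in range(50):
            n, t = 14, 3
            while True:
                y = rng.normal(0, 1, (n, t)) + rng.normal(0, 0.5, (n, 1))
                miss = rng.random((n, t - 1)) < 0.25
                y[:, 1:][miss] = np.nan
                obs = ~np.isnan(y)
                # every group x visit cell needs observations for a full-rank fit
                if obs[: n // 2].sum(0).min() >= 2 and obs[n // 2:].sum(0).min() >= 2:
                    break
            groups = np.where(np.arange(n) < n // 2, "placebo", "active")
            df = long_table(y, groups, [0, 3, 6])
            model = ConstrainedLMM(df, "y", constrain_baseline=bool(rep % 2),
                                   site_adjust=False)
            theta = rng.normal(0, 0.3, model.n_theta)
            assert model.reml_loglik(theta) == pytest.approx(
                reml_oracle(model, theta), abs=1e-8)

    def test_invariant_to_participant_ordering(self):
        rng = np.random.default_rng(2)
        y = rng.normal(24, 1, (20, 3))
        groups = np.repeat(["placebo", "active"], 10)
        df = long_table(y, groups, [0, 3, 6])
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        m1 = ConstrainedLMM(df, "y", site_adjust=False)
        m2 = ConstrainedLMM(shuffled, "y", site_adjust=False)
        theta = rng.normal(0, 0.2, m1.n_theta)
        assert m1.reml_loglik(theta) == pytest.approx(m2.reml_loglik(theta), abs=1e-10)

    def test_optimum_beats_random_perturbations(self, al_fit):
        rng = np.random.default_rng(4)
        ll_hat = al_fit.model.reml_loglik(al_fit.theta)
        for _ in range(100):
            ll = al_fit.model.reml_loglik(al_fit.theta + rng.normal(0, 0.05, al_fit.theta.shape))
            assert ll <= ll_hat + 1e-7


class TestClosedForms:
    def test_unconstrained_balanced_equals_cell_means(self):
        """On complete balanced data with no constraint/site terms, the
        group-by-visit estimates are the per-cell sample means (GLS = OLS)."""
        rng = np.random.default_rng(5)
        y = rng.normal(24, 0.8, (30, 3))
        groups = np.repeat(["placebo", "active"], 15)
        df = long_table(y, groups, [0, 3, 6])
        res = ConstrainedLMM(df, "y", constrain_baseline=False,
                             site_adjust=False).fit()
        for g, sel in (("placebo", slice(0, 15)), ("active", slice(15, 30))):
            cell = y[sel].mean(axis=0)
            assert res.params[f"mu0[{g}]"] == pytest.approx(cell[0], abs=1e-8)
            for j, v in enumerate((3, 6), start=1):
                assert res.delta(g, v) == pytest.approx(cell[j] - cell[0], abs=1e-8)

    def test_one_sample_single_visit_reml(self):
        """Single group, single visit: mu0 is the sample mean, Sigma the
        unbiased (n-1) variance, and the Satterthwaite df is n-1."""
        rng = np.random.default_rng(6)
        n = 25
        y = rng.normal(-3.0, 1.1, (n, 1))
        df = long_table(y, ["placebo"] * n, [0])
        res = ConstrainedLMM(df, "y", visits=[0], constrain_baseline=False,
                             site_adjust=False).fit()
        assert res.params["mu0[placebo]"] == pytest.approx(y.mean(), abs=1e-8)
        assert res.sigma[0, 0] == pytest.approx(y.var(ddof=1), rel=1e-7)
        c = np.array([1.0])
        assert res.satterthwaite_df(c) == pytest.approx(n - 1, abs=1e-2)

    def test_balanced_one_group_multivariate_closed_form(self):
        """Saturated one-group REML: means are the visit means and Sigma the
        (n-1)-denominator sample covariance."""
        rng = np.random.default_rng(7)
        n = 40
        y = rng.multivariate_normal([24, 24.1, 24.2],
                                    0.7 * np.eye(3) + 0.3, size=n)
        df = long_table(y, ["placebo"] * n, [0, 3, 6])
        res = ConstrainedLMM(df, "y", constrain_baseline=False,
                             site_adjust=False).fit()
        means = y.mean(axis=0)
        assert res.params["mu0[placebo]"] == pytest.approx(means[0], abs=1e-7)
        np.testing.assert_allclose(res.sigma, np.cov(y, rowvar=False, ddof=1),
                                   rtol=1e-5, atol=1e-7)

    def test_two_sample_single_visit_matches_pooled_t(self):
        """Balanced two-group single-visit fit reproduces the pooled
        two-sample t statistic with df ~ 2n-2."""
        rng = np.random.default_rng(8)
        n = 20
        y = np.concatenate([rng.normal(0.0, 1.0, n), rng.normal(0.5, 1.0, n)])
        groups = np.repeat(["placebo", "active"], n)
        df = long_table(y[:, None], groups, [0])
        res = ConstrainedLMM(df, "y", visits=[0], constrain_baseline=False,
                             site_adjust=False).fit()
        c = res._contrast([("mu0[active]", 1.0), ("mu0[placebo]", -1.0)])
        w = res.wald(c)
        t_ref = stats.ttest_ind(y[n:], y[:n], equal_var=True)
        assert w.statistic == pytest.approx(t_ref.statistic, rel=1e-5)
        assert w.df == pytest.approx(2 * n - 2, abs=0.5)
        assert w.p == pytest.approx(t_ref.pvalue, abs=1e-4)

    def test_change_ci_matches_one_sample_t_interval(self):
        """One group, two visits, complete data: the change CI equals the
        classic t interval of the participant-wise change scores."""
        rng = np.random.default_rng(9)
        n = 30
        y = rng.multivariate_normal([24.0, 24.15], [[0.7, 0.6], [0.6, 0.75]], size=n)
        df = long_table(y, ["placebo"] * n, [0, 3])
        res = ConstrainedLMM(df, "y", visits=[0, 3], constrain_baseline=False,
                             site_adjust=False).fit()
        w = res.group_change("placebo", 3)
        chg = y[:, 1] - y[:, 0]
        se_ref = chg.std(ddof=1) / np.sqrt(n)
        assert w.estimate == pytest.approx(chg.mean(), abs=1e-8)
        assert w.se == pytest.approx(se_ref, rel=1e-6)
        assert w.df == pytest.approx(n - 1, abs=0.1)
        tq = stats.t.ppf(0.975, n - 1)
        assert w.ci_low == pytest.approx(chg.mean() - tq * se_ref, rel=1e-4)
        assert w.ci_high == pytest.approx(chg.mean() + tq * se_ref, rel=1e-4)


class TestModelBehaviour:
    def test_baseline_constraint_pools_information(self):
        """A baseline-only participant shifts constrained-fit estimates of
        the *other* group (shared baseline), but leaves an unconstrained
        fit's other-group changes untouched."""
        rng = np.random.default_rng(10)
        y = rng.normal(24, 0.8, (21, 3))
        y[20, 1:] = np.nan                      # baseline-only participant
        groups = np.array(["placebo"] * 10 + ["active"] * 10 + ["placebo"])
        df_full = long_table(y, groups, [0, 3, 6])
        df_drop = long_table(y[:20], groups[:20], [0, 3, 6])

        unc_full = ConstrainedLMM(df_full, "y", constrain_baseline=False,
                                  site_adjust=False).fit()
        unc_drop = ConstrainedLMM(df_drop, "y", constrain_baseline=False,
                                  site_adjust=False).fit()
        assert unc_full.delta("active", 6) == pytest.approx(
            unc_drop.delta("active", 6), abs=1e-7)

        con_full = ConstrainedLMM(df_full, "y", site_adjust=False).fit()
        con_drop = ConstrainedLMM(df_drop, "y", site_adjust=False).fit()
        assert abs(con_full.delta("active", 6) - con_drop.delta("active", 6)) > 1e-6
        assert con_full.n_used == 21

    def test_unstructured_sigma_approaches_compound_symmetry_truth(self):
        var, rho = 0.84 ** 2, 0.7
        cs = var * ((1 - rho) * np.eye(3) + rho)
        cfg = SimulationConfig(n_per_arm=(1000, 1000, 1000), outcomes=("al_mm",),
                               visit_cov={"al_mm": cs}, missing_visit_prob=0.0,
                               site_shift_sd=0.0, seed=13)
        avg = biometry.average_eyes_table(
            simulate_trial(cfg).data.assign(**{c: np.nan for c in []}))
        res = ConstrainedLMM(avg, "al_mm").fit()
        corr = res.sigma / np.sqrt(np.outer(np.diag(res.sigma), np.diag(res.sigma)))
        off = corr[np.triu_indices(3, 1)]
        assert np.ptp(off) < 0.04                 # off-diagonal spread shrinks
        assert np.allclose(off, rho, atol=0.05)

    def test_site_label_recoding_invariance(self, medium_trial_avg):
        res1 = ConstrainedLMM(medium_trial_avg, "al_mm").fit()
        recoded = medium_trial_avg.assign(site=medium_trial_avg["site"] * 10 + 7)
        res2 = ConstrainedLMM(recoded, "al_mm").fit()
        for g in ("low_dose", "loading_dose"):
            for v in (3, 6):
                assert res1.group_difference(g, v).estimate == pytest.approx(
                    res2.group_difference(g, v).estimate, abs=1e-6)

    def test_rank_error(self):
        rng = np.random.default_rng(14)
        y = rng.normal(0, 1, (4, 3))
        df = long_table(y, ["a", "a", "b", "b"], [0, 3, 6])
        with pytest.raises(RankError):
            ConstrainedLMM(df, "y", reference="a", site_adjust=False)

    def test_reference_group_contrast_rejected(self, al_fit):
        with pytest.raises(ValueError):
            al_fit.group_difference("placebo", 6)
        with pytest.raises(KeyError):
            al_fit.group_difference("loading_dose", 12)

    def test_single_recovery_within_sampling_error(self, al_fit, medium_trial_avg):
        """One fit at n=100/arm: estimates within 4 SE of configured truth."""
        truth = {("low_dose", 3): -0.03, ("low_dose", 6): -0.06,
                 ("loading_dose", 3): -0.08, ("loading_dose", 6): -0.13}
        for (g, v), t in truth.items():
            w = al_fit.group_difference(g, v)
            assert abs(w.estimate - t) < 4 * w.se

    def test_summary_and_table(self, al_fit):
        tab = al_fit.table()
        assert len(tab) == 6
        assert {"estimate", "ci_low", "ci_high", "p", "df"} <= set(tab.columns)
        assert (tab["df"] > 0).all()
        assert "Constrained linear mixed model" in al_fit.summary()

    def test_wrapper_functions(self, medium_trial_avg):
        from ocutrial.clmm import (estimate_group_changes,
                                   group_difference_in_change, satterthwaite_df)
        res = fit_clmm(medium_trial_avg, "se_d")
        w = estimate_group_changes(res, "placebo", 6)
        assert np.isfinite(w.estimate)
        d = group_difference_in_change(res, "loading_dose", 6)
        assert d.ci_low <= d.estimate <= d.ci_high
        c = res._contrast([("delta[loading_dose,6]", 1.0)])
        assert satterthwaite_df(res, c) > 0
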