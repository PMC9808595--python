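"""Kaplan-Meier, log-rank, Cox fitting, risk scores and time-dependent ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from pbscreen import survival, synthetic
from pbscreen.errors import ConvergenceError, ValidationError
from pbscreen.survival import (
    dichotomize_median,
    fit_cox,
    five_group_assign,
    km_estimate,
    logrank_test,
    risk_score,
    td_roc_auc,
)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.median is None
        assert km.at(10.0) == 1.0

    def test_three_events_hand_computed(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0  # earliest time with S <= 0.5

    def test_censoring_between_events(self):
        # events at 1 and 3, censored at 2: S = 3/4 then 3/4 * 1/2
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        assert np.allclose(km.survival, [3 / 4, 3 / 8])

    @given(
        st.lists(
            st.tuples(st.floats(0.0, 50.0), st.integers(0, 1)),
            min_size=1,
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_curve_monotone_within_unit_interval(self, records):
        t = [r[0] for r in records]
        e = [r[1] for r in records]
        km = km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0], [1])

    def test_matches_lifelines_product_limit(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(5)
        for _ in range(5):
            t = rng.exponential(3.0, size=60)
            e = rng.integers(0, 2, size=60)
            km = km_estimate(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            theirs = kmf.survival_function_at_times(km.times).to_numpy()
            assert np.allclose(km.survival, theirs, atol=1e-10)


class TestLogrank:
    def test_group_against_its_copy_gives_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_anywhere(self):
        assert logrank_test([1.0], [0], [2.0], [0]) == (0.0, 1.0)

    def test_six_sample_hand_computed_table(self):
        """O/E/V worked by hand: sum(O-E)=0.6, sum(V)=0.74."""
        chi2, p = logrank_test([1.0, 3.0, 5.0], [1, 1, 0], [2.0, 4.0, 6.0], [1, 0, 1])
        assert chi2 == pytest.approx(0.36 / 0.74, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(0.36 / 0.74, 1), abs=1e-12)

    def test_p_within_monte_carlo_error_of_permutation_null(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(2.0, size=20)
        e = rng.integers(0, 2, size=20)
        labels = np.array([0] * 10 + [1] * 10)
        obs, p_chi2 = logrank_test(t[labels == 0], e[labels == 0],
                                   t[labels == 1], e[labels == 1])
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            stat, _ = logrank_test(t[perm == 0], e[perm == 0],
                                   t[perm == 1], e[perm == 1])
            hits += stat >= obs
        assert abs(hits / n_perm - p_chi2) < 0.04

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(11)
        for _ in range(5):
            ta, tb = rng.exponential(2, 30), rng.exponential(3, 25)
            ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
            chi2, p = logrank_test(ta, ea, tb, eb)
            res = ll_logrank(ta, tb, ea, eb)
            assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)
            assert p == pytest.approx(res.p_value, abs=1e-8)


class TestDichotomize:
    def test_even_split(self):
        labels = dichotomize_median(pd.Series([1, 2, 3, 4]))
        assert list(labels) == ["low", "low", "high", "high"]

    def test_odd_n_median_tie_goes_high(self):
        labels = dichotomize_median(pd.Series([1, 2, 3]))
        assert list(labels) == ["low", "high", "high"]

    def test_constant_row_warns_all_high(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = dichotomize_median(pd.Series([5.0, 5.0, 5.0]))
        assert (labels == "high").all()


class TestCox:
    def test_null_covariate_small_beta_ci_covers_zero(self):
        rng = np.random.default_rng(1)
        n = 200
        t = rng.exponential(2.0, size=n)
        e = rng.integers(0, 2, size=n)
        x = pd.DataFrame({"g": rng.permutation(np.linspace(-2, 2, n))})
        m = fit_cox(t, e, x)
        assert abs(m.beta[0]) < 0.1
        lo, hi = m.ci95[0]
        assert lo < 1.0 < hi  # HR interval covers the null

    def test_five_sample_brute_force_likelihood_oracle(self):
        """Newton fit equals direct maximization of the explicit partial
        likelihood on a tiny no-ties dataset."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 1])
        x = np.array([0.5, -0.2, 1.0, 0.1, -0.7])

        def neg_logpl(b):
            ll = 0.0
            for i in range(5):
                if e[i]:
                    risk = x[t >= t[i]]
                    ll += b * x[i] - np.log(np.sum(np.exp(b * risk)))
            return -ll

        res = optimize.minimize_scalar(neg_logpl, bounds=(-10, 10), method="bounded",
                                       options={"xatol": 1e-10})
        m = fit_cox(t, e, pd.DataFrame({"x": x}))
        assert m.beta[0] == pytest.approx(res.x, abs=1e-4)
        assert m.log_partial_likelihood == pytest.approx(-res.fun, abs=1e-8)

    def test_recovers_planted_signature_coefficients(self, four_gene_cohort):
        co = four_gene_cohort
        m = fit_cox(co.time_years, co.event, co.expression.T)
        for est, truth in zip(m.beta, co.true_beta):
            assert abs(est - truth) < 0.2  # n=300 single cohort
        assert m.aic == -2 * m.log_partial_likelihood + 2 * 4

    def test_perfect_separation_raises_naming_covariate(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        x = pd.DataFrame({"sep": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
        with pytest.raises(ConvergenceError, match="sep"):
            fit_cox(t, e, x)

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError, match="event"):
            fit_cox([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.1, 0.2]}))

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="flat"):
            fit_cox([1.0, 2.0, 3.0], [1, 1, 0],
                    pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_ridge_shrinks_toward_zero(self, four_gene_cohort):
        co = four_gene_cohort
        free = fit_cox(co.time_years, co.event, co.expression.T)
        pen = fit_cox(co.time_years, co.event, co.expression.T, ridge=50.0)
        assert np.linalg.norm(pen.beta) < np.linalg.norm(free.beta)

    def test_efron_ties_agree_with_reference(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(17)
        for seed in range(3):
            co = synthetic.simulate_survival_cohort(100, 2, [0.6, -0.3], 0.3,
                                                    seed + 30)
            t = np.ceil(co.time_years)  # year resolution forces ties
            m = fit_cox(t, co.event, co.expression.T)
            df = co.expression.T.copy()
            df["T"], df["E"] = t, co.event
            cph = CoxPHFitter().fit(df, "T", "E",
                                    fit_options={"precision": 1e-9})
            assert np.allclose(m.beta, cph.params_.values, atol=1e-5)
            assert np.allclose(m.se, cph.standard_errors_.values, atol=1e-5)


class TestRiskScore:
    def signature_model(self):
        return survival.CoxModel(
            gene_ids=["ZNF720", "REEP3", "CNNM2", "CGREF1"],
            beta=np.array([0.4193, 0.1222, 0.1394, 0.291]),
            se=np.ones(4) * 0.1,
            log_partial_likelihood=-178.0,
            n=95,
            n_events=50,
        )

    def test_zero_expression_gives_zero_score(self):
        model = self.signature_model()
        expr = pd.DataFrame(
            0.0, index=model.gene_ids, columns=[f"s{i}" for i in range(4)]
        )
        scores, groups = risk_score(model, expr)
        assert (scores == 0).all()

    def test_unit_expression_sums_coefficients(self):
        model = self.signature_model()
        expr = pd.DataFrame(1.0, index=model.gene_ids, columns=["s1", "s2"])
        scores, _ = risk_score(model, expr)
        assert scores["s1"] == pytest.approx(0.4193 + 0.1222 + 0.1394 + 0.291)

    def test_affine_equivariance(self, four_gene_cohort):
        co = four_gene_cohort
        model = fit_cox(co.time_years, co.event, co.expression.T)
        base, _ = risk_score(model, co.expression)
        shifted = co.expression.copy()
        shifted.loc["REEP3"] += 2.5
        scores, _ = risk_score(model, shifted)
        assert np.allclose(scores - base, model.beta[1] * 2.5)

    def test_missing_gene_listed_in_error(self):
        model = self.signature_model()
        expr = pd.DataFrame(0.0, index=["ZNF720"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="REEP3"):
            risk_score(model, expr)


class TestTimeDependentRoc:
    def test_constant_score_is_chance(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([1, 1, 0, 1, 0])
        assert td_roc_auc(t, e, np.ones(5), 3.0) == pytest.approx(0.5)

    def test_perfect_ranking_no_censoring(self):
        t = np.linspace(1, 10, 10)
        e = np.ones(10, dtype=int)
        assert td_roc_auc(t, e, -t, 5.0) == pytest.approx(1.0)

    def test_uncensored_equals_pairwise_concordance_enumeration(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(2.0, size=25)
        e = np.ones(25, dtype=int)
        s = rng.normal(size=25)
        horizon = float(np.median(t))
        auc = td_roc_auc(t, e, s, horizon)
        cases = np.nonzero(t <= horizon)[0]
        controls = np.nonzero(t > horizon)[0]
        num = sum(
            (s[i] > s[j]) + 0.5 * (s[i] == s[j]) for i in cases for j in controls
        )
        assert auc == pytest.approx(num / (len(cases) * len(controls)), abs=1e-12)

    def test_matches_scikit_survival_ipcw_estimator(self, four_gene_cohort):
        from sksurv.metrics import cumulative_dynamic_auc

        co = four_gene_cohort
        model = fit_cox(co.time_years, co.event, co.expression.T)
        scores, _ = risk_score(model, co.expression)
        y = np.array(
            list(zip(co.event.astype(bool), co.time_years)),
            dtype=[("e", bool), ("t", float)],
        )
        for horizon in (1.0, 3.0):
            ours = td_roc_auc(co.time_years, co.event, scores.to_numpy(), horizon)
            theirs = cumulative_dynamic_auc(y, y, scores.to_numpy(), [horizon])[0][0]
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_no_cases_at_horizon_undefined(self):
        assert td_roc_auc([5.0, 6.0], [1, 1], [0.1, 0.2], 1.0) is None


class TestFiveGroup:
    def test_extremes_and_partition(self, four_gene_cohort):
        expr = four_gene_cohort.expression
        genes = list(expr.index)
        labels = five_group_assign(expr, genes)
        assert labels.value_counts().sum() == expr.shape[1]
        medians = expr.median(axis=1)
        above_all = (expr.ge(medians, axis=0)).all(axis=0)
        assert (labels[above_all] == "Four_genes_high").all()
        below_all = (~expr.ge(medians, axis=0)).all(axis=0)
        assert (labels[below_all] == "Low_group").all()

    def test_requires_exactly_four_genes(self, four_gene_cohort):
        with pytest.raises(ValidationError):
            five_group_assign(four_gene_cohort.expression, ["ZNF720"])


class TestHighLowStratification:
    def test_high_risk_curve_dominated_and_logrank_significant(self):
        """With all-positive coefficients the high-risk group must do worse
        at every event time."""
        co = synthetic.simulate_survival_cohort(
            500, 4, [0.4193, 0.1222, 0.1394, 0.291], 0.35, 42
        )
        m = fit_cox(co.time_years, co.event, co.expression.T)
        scores, groups = risk_score(m, co.expression)
        hi = (groups == "high").to_numpy()
        chi2, p = logrank_test(
            co.time_years[hi], co.event[hi], co.time_years[~hi], co.event[~hi]
        )
        assert p < 0.01
        km_hi = km_estimate(co.time_years[hi], co.event[hi])
        km_lo = km_estimate(co.time_years[~hi], co.event[~hi])
        for t in np.union1d(km_hi.times, km_lo.times):
            assert km_hi.at(t) <= km_lo.at(t) + 1e-12
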