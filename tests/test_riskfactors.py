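import numpy as np
import pandas as pd
import pytest

from faerspv.riskfactors import (FactorSpec, fit_logistic_irls,
                                 fit_univariate_logistic, screen_factors,
                                 tabulate_coreported)
from faerspv.termset import TermSet
from conftest import make_case_table

RENAL = TermSet("renal", frozenset({"acute kidney injury"}))


def _binary_data(n11, n10, n01, n00):
    """events/non-events: exposed n11/n10, unexposed n01/n00."""
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    x = np.r_[np.full(n11 + n10, "yes"), np.full(n01 + n00, "no")]
    return pd.Series(y), pd.Series(x)


class TestUnivariateLogistic:
    def test_binary_or_equals_cross_product(self):
        y, x = _binary_data(10, 10, 5, 20)
        res = fit_univariate_logistic(y, x, FactorSpec("exposed", reference="no"))
        (r,) = res
        assert r.odds_ratio == pytest.approx(4.0, rel=1e-6)
        assert np.log(r.odds_ratio) == pytest.approx(np.log(4), rel=1e-6)
        assert r.ci95[0] < r.odds_ratio < r.ci95[1]
        assert r.n_used == 45

    def test_constant_factor_not_estimable(self):
        y = pd.Series([0.0, 1.0, 0.0, 1.0])
        x = pd.Series(["a", "a", "a", "a"])
        (r,) = fit_univariate_logistic(y, x, FactorSpec("f"))
        assert not r.estimable and "no contrast" in r.note

    def test_single_outcome_class_not_estimable(self):
        y = pd.Series([1.0, 1.0, 1.0])
        x = pd.Series(["a", "b", "a"])
        (r,) = fit_univariate_logistic(y, x, FactorSpec("f"))
        assert not r.estimable

    def test_separation_flagged_not_exploded(self):
        y, x = _binary_data(10, 0, 5, 20)  # exposed level all-event
        res = fit_univariate_logistic(y, x, FactorSpec("exposed", reference="no"))
        (r,) = res
        assert not r.estimable and "separation" in r.note

    def test_complete_case_rule(self):
        y = pd.Series([1.0, 0, 1, 0, 1, np.nan])
        x = pd.Series(["a", "b", "a", "b", np.nan, "a"])
        (r,) = fit_univariate_logistic(y, x, FactorSpec("f", reference="a"))
        assert r.n_used == 4

    def test_continuous_slope_or(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=n)
        logit = -0.5 + 0.7 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        (r,) = fit_univariate_logistic(pd.Series(y), pd.Series(x),
                                       FactorSpec("x", "continuous"))
        assert r.ci95[0] < np.exp(0.7) < r.ci95[1]

    def test_agreement_with_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        n = 500
        x = rng.choice(["a", "b", "c"], size=n)
        y = (rng.random(n) < np.select([x == "a", x == "b"], [0.2, 0.45], 0.6)).astype(float)
        res = fit_univariate_logistic(pd.Series(y), pd.Series(x),
                                      FactorSpec("f", reference="a"))
        X = sm.add_constant(np.column_stack([(x == "b").astype(float),
                                             (x == "c").astype(float)]))
        sm_fit = sm.Logit(y, X).fit(disp=0)
        for j, r in enumerate(res, start=1):
            assert np.log(r.odds_ratio) == pytest.approx(sm_fit.params[j], abs=1e-6)
            assert r.p_value == pytest.approx(sm_fit.pvalues[j], abs=1e-6)

    def test_loglik_nondecreasing_across_irls_iterations(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = (rng.random(n) < 0.4).astype(float)
            fit = fit_logistic_irls(X, y)
            assert fit.converged
            diffs = np.diff(fit.loglik_trace)
            assert (diffs >= -1e-9).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        n = 300
        x = rng.choice(["a", "b"], size=n)
        y = (rng.random(n) < 0.3).astype(float)
        perm = rng.permutation(n)
        r1 = fit_univariate_logistic(pd.Series(y), pd.Series(x),
                                     FactorSpec("f", reference="a"))[0]
        r2 = fit_univariate_logistic(pd.Series(y[perm]), pd.Series(x[perm]),
                                     FactorSpec("f", reference="a"))[0]
        assert abs(r1.odds_ratio - r2.odds_ratio) < 1e-10
        assert abs(r1.p_value - r2.p_value) < 1e-10

    def test_planted_or_coverage(self):
        """Wald CI covers the true odds ratio at roughly nominal rate."""
        rng = np.random.default_rng(23)
        true_or = 0.14
        p_ref = 0.35
        odds_ref = p_ref / (1 - p_ref)
        p_alt = true_or * odds_ref / (1 + true_or * odds_ref)
        covered = estimable = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 800
            x = rng.choice(["omeprazole", "lansoprazole"], size=n)
            p = np.where(x == "omeprazole", p_ref, p_alt)
            y = (rng.random(n) < p).astype(float)
            res = fit_univariate_logistic(pd.Series(y), pd.Series(x),
                                          FactorSpec("ppi", reference="omeprazole"))
            r = res[0]
            if not r.estimable:
                continue
            estimable += 1
            covered += r.ci95[0] <= true_or <= r.ci95[1]
        assert estimable >= 0.95 * n_rep
        assert covered / estimable >= 0.93


class TestScreenFactors:
    def test_forest_frame_shape(self):
        rng = np.random.default_rng(1)
        n = 400
        data = pd.DataFrame({
            "renal_event": (rng.random(n) < 0.4).astype(float),
            "sex": rng.choice(["M", "F"], size=n),
            "age_years": rng.normal(60, 10, size=n),
        })
        out = screen_factors(data, "renal_event", [
            FactorSpec("sex", reference="F"), FactorSpec("age_years", "continuous")])
        assert list(out["factor"]) == ["sex", "age_years"]
        assert set(out.columns) >= {"odds_ratio", "ci_low", "ci_high", "p", "n_used"}


class TestCoreported:
    def test_renal_only_case_is_not_coreporting(self):
        table = make_case_table([
            dict(caseid="C1", reactions=["acute kidney injury"]),
            dict(caseid="C2", reactions=["acute kidney injury", "colitis"]),
        ])
        soc_map = {"colitis": "Gastrointestinal disorders"}
        co = tabulate_coreported(table, {"C1", "C2"}, RENAL, soc_map=soc_map)
        assert co.n_cases == 2 and co.n_coreporting == 1
        assert co.fraction == pytest.approx(0.5)
        assert list(co.breakdown["soc"]) == ["Gastrointestinal disorders"]
        assert list(co.breakdown["pct_of_coreporting"]) == [100.0]

    def test_missing_soc_map_skips_breakdown(self):
        table = make_case_table([
            dict(caseid="C1", reactions=["acute kidney injury", "rash"])])
        co = tabulate_coreported(table, {"C1"}, RENAL)
        assert co.fraction == 1.0 and co.breakdown is None

    def test_planted_coreporting_fraction_recovered(self):
        rng = np.random.default_rng(29)
        cases = []
        for i in range(2000):
            pts = ["acute kidney injury"]
            if rng.random() < 0.55:
                pts.append("colitis")
            cases.append(dict(caseid=f"C{i}", reactions=pts))
        table = make_case_table(cases)
        co = tabulate_coreported(table, {f"C{i}" for i in range(2000)}, RENAL)
        assert 0.52 <= co.fraction <= 0.58
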