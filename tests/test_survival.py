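import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radbcr.survival import (
    cox_fit,
    evaluate_models,
    km_logrank,
    logistic_or_report,
    roc_auc,
    univariate_report,
    youden_cutoff,
)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc(np.array([1.0, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1]))
        assert r.auc == 1.0
        assert r.sensitivity == 100.0 and r.specificity == 100.0

    def test_constant_feature_is_chance(self):
        r = roc_auc(np.ones(8), np.array([0, 1] * 4))
        assert r.auc == 0.5
        assert r.p_value == 1.0

    def test_worked_example(self):
        r = roc_auc(np.array([1.0, 2, 3, 4]), np.array([0, 1, 0, 1]))
        assert r.auc == pytest.approx(0.75)

    def test_orientation_flip(self):
        r = roc_auc(np.array([1.0, 2, 3, 4]), np.array([1, 1, 0, 0]))
        assert r.orientation == "low"
        assert r.auc == 1.0

    def test_rank_auc_equals_trapezoidal_integration(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(25):
            n = rng.integers(12, 60)
            y = (rng.random(n) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            x = np.round(rng.normal(size=n), 1)   # induce ties
            raw = roc_auc_score(y, x)
            r = roc_auc(x, y)
            assert r.auc == pytest.approx(max(raw, 1 - raw), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.zeros(4))


class TestYouden:
    def test_worked_example_midpoint(self):
        cut, se, sp = youden_cutoff(np.array([1.0, 2, 3, 4]),
                                    np.array([0, 0, 1, 1]), "high")
        assert cut == pytest.approx(2.5)
        assert se == 100.0 and sp == 100.0

    def test_all_equal_values_give_zero_j(self):
        _, se, sp = youden_cutoff(np.ones(6), np.array([0, 0, 0, 1, 1, 1]), "high")
        assert se / 100 + sp / 100 - 1 == pytest.approx(0.0)

    def test_dichotomizing_at_cutoff_reproduces_max_j(self, rng):
        for _ in range(20):
            n = 40
            y = (rng.random(n) < 0.3).astype(int)
            if y.min() == y.max():
                continue
            x = rng.normal(size=n) + y
            cut, se, sp = youden_cutoff(x, y, "high")
            pos = x > cut
            se2 = (pos & (y == 1)).sum() / (y == 1).sum()
            sp2 = (~pos & (y == 0)).sum() / (y == 0).sum()
            assert se2 * 100 == pytest.approx(se)
            assert sp2 * 100 == pytest.approx(sp)

    def test_tie_broken_toward_sensitivity(self):
        # J = 0.5 at two thresholds; the Se-heavier one must win
        x = np.array([1.0, 2, 3, 4])
        y = np.array([0, 1, 0, 1])
        cut, se, sp = youden_cutoff(x, y, "high")
        assert cut == pytest.approx(1.5)
        assert se == 100.0 and sp == 50.0


class TestUnivariateReport:
    def test_rows_consistent_with_roc(self, rng):
        y = np.array([0] * 20 + [1] * 10)
        table = pd.DataFrame({"f1": rng.normal(size=30),
                              "f2": rng.normal(size=30) + y})
        rep = univariate_report(table, y)
        for col in table.columns:
            r = roc_auc(table[col].to_numpy(), y)
            assert rep.loc[col, "auc"] == pytest.approx(r.auc)
            assert rep.loc[col, "cutoff"] == pytest.approx(r.cutoff)

    def test_p_value_monotone_with_auc_at_fixed_n(self, rng):
        y = np.array([0] * 30 + [1] * 30)
        table = pd.DataFrame({
            f"f{i}": rng.normal(size=60) + 0.12 * i * y for i in range(6)
        })
        rep = univariate_report(table, y).sort_values("auc")
        assert (np.diff(rep["p_value"]) <= 1e-12).all()

    def test_clinical_only_when_no_radiomics(self, rng):
        y = np.array([0, 1] * 10)
        clin = pd.DataFrame({"age": rng.normal(65, 5, size=20)})
        rep = univariate_report(clin, y)
        assert list(rep.index) == ["age"]


class TestCox:
    def test_identical_event_experience_gives_unit_hr(self):
        # same survival data in both groups
        times = np.tile([5.0, 10, 15, 20, 25, 30], 2)
        events = np.tile([1, 0, 1, 0, 1, 0], 2)
        group = np.repeat([0, 1], 6)
        fit = cox_fit(pd.DataFrame({
            "group": group, "time_months": times, "event": events,
        }))
        assert fit.hr("group") == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_implementation(self):
        # 10-subject fixture, one covariate; oracle: statsmodels PHReg
        import statsmodels.api as sm

        times = np.array([3.0, 5, 6, 7, 8, 10, 12, 14, 15, 20])
        events = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1, 0])
        x = np.array([0.2, 1.1, -0.3, 0.8, 1.5, -0.9, 0.1, 1.9, -1.2, 0.4])
        fit = cox_fit(pd.DataFrame({
            "x": x, "time_months": times, "event": events,
        }))
        oracle = sm.PHReg(times, x[:, None], status=events, ties="efron").fit()
        assert np.log(fit.hr("x")) == pytest.approx(oracle.params[0], abs=1e-4)

    def test_planted_hazard_ratio_recovered(self, rng):
        # a couple of replicates here; the full 100-rep recovery check
        # lives in the acceptance suite
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 500
            x = r.integers(0, 2, size=n)
            t = r.exponential(1.0, size=n) / np.exp(np.log(3.0) * x)
            c = r.uniform(0, 2.0, size=n)
            fit = cox_fit(pd.DataFrame({
                "x": x,
                "time_months": np.minimum(t, c),
                "event": (t <= c).astype(int),
            }))
            assert 2.2 < fit.hr("x") < 4.0

    def test_separation_falls_back_to_penalized(self):
        times = np.array([1.0, 2, 3, 10, 11, 12])
        events = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0])
        fit = cox_fit(pd.DataFrame({
            "x": x, "time_months": times, "event": events,
        }))
        assert np.isfinite(fit.hr("x"))


class TestKaplanMeierLogrank:
    def test_identical_groups(self):
        res = km_logrank(np.array([0, 0, 1, 1]),
                        np.array([2.0, 4, 2, 4]),
                        np.array([1, 0, 1, 0]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_four_subject_hand_computed_fixture(self):
        # times 1,2,3,4; events 1,1,1,0; groups A,A,B,B
        # hypergeometric sums: O-E = 7/6, Var = 17/36, chi2 = 49/17
        res = km_logrank(np.array(["A", "A", "B", "B"]),
                        np.array([1.0, 2, 3, 4]),
                        np.array([1, 1, 1, 0]))
        assert res.statistic == pytest.approx(49 / 17, rel=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(49 / 17, 1), rel=1e-10)

    def test_km_without_censoring_is_empirical_survival(self, rng):
        times = rng.exponential(10, size=25)
        res = km_logrank(np.zeros(25), times, np.ones(25))
        curve = res.curves["0.0"] if "0.0" in res.curves else res.curves["0"]
        for t in np.quantile(times, [0.2, 0.5, 0.8]):
            emp = (times > t).mean()
            km_at = curve[curve["time"] <= t]["survival"].iloc[-1]
            assert km_at == pytest.approx(emp, abs=1e-12)
        steps = curve["survival"].diff().dropna()
        assert np.allclose(steps[steps < 0], -1 / 25)

    def test_logrank_p_uniform_under_permutation(self, rng):
        times = rng.exponential(10, size=30)
        events = (rng.random(30) < 0.7).astype(int)
        ps = []
        for _ in range(300):
            g = rng.permutation(np.repeat([0, 1], 15))
            ps.append(km_logrank(g, times, events).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestEvaluateModels:
    def _cohort(self, rng, n=60):
        y = (rng.random(n) < 0.3).astype(int)
        rad = pd.DataFrame({
            "ADC|LLL|FBN8|SZE": y * 1.6 + rng.normal(size=n),
            "ADC|LLL|FBN8|HGRE": rng.normal(size=n),
        })
        clin = pd.DataFrame({"age": rng.normal(65, 5, size=n) + 2 * y,
                             "psa_pre": rng.lognormal(2, 0.4, size=n)})
        t = np.where(y, rng.uniform(5, 40, size=n), rng.uniform(20, 90, size=n))
        outcome = pd.DataFrame({"event": y, "time_months": t})
        return rad, clin, outcome

    def test_reports_three_models_on_both_sides(self, rng):
        rad, clin, out = self._cohort(rng)
        comp = evaluate_models(rad[:40], rad[40:], clin[:40], clin[40:],
                               out[:40], out[40:])
        assert set(comp.results) == {"clinical", "radiomics", "combined"}
        for sides in comp.results.values():
            assert set(sides) == {"train", "test"}

    def test_additive_score_range(self, rng):
        rad, clin, out = self._cohort(rng)
        comp = evaluate_models(rad[:40], rad[40:], clin[:40], clin[40:],
                               out[:40], out[40:])
        from radbcr.survival import _score
        k = len(comp.factors["combined"])
        score = _score(comp.factors["combined"], pd.concat([rad, clin], axis=1))
        assert score.min() >= 0 and score.max() <= k

    def test_cutoffs_frozen_from_train(self, rng):
        rad, clin, out = self._cohort(rng)
        comp_a = evaluate_models(rad[:40], rad[40:], clin[:40], clin[40:],
                                 out[:40], out[40:])
        # perturbing only the test side must leave factors and cutoffs
        rad_p = rad.copy()
        rad_p.iloc[40:] = rng.normal(size=(20, 2))
        comp_b = evaluate_models(rad_p[:40], rad_p[40:], clin[:40], clin[40:],
                                 out[:40], out[40:])
        assert [vars(f) for fs in comp_a.factors.values() for f in fs] == \
               [vars(f) for fs in comp_b.factors.values() for f in fs]
        assert comp_a.score_cutoffs == comp_b.score_cutoffs

    def test_empty_radiomics_scores_chance(self, rng):
        rad, clin, out = self._cohort(rng)
        empty = rad.iloc[:, :0]
        comp = evaluate_models(empty[:40], empty[40:], clin[:40], clin[40:],
                               out[:40], out[40:])
        assert comp.results["radiomics"]["test"].auc == 0.5


def test_logistic_or_cross_check_against_statsmodels(rng):
    import statsmodels.api as sm

    n = 200
    x = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    logits = 0.8 * x["a"] - 0.4 * x["b"] - 1.0
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    ours = logistic_or_report(x, y)
    oracle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    np.testing.assert_allclose(
        np.log(ours["odds_ratio"]), oracle.params[["a", "b"]], atol=1e-6
    )
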