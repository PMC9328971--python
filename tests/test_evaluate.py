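"""Survival-curve, association, independence, decision-curve, nomogram and
panel-comparison checks against hand computations and library oracles.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ferropair as fp
from ferropair.evaluate import (
    build_nomogram,
    clinical_association,
    decision_curve,
    independence_cox,
    km_estimate,
    logrank_test,
    panel_group_compare,
)
from ferropair.types import SurvivalData

from conftest import expression_from_array


def surv_of(samples, time, event):
    return SurvivalData(pd.Index(samples), np.asarray(time), np.asarray(event))


def groups_of(samples, labels):
    return pd.Series(labels, index=samples)


class TestKaplanMeier:
    def test_hand_product_limit_all_events(self):
        samples = ["a", "b", "c"]
        curves = km_estimate(
            surv_of(samples, [1.0, 2.0, 3.0], [1, 1, 1]),
            groups_of(samples, ["g", "g", "g"]),
        )
        np.testing.assert_allclose(curves["g"].survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_is_one(self):
        samples = ["a", "b"]
        curves = km_estimate(
            surv_of(samples, [5.0, 9.0], [0, 0]), groups_of(samples, ["g", "g"])
        )
        assert (curves["g"].survival == 1.0).all()

    def test_censor_at_event_time_handled_after_event(self):
        # event and censoring at t=2: the censored subject counts in the
        # risk set of the event, so S(2) = 1 * (1 - 1/2) with 2 at risk
        samples = ["a", "b", "c"]
        curves = km_estimate(
            surv_of(samples, [1.0, 2.0, 2.0], [0, 1, 0]),
            groups_of(samples, ["g"] * 3),
        )
        km2 = curves["g"].survival[curves["g"].times == 2.0]
        assert km2[0] == pytest.approx(0.5)

    def test_empty_group_is_error(self):
        samples = ["a"]
        with pytest.raises((ValueError, KeyError)):
            km_estimate(
                surv_of(samples, [1.0], [1]), pd.Series([], dtype=object)
            )


def hand_logrank(time, event, group):
    """O-E/V log-rank by direct summation over event times."""
    stat_num, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        stat_num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = stat_num ** 2 / var
    return chi2, stats.chi2.sf(chi2, 1)


class TestLogrank:
    def test_identical_groups_give_null(self):
        samples = [f"s{i}" for i in range(8)]
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        stat, p = logrank_test(
            surv_of(samples, time, event),
            groups_of(samples, ["a"] * 4 + ["b"] * 4),
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation_on_four_subjects(self):
        samples = ["a", "b", "c", "d"]
        time = np.array([1.0, 2.0, 10.0, 20.0])
        event = np.array([1, 1, 1, 1])
        group = np.array([True, True, False, False])
        stat, p = logrank_test(
            surv_of(samples, time, event), groups_of(samples, ["A", "A", "B", "B"])
        )
        chi2, p_hand = hand_logrank(time, event, group)
        assert stat == pytest.approx(chi2, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_matches_hand_computation_with_censoring(self):
        rng = np.random.default_rng(30)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        group = rng.random(n) < 0.5
        time = rng.exponential(50, n) * np.exp(-0.8 * group)
        event = rng.random(n) < 0.7
        stat, p = logrank_test(
            surv_of(samples, time, event.astype(int)),
            groups_of(samples, np.where(group, "hi", "lo")),
        )
        chi2, p_hand = hand_logrank(time, event.astype(int), group)
        assert stat == pytest.approx(chi2, abs=1e-8)

    def test_three_groups_is_error(self):
        samples = ["a", "b", "c"]
        with pytest.raises(ValueError):
            logrank_test(
                surv_of(samples, [1, 2, 3], [1, 1, 1]),
                groups_of(samples, ["x", "y", "z"]),
            )


def make_profile(samples, scores, cutoff=0.0):
    return fp.RiskProfile(pd.Series(scores, index=samples, dtype=float), cutoff)


def make_clinical(samples, rng, time=None, event=None):
    n = len(samples)
    df = pd.DataFrame(
        {
            "time": rng.exponential(100, n) + 1 if time is None else time,
            "event": rng.binomial(1, 0.7, n) if event is None else event,
            "age": rng.integers(40, 80, n),
            "gender": rng.choice(["female", "male"], n),
            "grade": rng.choice(["G1", "G2", "G3"], n),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
            "T": rng.choice(["T1", "T2"], n),
            "N": rng.choice(["N0", "N1"], n),
            "M": rng.choice(["M0", "unknown"], n),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return fp.ClinicalTable(df)


class TestClinicalAssociation:
    def test_balanced_table_gives_zero_chi2(self):
        rng = np.random.default_rng(31)
        samples = [f"s{i}" for i in range(100)]
        # perfectly balanced 2x2: group x gender, 25 per cell
        scores = np.r_[np.ones(50), -np.ones(50)]
        clin = make_clinical(samples, rng)
        clin.data["gender"] = ["female", "male"] * 50
        prof = make_profile(samples, scores)
        rep = clinical_association(prof, clin)
        chi = rep[(rep.feature == "gender") & (rep.test == "chi2")].iloc[0]
        assert chi["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert chi["p"] == pytest.approx(1.0)

    def test_skewed_table_matches_contingency_oracle(self):
        rng = np.random.default_rng(32)
        samples = [f"s{i}" for i in range(80)]
        scores = np.r_[np.ones(40), -np.ones(40)]
        gender = ["female"] * 30 + ["male"] * 10 + ["female"] * 10 + ["male"] * 30
        clin = make_clinical(samples, rng)
        clin.data["gender"] = gender
        rep = clinical_association(make_profile(samples, scores), clin)
        chi = rep[(rep.feature == "gender") & (rep.test == "chi2")].iloc[0]
        # direct formula: sum (O-E)^2/E with all margins 40 -> 20 expected
        table = np.array([[30, 10], [10, 30]])
        expected = np.full((2, 2), 20.0)
        hand = ((table - expected) ** 2 / expected).sum()
        assert hand == pytest.approx(20.0)
        assert chi["statistic"] == pytest.approx(hand, abs=1e-10)
        assert chi["p"] < 0.001

    def test_ranksum_p_uniform_under_null(self):
        # identically drawn scores in two strata: p-values ~ U(0,1)
        rng = np.random.default_rng(33)
        pvals = []
        for _ in range(200):
            a = rng.normal(size=20)
            b = rng.normal(size=25)
            pvals.append(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_category_feature_skipped(self):
        rng = np.random.default_rng(34)
        samples = [f"s{i}" for i in range(40)]
        clin = make_clinical(samples, rng)
        clin.data["grade"] = "unknown"
        rep = clinical_association(
            make_profile(samples, rng.normal(size=40)), clin
        )
        assert "grade" not in set(rep["feature"])


class TestIndependenceCox:
    def test_planted_score_is_independent_predictor(self):
        rng = np.random.default_rng(35)
        n = 200
        samples = [f"s{i}" for i in range(n)]
        score = rng.normal(size=n)
        T = rng.exponential(100, n) * np.exp(-1.0 * score)
        C = rng.exponential(150, n)
        clin = make_clinical(
            samples, rng, time=np.minimum(T, C) + 1e-6, event=(T <= C).astype(int)
        )
        res = independence_cox(make_profile(samples, score), clin)
        multi_score = res.multivariate.set_index("covariate").loc["score"]
        uni_score = res.univariate.set_index("covariate").loc["score"]
        assert multi_score["p"] < 0.01 and uni_score["p"] < 0.01
        assert not res.collinear

    def test_duplicated_score_flags_collinearity(self):
        rng = np.random.default_rng(36)
        n = 60
        samples = [f"s{i}" for i in range(n)]
        clin = make_clinical(samples, rng)
        clin.data["age"] = 0.0  # constant: still fine
        prof = make_profile(samples, rng.normal(size=n))
        clin.data["age"] = prof.scores.to_numpy()  # age duplicates the score
        res = independence_cox(prof, clin)
        assert res.collinear

    def test_single_covariate_agrees_with_univariate_screen(self):
        from ferropair.cox import cox_fit_single

        rng = np.random.default_rng(37)
        n = 80
        samples = [f"s{i}" for i in range(n)]
        x = rng.binomial(1, 0.5, n).astype(float)
        time = rng.exponential(100, n) * np.exp(-0.7 * x) + 1e-9
        event = rng.binomial(1, 0.8, n)
        clin = fp.ClinicalTable(
            pd.DataFrame(
                {"time": time, "event": event},
                index=pd.Index(samples, name="sample_id"),
            )
        )
        res = independence_cox(make_profile(samples, x), clin)
        row = res.univariate.set_index("covariate").loc["score"]
        direct = cox_fit_single(x, time, event)
        assert np.log(row["hr"]) == pytest.approx(direct.beta, abs=1e-4)


class TestDecisionCurve:
    @staticmethod
    def perfect_toy():
        # 20 uncensored subjects; the 8 earliest deaths have the top scores
        n = 20
        samples = [f"s{i}" for i in range(n)]
        scores = pd.Series(np.arange(n, 0, -1.0), index=samples)
        time = np.arange(1.0, n + 1)
        surv = surv_of(samples, time, np.ones(n, dtype=int))
        return samples, scores, surv

    def test_treat_none_is_zero(self):
        _, scores, surv = self.perfect_toy()
        nb = decision_curve(scores, surv, horizon=8.5)
        assert (nb["nb_none"] == 0.0).all()

    def test_treat_all_limit_is_prevalence(self):
        _, scores, surv = self.perfect_toy()
        nb = decision_curve(scores, surv, horizon=8.5, grid=np.array([0.001]))
        prevalence = 8 / 20  # events by t=8.5, no censoring
        assert nb["nb_all"].iloc[0] == pytest.approx(prevalence, abs=1e-2)

    def test_perfect_model_attains_prevalence_at_low_thresholds(self):
        _, scores, surv = self.perfect_toy()
        nb = decision_curve(scores, surv, horizon=8.5)
        prevalence = 8 / 20
        # brute-force confusion counts: treating exactly the 8 cases gives
        # TP/n = prevalence, FP = 0, so NB = prevalence at any p_t
        assert nb["nb_model"].max() == pytest.approx(prevalence, abs=0.02)
        assert (nb["nb_model"] >= nb["nb_all"] - 1e-9).all()

    def test_empty_grid_is_error(self):
        _, scores, surv = self.perfect_toy()
        with pytest.raises(ValueError):
            decision_curve(scores, surv, horizon=8.5, grid=np.array([]))


class TestNomogram:
    @staticmethod
    def fitted(seed=38, n=120):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {
                "score": rng.normal(size=n),
                "age": rng.integers(40, 80, n).astype(float),
                "stage_hi": rng.binomial(1, 0.4, n).astype(float),
            },
            index=[f"s{i}" for i in range(n)],
        )
        lp = 1.0 * X["score"] + 0.02 * X["age"] + 0.5 * X["stage_hi"]
        T = rng.exponential(2000, n) * np.exp(-lp)
        C = rng.exponential(3000, n)
        surv = surv_of(
            list(X.index), np.minimum(T, C) + 1e-9, (T <= C).astype(int)
        )
        return X, surv

    def test_reference_profile_gets_zero_points(self):
        X, surv = self.fitted()
        nom = build_nomogram(X, surv)
        ref = nom.reference
        assert nom.points(ref).sum() == pytest.approx(0.0, abs=1e-10)

    def test_predictions_match_closed_form(self):
        X, surv = self.fitted()
        nom = build_nomogram(X, surv)
        horizon = float(np.quantile(surv.time, 0.5))
        idx = np.searchsorted(nom.baseline_times, horizon, side="right") - 1
        h0 = nom.baseline_cumhaz[idx]
        rng = np.random.default_rng(39)
        for _ in range(5):
            profile = X.iloc[rng.integers(0, len(X))]
            lp = float((profile * nom.betas).sum())
            expected = np.exp(-h0 * np.exp(lp))
            assert nom.predict_survival(profile, horizon) == pytest.approx(
                expected, abs=1e-9
            )

    def test_survival_decreases_with_linear_predictor(self):
        X, surv = self.fitted()
        nom = build_nomogram(X, surv)
        horizon = float(np.quantile(surv.time, 0.5))
        profiles = [X.iloc[i] for i in range(20)]
        lps = [nom.linear_predictor(p) for p in profiles]
        preds = [nom.predict_survival(p, horizon) for p in profiles]
        order = np.argsort(lps)
        assert (np.diff(np.array(preds)[order]) <= 1e-12).all()

    def test_extrapolation_refused(self):
        X, surv = self.fitted()
        nom = build_nomogram(X, surv)
        with pytest.raises(ValueError, match="extrapolation"):
            nom.predict_survival(X.iloc[0], surv.time.max() * 10)


class TestPanelCompare:
    @staticmethod
    def cohort(shift=0.0, n=100, seed=40):
        rng = np.random.default_rng(seed)
        genes = ["CTLA4", "PDCD1", "FLAT1"]
        half = n // 2
        vals = rng.lognormal(3, 0.5, size=(3, n))
        vals[0, :half] *= np.exp(shift)  # CTLA4 shifted in the high group
        vals[2] = 7.0  # FLAT1 identical everywhere
        em = expression_from_array(vals, genes, [f"s{i}" for i in range(n)], n)
        prof = make_profile(list(em.sample_ids), np.r_[np.ones(half), -np.ones(n - half)])
        return em, prof

    def test_identical_gene_has_p_one(self):
        em, prof = self.cohort()
        res = panel_group_compare(em, fp.GeneSet.from_iterable("p", ["FLAT1"]), prof)
        assert res.loc[res.gene == "FLAT1", "p"].iloc[0] == pytest.approx(1.0)

    def test_strongly_shifted_gene_is_significant(self):
        em, prof = self.cohort(shift=2.0)  # ~4 SD on the log scale
        res = panel_group_compare(
            em, fp.GeneSet.from_iterable("p", ["CTLA4", "PDCD1", "FLAT1"]), prof
        )
        row = res.set_index("gene").loc["CTLA4"]
        assert row["q"] < 0.001 and row["direction"] == "up"

    def test_missing_gene_reported_not_fatal(self):
        em, prof = self.cohort()
        res = panel_group_compare(
            em, fp.GeneSet.from_iterable("p", ["CTLA4", "GHOST"]), prof
        )
        ghost = res.set_index("gene").loc["GHOST"]
        assert not ghost["present"] and np.isnan(ghost["p"])

    def test_small_group_is_error(self):
        em, prof = self.cohort()
        tiny = fp.RiskProfile(prof.scores.iloc[:4], 0.0)
        with pytest.raises(ValueError):
            panel_group_compare(
                em, fp.GeneSet.from_iterable("p", ["CTLA4"]), tiny
            )
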