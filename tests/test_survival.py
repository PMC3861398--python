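"""KM/log-rank, chi-square association, ROC for recurrence, Cox models."""

import numpy as np
import pandas as pd
import pytest
from helpers import cox_score_test_oracle, km_survival_oracle
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from nestmorph import (SurvRecord, chisq_association, cox_multivariate,
                       km_logrank, roc_for_recurrence)


def _df(t, e):
    return pd.DataFrame({"time": t, "event": e})


class TestKMLogrank:
    def test_no_events_curve_constant_at_one(self):
        g = _df([5.0, 10.0, 20.0], [0, 0, 0])
        curves, chisq, p = km_logrank([g, g.copy()])
        for c in curves:
            assert (c.survival == 1.0).all()
        assert chisq == pytest.approx(0.0, abs=1e-12)

    def test_identical_groups_give_zero_chisq(self, rng):
        t = rng.exponential(20, 50)
        e = rng.integers(0, 2, 50)
        _, chisq, p = km_logrank([_df(t, e), _df(t, e)])
        assert chisq == pytest.approx(0.0, abs=1e-9)
        assert p > 0.9

    def test_km_equals_empirical_survivor_without_censoring(self, rng):
        t = rng.exponential(15, 40)
        e = np.ones(40, int)
        curves, _, _ = km_logrank([_df(t, e), _df(rng.exponential(15, 40), e)])
        c = curves[0]
        for q in [np.min(t), np.median(t), np.percentile(t, 90)]:
            assert c.at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_km_matches_textbook_oracle_with_censoring(self, rng):
        t = rng.exponential(15, 60)
        e = rng.integers(0, 2, 60)
        curves, _, _ = km_logrank([_df(t, e), _df(t, e)])
        for q in [5.0, 12.0, 30.0]:
            assert curves[0].at(q) == pytest.approx(
                km_survival_oracle(t, e, q), abs=1e-12)

    def test_relabeling_invariance(self, rng):
        gs = [_df(rng.exponential(s, 40), rng.integers(0, 2, 40))
              for s in (10, 20, 30)]
        _, chi_a, _ = km_logrank(gs)
        _, chi_b, _ = km_logrank(gs[::-1])
        assert chi_a == pytest.approx(chi_b, abs=1e-9)

    def test_power_against_true_hazard_ratio_two(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(900 + rep)
            a = _df(rng.exponential(50, 500), np.ones(500, int))
            b = _df(rng.exponential(25, 500), np.ones(500, int))
            _, _, p = km_logrank([a, b])
            hits += p < 0.05
        assert hits >= 0.95 * n_rep

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([_df([1.0], [1]), _df([], [])])

    def test_accepts_record_sequences(self):
        recs = [SurvRecord("P1", 5.0, 1), SurvRecord("P2", 9.0, 0)]
        curves, chisq, _ = km_logrank([recs, recs])
        assert chisq == pytest.approx(0.0, abs=1e-12)

    def test_cox_score_test_equals_logrank_without_ties(self, rng):
        """Classical identity between the 2-group log-rank chi-square and the
        Cox partial-likelihood score test at beta = 0."""
        t = rng.exponential(20, 80)
        e = rng.integers(0, 2, 80)
        x = rng.integers(0, 2, 80)
        while len(np.unique(x)) < 2:
            x = rng.integers(0, 2, 80)
        _, chisq, _ = km_logrank([_df(t[x == 0], e[x == 0]),
                                  _df(t[x == 1], e[x == 1])])
        assert chisq == pytest.approx(cox_score_test_oracle(t, e, x), abs=1e-8)


class TestChisqAssociation:
    def test_identical_balanced_vectors(self):
        v = np.repeat([0, 1, 2], 30)
        chi2, p = chisq_association(v, v)
        assert chi2 == pytest.approx(90 * 2, abs=1e-9)  # n (k - 1)
        assert p < 1e-12

    def test_hand_computed_2x2(self):
        a = [0] * 10 + [1] * 10
        b = [0] * 10 + [1] * 10
        chi2, _ = chisq_association(a, b)
        assert chi2 == pytest.approx(20.0, abs=1e-9)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            chisq_association([1, 1, 1], [0, 1, 0])

    def test_independent_categories_p_roughly_uniform(self):
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            ps.append(chisq_association(rng.integers(0, 3, 300),
                                        rng.integers(0, 3, 300))[1])
        ps = np.array(ps)
        # null p-values: mean near 0.5, rejection near nominal
        assert abs(ps.mean() - 0.5) < 0.08
        assert ((ps < 0.05).mean()) < 0.12


class TestRoc:
    def test_perfect_marker(self):
        t = np.array([10.0] * 20 + [70.0] * 20)
        e = np.array([1] * 20 + [0] * 20)
        marker = np.array([5.0] * 20 + [1.0] * 20)
        r = roc_for_recurrence(marker, t, e)
        assert r.auc == 1.0
        assert r.p_value < 1e-6
        assert r.n_pos == 20 and r.n_neg == 20

    def test_censored_before_horizon_excluded(self):
        t = np.array([10.0, 30.0, 70.0, 80.0, 20.0])
        e = np.array([1, 0, 0, 0, 1])
        r = roc_for_recurrence(np.arange(5.0), t, e)
        assert r.n_excluded == 1  # the patient censored at 30 months
        assert r.n_pos == 2 and r.n_neg == 2

    def test_empty_class_rejected(self):
        t = np.array([70.0, 80.0])
        e = np.array([0, 0])
        with pytest.raises(ValueError):
            roc_for_recurrence(np.array([1.0, 2.0]), t, e)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 100_000))
    def test_auc_equals_mann_whitney_identity(self, seed):
        """Trapezoidal AUC == U / (n_pos * n_neg), ties included."""
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 120)
        marker = rng.choice([0.0, 0.5, 1.0, 2.0, 3.5], size=n)  # force ties
        t = rng.exponential(40, n)
        e = rng.integers(0, 2, n)
        pos = (e == 1) & (t <= 60.0)
        neg = ~pos & (t >= 60.0)
        if pos.sum() == 0 or neg.sum() == 0:
            return
        r = roc_for_recurrence(marker, t, e)
        U = mannwhitneyu(marker[pos], marker[neg]).statistic
        assert abs(r.auc - U / (pos.sum() * neg.sum())) < 1e-12

    def test_ci_contains_auc(self, rng):
        marker = rng.normal(size=120)
        t = rng.exponential(40, 120)
        e = rng.integers(0, 2, 120)
        r = roc_for_recurrence(marker, t, e)
        assert r.ci95[0] <= r.auc <= r.ci95[1]


class TestCox:
    def test_binary_covariate_hazard_ratio_recovery(self):
        rng = np.random.default_rng(21)
        n = 2000
        x = rng.integers(0, 2, n)
        lam = 0.02 * 1.5**x
        t = rng.exponential(1.0 / lam)
        cens = rng.exponential(120.0, n)
        time = np.minimum(t, cens)
        event = (t <= cens).astype(int)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        res = cox_multivariate(df, ["x"])
        assert 1.35 <= res.summary.loc["x", "hr"] <= 1.65
        assert res.summary.loc["x", "ci_low"] <= res.summary.loc["x", "hr"] \
            <= res.summary.loc["x", "ci_high"]

    def test_constant_covariate_rejected(self, rng):
        df = pd.DataFrame({"time": rng.exponential(20, 50),
                           "event": np.ones(50, int),
                           "x": np.zeros(50)})
        with pytest.raises(ValueError, match="degenerate"):
            cox_multivariate(df, ["x"])

    def test_null_covariate_ci_contains_one(self, rng):
        n = 800
        df = pd.DataFrame({
            "time": rng.exponential(30, n),
            "event": rng.integers(0, 2, n),
            "signal": rng.integers(1, 4, n),
            "noise": rng.integers(0, 2, n),
        })
        res = cox_multivariate(df, ["signal", "noise"])
        assert res.summary.loc["noise", "ci_low"] <= 1.0 \
            <= res.summary.loc["noise", "ci_high"]

    def test_result_counts(self, rng):
        n = 100
        df = pd.DataFrame({"time": rng.exponential(20, n),
                           "event": rng.integers(0, 2, n),
                           "x": rng.integers(0, 2, n)})
        res = cox_multivariate(df, ["x"])
        assert res.n == n
        assert res.n_events == int(df["event"].sum())
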