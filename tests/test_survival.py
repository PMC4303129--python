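"""Kaplan-Meier, log-rank and Cox models: hand oracles and recovery checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

from methclust.simulate import generate_survival
from methclust.survival import (
    breslow_cox,
    cox_fit,
    cox_score_test,
    kaplan_meier,
    log_rank,
    ph_check,
)


def _records(times, events, **cols):
    df = pd.DataFrame({"time": times, "event": events})
    for k, v in cols.items():
        df[k] = v
    return df


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # {(1,event),(2,censored),(3,event)}: S = 2/3 after t=1 (3 at risk),
        # unchanged at the censoring, then 0 after t=3 (1 at risk, 1 event)
        km = kaplan_meier(_records([1, 2, 3], [1, 0, 1]))["all"]
        surv = dict(zip(km["time"], km["survival"]))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(2 / 3)  # censoring does not drop S
        assert surv[3.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(10, size=50)
        km = kaplan_meier(_records(t, np.ones(50, dtype=int)))["all"]
        for time, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((t > time).mean(), abs=1e-12)

    def test_all_censored_flat_at_one(self):
        km = kaplan_meier(_records([1, 2, 3], [0, 0, 0]))["all"]
        assert (km["survival"] == 1.0).all()

    def test_all_event_curve_integrates_to_mean(self, rng):
        t = np.sort(rng.exponential(5, size=40))
        km = kaplan_meier(_records(t, np.ones(40, dtype=int)))["all"]
        grid = np.concatenate([[0.0], km["time"].to_numpy()])
        surv = np.concatenate([[1.0], km["survival"].to_numpy()])
        # left-continuous step integral of S(t) up to the largest time
        area = np.sum(np.diff(grid) * surv[:-1])
        assert area == pytest.approx(t.mean(), rel=1e-9)


class TestLogRank:
    def test_identical_groups_null(self):
        rec = _records([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0], g=[1, 1, 1, 2, 2, 2])
        chi2, df, p = log_rank(rec, "g")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_event_table(self):
        # groups A: events at 1, 3; B: events at 2, 4 (no censoring).
        # O-E for A: t=1 (2/4), t=2 (1/3), t=3 (1/2), t=4 (0)
        rec = _records([1, 3, 2, 4], [1, 1, 1, 1], g=list("AABB"))
        o_minus_e = (1 - 2 / 4) + (0 - 1 / 3) + (1 - 1 / 2) + 0
        # hypergeometric variance at each event time: n1*n2*d*(n-d)/(n^2*(n-1))
        var = (2 * 2 * 1 * 3) / (16 * 3) + (1 * 2 * 1 * 2) / (9 * 2) + (1 * 1 * 1 * 1) / (4 * 1)
        chi2, df, p = log_rank(rec, "g")
        assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-9)

    def test_label_permutation_invariant(self, rng):
        t = rng.exponential(5, 30)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        rec = _records(t, e, g=g)
        chi2a, _, _ = log_rank(rec, "g")
        rec2 = rec.assign(g=1 - rec["g"])
        chi2b, _, _ = log_rank(rec2, "g")
        assert chi2a == pytest.approx(chi2b)

    def test_equals_cox_score_test_on_tie_free_data(self, rng):
        t = rng.exponential(5, 40) + rng.uniform(0, 1e-6, 40)  # tie-free
        e = rng.integers(0, 2, 40)
        e[0] = 1
        g = rng.integers(0, 2, 40)
        rec = _records(t, e, g=g)
        chi2_lr, _, _ = log_rank(rec, "g")
        chi2_score, _ = cox_score_test(g.astype(float), t, e)
        assert chi2_lr == pytest.approx(chi2_score, abs=1e-6)


class TestCox:
    def test_small_instance_matches_score_equation_root(self, rng):
        """The fitted coefficient solves the partial-likelihood score
        equation; compare against an independent brentq root of the
        hand-assembled score function (tie-free data)."""
        n = 30
        t = rng.exponential(5, n) + rng.uniform(0, 1e-9, n)
        x = rng.integers(0, 2, n).astype(float)
        e = np.ones(n, dtype=int)

        def score(beta):
            order = np.argsort(t)
            ts, xs = t[order], x[order]
            total = 0.0
            for i in range(n):
                risk = ts >= ts[i]
                w = np.exp(beta * xs[risk])
                total += xs[i] - (w * xs[risk]).sum() / w.sum()
            return total

        root = brentq(score, -5, 5)
        fit = cox_fit(_records(t, e, x=x), ["x"])
        assert fit.table.loc["x", "coef"] == pytest.approx(root, abs=1e-4)
        coef_b, _, _ = breslow_cox(x, t, e)
        assert coef_b[0] == pytest.approx(root, abs=1e-6)

    def test_efron_and_breslow_agree_without_ties(self, rng):
        n = 60
        t = rng.exponential(5, n) + rng.uniform(0, 1e-9, n)
        e = rng.integers(0, 2, n)
        e[:5] = 1
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        rec = _records(t, e, a=x1, b=x2)
        efron = cox_fit(rec, ["a", "b"], ties="efron")
        breslow = cox_fit(rec, ["a", "b"], ties="breslow")
        for term in ("a", "b"):
            assert efron.table.loc[term, "coef"] == pytest.approx(
                breslow.table.loc[term, "coef"], abs=1e-5
            )
            assert efron.table.loc[term, "se"] == pytest.approx(
                breslow.table.loc[term, "se"], rel=1e-3
            )

    def test_hr_and_ci_consistency(self, rng):
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        x = rng.normal(size=50)
        fit = cox_fit(_records(t, e, x=x), ["x"])
        row = fit.table.loc["x"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci_lower"] <= row["hr"] <= row["ci_upper"]

    def test_null_covariate_ci_coverage(self):
        """Covariate independent of hazard: 95% CI covers 0 at ~95% rate."""
        hits = 0
        n_reps = 120
        for rep in range(n_reps):
            rng = np.random.default_rng(4000 + rep)
            t = rng.exponential(10, 150)
            c = rng.exponential(20, 150)
            time = np.minimum(t, c)
            e = (t <= c).astype(int)
            x = rng.normal(size=150)
            fit = cox_fit(_records(time, e, x=x), ["x"])
            lo = fit.table.loc["x", "coef"] - 1.96 * fit.table.loc["x", "se"]
            hi = fit.table.loc["x", "coef"] + 1.96 * fit.table.loc["x", "se"]
            hits += lo <= 0 <= hi
        assert 0.90 <= hits / n_reps <= 0.99

    def test_time_rescaling_invariance(self, rng):
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        x = rng.normal(size=60)
        f1 = cox_fit(_records(t, e, x=x), ["x"])
        f2 = cox_fit(_records(t * 12.0, e, x=x), ["x"])
        assert f1.table.loc["x", "coef"] == pytest.approx(f2.table.loc["x", "coef"], rel=1e-6)

    def test_constant_term_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(_records([1, 2, 3], [1, 1, 0], x=[1.0, 1.0, 1.0]), ["x"])

    def test_invalid_ties_rejected(self):
        with pytest.raises(ValueError, match="ties"):
            cox_fit(_records([1, 2], [1, 1], x=[0.0, 1.0]), ["x"], ties="exact")

    def test_planted_hazard_ratio_recovered(self):
        """Mean univariate HR over replicates lands near the planted 1.91."""
        planted = 1.91
        model = {
            "baseline_hazard": 0.01,
            "log_hr": (0.0, float(np.log(planted)), 0.0, 0.0),
            "censoring_rate": 0.3,
        }
        coefs = []
        for rep in range(60):
            rng = np.random.default_rng(5000 + rep)
            labels = pd.Series(rng.integers(1, 5, size=400))
            out = generate_survival(labels, model, rng=rng)
            for g in (1, 2, 3):
                out[f"g{g}"] = (labels == g).astype(float).to_numpy()
            fit = cox_fit(out, ["g1", "g2", "g3"])
            coefs.append(fit.table.loc["g2", "coef"])
        assert np.exp(np.mean(coefs)) == pytest.approx(planted, abs=0.15)


class TestPHCheck:
    def test_proportional_data_rarely_rejected(self):
        rejections = 0
        n_reps = 40
        for rep in range(n_reps):
            rng = np.random.default_rng(6000 + rep)
            x = rng.integers(0, 2, 120).astype(float)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
            c = rng.exponential(30, 120)
            rec = _records(np.minimum(t, c), (t <= c).astype(int), x=x)
            fit = cox_fit(rec, ["x"])
            out = ph_check(fit)
            rejections += out.loc["x", "p"] < 0.05
        assert rejections / n_reps <= 0.15

    def test_time_varying_effect_detected(self):
        rejections = 0
        n_reps = 25
        for rep in range(n_reps):
            rng = np.random.default_rng(7000 + rep)
            n = 300
            x = rng.integers(0, 2, n).astype(float)
            # effect reverses over time: early hazard up, late hazard down
            t = np.where(
                x == 1,
                np.where(rng.random(n) < 0.7, rng.exponential(2, n), rng.exponential(60, n)),
                rng.exponential(12, n),
            )
            rec = _records(t, np.ones(n, dtype=int), x=x)
            fit = cox_fit(rec, ["x"])
            out = ph_check(fit)
            rejections += out.loc["x", "p"] < 0.05
        assert rejections / n_reps >= 0.8

    def test_degenerate_single_event_time_skipped(self):
        rec = _records([5, 5, 7, 8], [1, 1, 0, 0], x=[0.0, 1.0, 0.0, 1.0])
        fit = cox_fit(rec, ["x"])
        assert ph_check(fit) is None
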