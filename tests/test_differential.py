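"""Rank tests, adjusted linear models, FDR, overlaps, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methclust.differential import (
    bh_fdr,
    default_covariate_spec,
    direction_summary,
    fit_probe_model,
    kruskal_wallis,
    methylation_expression_correlation,
    overlap_sets,
    run_comparison,
    signature_overlap_test,
    wilcoxon_rank_sum,
)
from methclust.preprocess import logit_transform


# ---------------------------------------------------------------- oracles
def exact_wilcoxon_p(x, y):
    """Enumeration oracle: two-sided p over all C(n+m, n) rank splits."""
    combined = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(combined)
    observed = ranks[:n].sum()
    splits = list(itertools.combinations(range(len(combined)), n))
    sums = np.array([ranks[list(s)].sum() for s in splits])
    mean = sums.mean()
    p = np.mean(np.abs(sums - mean) >= np.abs(observed - mean) - 1e-12)
    return p


def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_tail(k, N, K, n):
    """Direct summation of the upper hypergeometric tail P(X >= k)."""
    from math import comb

    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / comb(N, n)


# ---------------------------------------------------------------- rank tests
class TestWilcoxon:
    def test_enumeration_example(self):
        # A={1,2,3}, B={4,5,6}: 2 extreme splits of 20 -> p = 0.1
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @given(data=st.data())
    @settings(deadline=None, max_examples=100)
    def test_exact_p_matches_enumeration(self, data):
        n = data.draw(st.integers(2, 5))
        m = data.draw(st.integers(2, 10 - n))
        vals = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False),
                min_size=n + m, max_size=n + m, unique=True,
            )
        )
        x, y = np.array(vals[:n]), np.array(vals[n:])
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_statistic_is_u_statistic(self, rng):
        for _ in range(30):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            stat, _ = wilcoxon_rank_sum(x, y)
            ranks = stats.rankdata(np.concatenate([x, y]))
            rank_sum = ranks[: len(x)].sum()
            u = rank_sum - len(x) * (len(x) + 1) / 2  # rank-sum minus its minimum
            assert stat == pytest.approx(u)


class TestKruskal:
    def test_all_equal_is_null(self):
        h, p = kruskal_wallis([1.0, 1.0], [1.0, 1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_two_groups_matches_squared_z(self, rng):
        # chi2 on 1 df is z^2: KW p equals the (no-continuity) normal-approx
        # rank-sum p on tie-free data
        x = rng.normal(size=20)
        y = rng.normal(1.0, 1, size=25)
        h, p_kw = kruskal_wallis(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        assert p_kw == pytest.approx(res.pvalue, abs=1e-6)

    def test_hand_computed_three_groups(self):
        # groups {1,2}, {3,4}, {5,6}: ranks 1..6, H = 12/(6*7) * sum(R^2/n) - 3*7
        groups = ([1, 2], [3, 4], [5, 6])
        rank_sums = [3, 7, 11]
        expected_h = 12 / (6 * 7) * sum(r**2 / 2 for r in rank_sums) - 3 * 7
        h, p = kruskal_wallis(*groups)
        assert h == pytest.approx(expected_h)
        assert p == pytest.approx(stats.chi2.sf(expected_h, df=2))


# ---------------------------------------------------------------- OLS models
class TestProbeModel:
    def test_orthogonal_covariate_leaves_group_difference(self, rng):
        # balanced factor, covariate orthogonal to it and with zero effect:
        # coefficient equals the raw group mean difference on the logit scale
        n = 40
        factor = pd.Series(np.repeat([0.0, 1.0], n // 2))
        # +1/-1 alternating within each factor group: orthogonal to both the
        # factor contrast and the intercept
        cov = pd.DataFrame({"z": np.tile([1.0, -1.0], n // 2)})
        y = pd.Series(rng.normal(size=n)) + 0.7 * factor
        coef, _ = fit_probe_model(y, factor, cov)
        raw_diff = y[factor == 1].mean() - y[factor == 0].mean()
        assert coef == pytest.approx(raw_diff, abs=1e-10)

    def test_rank_deficient_raises(self):
        y = pd.Series(np.arange(6, dtype=float))
        factor = pd.Series([0.0, 1.0] * 3)
        cov = pd.DataFrame({"dup": factor})  # collinear with factor
        with pytest.raises(np.linalg.LinAlgError):
            fit_probe_model(y, factor, cov)

    def test_matrix_route_matches_statsmodels(self, rng):
        # the vectorised many-probe OLS must agree with probe-wise statsmodels
        n, n_probes = 60, 5
        ann = pd.DataFrame(
            {
                "f": rng.integers(0, 2, n).astype(float),
                "age": rng.uniform(30, 70, n),
            },
            index=[f"t{i}" for i in range(n)],
        )
        beta = pd.DataFrame(
            rng.beta(2, 2, size=(n_probes, n)),
            index=[f"cg{i}" for i in range(n_probes)],
            columns=ann.index,
        )
        spec = default_covariate_spec()
        spec.adjustments["toy"] = ["age"]
        res = run_comparison(beta, ann, "toy", "f", spec=spec, contrast=(0.0, 1.0))
        for probe in beta.index:
            y = logit_transform(beta.loc[probe], eps=1e-3)
            coef, p = fit_probe_model(y, ann["f"], ann[["age"]])
            assert res.loc[probe, "estimate"] == pytest.approx(coef, rel=1e-9)
            assert res.loc[probe, "raw_p"] == pytest.approx(p, rel=1e-6)

    def test_own_outcome_adjustment_rejected(self, rng):
        ann = pd.DataFrame({"stage": [1, 2] * 5, "age": rng.uniform(30, 70, 10)})
        beta = pd.DataFrame(rng.beta(2, 2, size=(2, 10)), columns=ann.index)
        spec = default_covariate_spec()
        spec.adjustments["toy"] = ["age", "stage"]
        with pytest.raises(ValueError, match="own factor"):
            run_comparison(beta, ann, "toy", "stage", spec=spec, ordinal=True)

    def test_global_null_fdr_control(self, rng):
        """No planted effects: at most 1% of probes reach q < 0.05."""
        n, n_probes = 200, 500
        ann = pd.DataFrame(
            {
                "f": rng.integers(0, 2, n).astype(float),
                "age": rng.uniform(25, 75, n),
                "race": rng.choice(["A", "B"], n),
                "menopause": rng.choice(["Pre", "Post"], n),
                "stage": rng.choice([1, 2, 3, 4], n),
            },
            index=[f"t{i}" for i in range(n)],
        )
        beta = pd.DataFrame(
            rng.beta(5, 5, size=(n_probes, n)),
            index=[f"cg{i}" for i in range(n_probes)],
            columns=ann.index,
        )
        res = run_comparison(beta, ann, "hr_status", "f", contrast=(0.0, 1.0))
        assert (res["q"] < 0.05).mean() <= 0.01

    def test_planted_effects_detected_with_direction(self, rng):
        """+0.3 β shift at 50 of 300 probes, n=400: >=90% flagged, all hyper."""
        n, n_probes, n_planted = 400, 300, 50
        group = rng.integers(0, 2, n).astype(float)
        means = np.full((n_probes, n), 0.3)
        means[:n_planted, group == 1] = 0.6
        conc = 50.0
        beta_vals = rng.beta(means * conc, (1 - means) * conc)
        ann = pd.DataFrame(
            {
                "f": group,
                "age": rng.uniform(25, 75, n),
                "race": rng.choice(["A", "B"], n),
                "menopause": rng.choice(["Pre", "Post"], n),
                "stage": rng.choice([1, 2, 3, 4], n),
            },
            index=[f"t{i}" for i in range(n)],
        )
        beta = pd.DataFrame(beta_vals, index=[f"cg{i}" for i in range(n_probes)],
                            columns=ann.index)
        res = run_comparison(beta, ann, "hr_status", "f", contrast=(0.0, 1.0))
        planted = res.iloc[:n_planted]
        flagged = planted[planted["q"] < 0.05]
        assert len(flagged) >= 0.9 * n_planted
        assert (flagged["direction"] == "hyper").all()
        # sign of every estimate matches the adjusted group difference in mean logit
        lb = logit_transform(beta, eps=1e-3)
        diff = lb.loc[:, group == 1].mean(axis=1) - lb.loc[:, group == 0].mean(axis=1)
        strong = res["raw_p"] < 1e-4
        assert (np.sign(res.loc[strong, "estimate"]) == np.sign(diff[strong])).all()


# ---------------------------------------------------------------- FDR
class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_constant(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60)
    )
    @settings(deadline=None, max_examples=150)
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=100)
        assert (bh_fdr(p) >= p - 1e-15).all()

    def test_fdr_controlled_under_null(self, rng):
        """>=200 null replicates: mean fraction of q<0.05 discoveries <= 0.05."""
        fdr_events = []
        for _ in range(200):
            x = rng.standard_normal((100, 10))
            y = rng.standard_normal((100, 12))
            p = stats.ttest_ind(x, y, axis=1).pvalue
            fdr_events.append((bh_fdr(p) < 0.05).mean())
        assert np.mean(fdr_events) <= 0.05


# ---------------------------------------------------------------- summaries
class TestSummaries:
    def _results(self, qs, dirs):
        return pd.DataFrame({"q": qs, "direction": dirs})

    def test_direction_partition(self, rng):
        qs = rng.uniform(size=40)
        dirs = rng.choice(["hyper", "hypo"], size=40)
        res = self._results(qs, dirs)
        n_hyper, n_hypo = direction_summary(res)
        assert n_hyper + n_hypo == (qs < 0.05).sum()

    def test_no_significant_gives_zeros(self):
        res = self._results([0.9, 0.8], ["hyper", "hypo"])
        assert direction_summary(res) == (0, 0)

    def test_overlap_matches_brute_force(self, rng):
        for _ in range(100):
            universe = list(range(30))
            sets = {
                name: set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
                for name in "ABC"
            }
            regions = overlap_sets(sets)
            assert sum(regions.values()) == len(set().union(*sets.values()))
            for el in set().union(*sets.values()):
                key = frozenset(n for n in "ABC" if el in sets[n])
                assert regions[key] >= 1
        disjoint = overlap_sets({"A": {1}, "B": {2}, "C": {3}})
        assert frozenset("ABC") not in disjoint
        identical = overlap_sets({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
        assert identical == {frozenset("ABC"): 2}


class TestSignatureOverlap:
    def test_saturated_table_p_one(self):
        bg = set(range(20))
        assert signature_overlap_test(bg, bg, bg) == pytest.approx(1.0)

    def test_matches_tail_sum(self):
        from conftest import TEST_SEED

        rng = np.random.default_rng(TEST_SEED)
        # (overlap 8, 2, 2, 88): N=100, list 10, signature 10
        bg = set(range(100))
        a = set(range(10))
        b = set(range(8)) | {50, 51}
        p = signature_overlap_test(a, b, bg)
        assert p == pytest.approx(hypergeom_tail(8, 100, 10, 10), rel=1e-9)
        for _ in range(50):
            a = set(rng.choice(100, size=rng.integers(1, 30), replace=False))
            b = set(rng.choice(100, size=rng.integers(1, 30), replace=False))
            k = len(a & b)
            expected = hypergeom_tail(k, 100, len(b), len(a))
            assert signature_overlap_test(a, b, bg) == pytest.approx(expected, rel=1e-9)

    def test_empty_overlap_with_large_sets_near_one(self):
        bg = set(range(100))
        p = signature_overlap_test(set(range(40)), set(range(40, 80)), bg)
        assert p > 0.999


# ---------------------------------------------------------------- correlation
class TestMethylationExpression:
    def _frames(self, b, e):
        beta = pd.DataFrame([b], index=["cg1"], columns=[f"t{i}" for i in range(len(b))])
        expr = pd.DataFrame([e], index=["G1"], columns=beta.columns)
        return beta, expr

    def test_perfect_anticorrelation(self, rng):
        b = rng.uniform(size=20)
        beta, expr = self._frames(b, -b)
        out = methylation_expression_correlation(beta, expr, pd.Series({"cg1": "G1"}))
        assert out.loc[0, "r"] == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self, rng):
        n, rho = 300, -0.6
        z = rng.standard_normal(n)
        b = stats.norm.cdf(z)
        e = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        beta, expr = self._frames(b, e)
        out = methylation_expression_correlation(beta, expr, pd.Series({"cg1": "G1"}))
        assert out.loc[0, "r"] == pytest.approx(rho, abs=0.1)

    def test_independent_data_null_p(self):
        pvals = []
        for rep in range(100):
            rng = np.random.default_rng(3000 + rep)
            b = rng.uniform(size=50)
            e = rng.standard_normal(50)
            beta, expr = self._frames(b, e)
            out = methylation_expression_correlation(beta, expr, pd.Series({"cg1": "G1"}))
            pvals.append(out.loc[0, "p"])
        assert np.mean(np.array(pvals) < 0.05) < 0.15
        assert 0.35 < np.mean(pvals) < 0.65

    def test_strata_and_min_pairs(self, rng):
        b = rng.uniform(size=10)
        beta, expr = self._frames(b, -b)
        strata = pd.Series(["X"] * 8 + ["Y"] * 2, index=beta.columns)
        out = methylation_expression_correlation(
            beta, expr, pd.Series({"cg1": "G1"}), strata=strata
        )
        assert set(out["stratum"]) == {"all", "X"}  # Y has <3 pairs, skipped
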