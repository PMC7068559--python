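"""Correlations, DLA regression, effect sizes, logistic tests, BH control."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from drunklens.association import (
    aggregate_to_groups,
    benjamini_hochberg,
    cohens_d,
    community_contrasts,
    dla_regression,
    logistic_pvalue,
    pearson_with_ci,
)
from drunklens.evaluation import pearson_reference, stepup_bh_reference


class TestPearson:
    def test_affine_dependence(self):
        x = np.arange(10.0)
        r, lo, hi, p = pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, *_ = pearson_with_ci([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_example(self):
        # direct formula: cov sum = 10, sx^2 sum = 10, sy^2 sum = 14.8
        r, lo, hi, p = pearson_with_ci([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10 / np.sqrt(10 * 14.8), abs=1e-12)
        assert r == pytest.approx(pearson_reference([1, 2, 3, 4, 5], [2, 1, 4, 3, 6]))
        assert lo < r < hi

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1, 1, 1], [1, 2, 3])

    def test_ci_fisher_z(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r, lo, hi, p = pearson_with_ci(x, y)
        zr, se = np.arctanh(r), 1 / np.sqrt(47)
        assert lo == pytest.approx(np.tanh(zr - 1.959963984540054 * se))
        assert hi == pytest.approx(np.tanh(zr + 1.959963984540054 * se))


class TestAggregateToGroups:
    def test_identity_and_mean(self):
        vals = {"a": 2.0, "b": 4.0, "c": 5.0}
        groups = {"a": "g1", "b": "g1", "c": "g2"}
        out = aggregate_to_groups(vals, groups)
        assert out.loc["g1", "mean"] == pytest.approx(3.0)
        assert out.loc["g2", "mean"] == pytest.approx(5.0)
        assert out.loc["g1", "n"] == 2

    def test_permutation_invariance(self):
        vals = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        groups = pd.Series({"a": "x", "b": "y", "c": "x", "d": "y"})
        fwd = aggregate_to_groups(vals, groups)
        rev = aggregate_to_groups(vals[::-1], groups[::-1])
        pd.testing.assert_frame_equal(fwd, rev)


class TestDlaRegression:
    def _loadings(self, arr, counties=None):
        arr = np.atleast_2d(np.asarray(arr, dtype=float)).T
        counties = counties or [f"c{i}" for i in range(arr.shape[0])]
        return pd.DataFrame(arr, index=counties,
                            columns=[f"topic_{k:03d}" for k in range(arr.shape[1])])

    def test_identical_loading_and_outcome(self):
        vals = np.linspace(0.1, 0.3, 10)
        loadings = self._loadings(vals)
        out = dla_regression(loadings, pd.Series(vals, index=loadings.index))
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["p_raw"] == 0.0

    def test_ols_p_equals_pearson_p(self, rng):
        """Single-predictor OLS t-test p == correlation-test p (identity)."""
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        loadings = self._loadings(x)
        out = dla_regression(loadings, pd.Series(y, index=loadings.index))
        _, p_ref = stats.pearsonr(x, y)
        assert out.iloc[0]["p_raw"] == pytest.approx(p_ref, rel=1e-9)

    def test_null_p_values_uniform(self):
        """Independent loadings: raw p over 100 seeds x 10 topics passes a
        KS test against Uniform(0,1) at the 1% level."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(100):
            loadings = pd.DataFrame(
                rng.normal(size=(60, 10)),
                index=[f"c{i}" for i in range(60)],
                columns=[f"topic_{k:03d}" for k in range(10)],
            )
            outcome = pd.Series(rng.normal(size=60), index=loadings.index)
            ps.extend(dla_regression(loadings, outcome)["p_raw"].tolist())
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_signal_ranks_first(self, rng):
        n = 200
        outcome = rng.uniform(0.1, 0.3, size=n)
        effect = outcome + rng.normal(0, 0.02, size=n)
        noise = rng.normal(size=n)
        loadings = pd.DataFrame(
            {"topic_000": noise, "topic_001": effect},
            index=[f"c{i}" for i in range(n)],
        )
        out = dla_regression(loadings, pd.Series(outcome, index=loadings.index))
        assert out.index[0] == "topic_001"
        assert out.loc["topic_001", "significant"]

    def test_constant_column_flagged_excluded(self):
        loadings = pd.DataFrame(
            {"topic_000": [0.5] * 10, "topic_001": np.linspace(0, 1, 10)},
            index=[f"c{i}" for i in range(10)],
        )
        outcome = pd.Series(np.linspace(0.1, 0.2, 10), index=loadings.index)
        out = dla_regression(loadings, outcome)
        assert "topic_000" not in out.index
        assert out.attrs["skipped_constant"] == ["topic_000"]


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3, 1, 2, 3], [True] * 3 + [False] * 3) == pytest.approx(0.0)

    def test_hand_example(self):
        # means 4 and 2; pooled sd 1 -> d = 2
        d = cohens_d([3, 4, 5, 1, 2, 3], [True] * 3 + [False] * 3)
        assert d == pytest.approx(2.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        vals = rng.normal(size=30)
        member = rng.random(30) < 0.4
        if member.sum() < 2 or (~member).sum() < 2:
            member[:2], member[2:] = True, False
        assert cohens_d(vals * 3.7, member) == pytest.approx(cohens_d(vals, member))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1, 2, 3], [True, False, False])


class TestLogisticPvalue:
    def test_null_p_approximately_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(100):
            x = rng.normal(size=120)
            y = rng.random(120) < 0.5
            if y.all() or not y.any():
                continue
            res = logistic_pvalue(x, y)
            if not res.separated:
                ps.append(res.p)
        # Wald p under the null is approximately uniform
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_pvalue([1.0, 2.0, 3.0], [True, True, True])

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError):
            logistic_pvalue([1.0, 1.0, 1.0, 1.0], [True, False, True, False])

    def test_separation_flagged(self):
        x = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        y = np.array([False, False, False, True, True, True])
        res = logistic_pvalue(x, y)
        assert res.separated
        assert np.isnan(res.p)

    def test_signal_detected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(1.5, 1, 200)])
        y = np.array([False] * 200 + [True] * 200)
        res = logistic_pvalue(x, y)
        assert not res.separated
        assert res.p < 1e-6
        assert res.coef > 0


class TestBenjaminiHochberg:
    def test_stepup_hand_example(self):
        reject, adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()  # 0.04 <= 4 * 0.05 / 4

    def test_all_ones(self):
        reject, adjusted = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not reject.any()
        assert (adjusted == 1.0).all()

    def test_single_p_identity(self):
        reject, adjusted = benjamini_hochberg([0.04], q=0.05)
        assert reject[0]
        assert adjusted[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_superset_of_bonferroni(self, rng):
        for _ in range(50):
            p = rng.random(12)
            reject_bh, _ = benjamini_hochberg(p, q=0.05)
            bonferroni = p <= 0.05 / p.size
            assert (reject_bh | ~bonferroni).all()

    def test_adjusted_monotone_in_raw(self, rng):
        p = rng.random(15)
        _, adjusted = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()

    def test_matches_reference_on_random_vectors(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 21))
            p = np.round(rng.random(m), 4)
            q = float(rng.choice([0.01, 0.05, 0.1]))
            reject, adjusted = benjamini_hochberg(p, q=q)
            ref_reject, ref_adjusted = stepup_bh_reference(p, q)
            assert list(reject) == ref_reject
            assert np.allclose(adjusted, ref_adjusted, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 30)))
            reject, adjusted = benjamini_hochberg(p, q=0.05)
            sm_reject, sm_adjusted, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            assert (reject == sm_reject).all()
            assert np.allclose(adjusted, sm_adjusted, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.permutations(range(12)))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_invariance(self, p, perm):
        p = np.asarray(p)
        idx = [i for i in perm if i < len(p)]
        if sorted(idx) != list(range(len(p))):
            return
        reject, adjusted = benjamini_hochberg(p)
        reject_p, adjusted_p = benjamini_hochberg(p[idx])
        assert (reject[idx] == reject_p).all()
        assert np.allclose(adjusted[idx], adjusted_p)


class TestCommunityContrasts:
    def test_planted_community_topic(self, rng):
        n = 120
        counties = [f"c{i}" for i in range(n)]
        labels = pd.Series(["red" if i < 40 else "blue" for i in range(n)], index=counties)
        elevated = np.where(np.arange(n) < 40, 0.6, 0.2) + rng.normal(0, 0.05, n)
        flat = rng.normal(0.4, 0.05, n)
        loadings = pd.DataFrame({"topic_000": flat, "topic_001": elevated}, index=counties)
        out = community_contrasts(loadings, labels)
        top_red = out[out["community"] == "red"].iloc[0]
        assert top_red["feature"] == "topic_001"
        assert top_red["cohens_d"] > 2
        assert top_red["significant"] or top_red["separated"]
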