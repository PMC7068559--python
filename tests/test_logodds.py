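"""Weighted log-odds with informative Dirichlet prior; top-k restriction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drunklens.evaluation import direct_log_odds
from drunklens.logodds import (
    restrict_corpus,
    select_top_tokens,
    weighted_log_odds,
)
from drunklens.tokenize import TokenizedTweet


class TestWeightedLogOdds:
    def test_identical_corpora_symmetric_prior_zero(self):
        counts = {"a": 5, "b": 3, "c": 9}
        table = weighted_log_odds(counts, dict(counts), alpha0=10.0)
        assert table["delta"].abs().max() < 1e-12
        assert table["z"].abs().max() < 1e-12

    def test_hand_evaluated_example(self):
        """V=2, uniform prior alpha0=2; token A: y_i=5/10 vs y_j=2/10."""
        counts_i = {"A": 5, "B": 5}
        counts_j = {"A": 2, "B": 8}
        prior = {"A": 1.0, "B": 1.0}
        table = weighted_log_odds(counts_i, counts_j, prior=prior)
        row = table.loc["A"]
        assert row["delta"] == pytest.approx(np.log(6 / 6) - np.log(3 / 9), abs=1e-12)
        assert row["variance"] == pytest.approx(1 / 6 + 1 / 3, abs=1e-12)
        assert row["z"] == pytest.approx(row["delta"] / np.sqrt(0.5), abs=1e-12)
        assert row["z"] == pytest.approx(1.5537, abs=1e-3)

    def test_antisymmetry_under_corpus_swap(self, rng):
        for _ in range(20):
            v = rng.integers(2, 8)
            vocab = [f"w{i}" for i in range(v)]
            ci = {w: int(rng.integers(0, 30)) for w in vocab}
            cj = {w: int(rng.integers(0, 30)) for w in vocab}
            fwd = weighted_log_odds(ci, cj, alpha0=20.0)
            rev = weighted_log_odds(cj, ci, alpha0=20.0)
            fwd, rev = fwd.sort_index(), rev.sort_index()
            assert np.allclose(fwd["delta"], -rev["delta"], atol=1e-12)
            assert np.allclose(fwd["z"], -rev["z"], atol=1e-12)

    def test_matches_direct_evaluation(self, rng):
        """Vectorized table equals the scalar formula to 1e-10."""
        for _ in range(50):
            v = int(rng.integers(2, 10))
            vocab = [f"w{i}" for i in range(v)]
            ci = {w: int(rng.integers(0, 50)) for w in vocab}
            cj = {w: int(rng.integers(0, 50)) for w in vocab}
            a0 = float(rng.uniform(1.0, 100.0))
            table = weighted_log_odds(ci, cj, alpha0=a0)
            n_i, n_j = sum(ci.values()), sum(cj.values())
            if n_i == 0 or n_j == 0:
                continue
            pooled_total = n_i + n_j
            for w in vocab:
                a_w = a0 * (ci[w] + cj[w]) / pooled_total
                if a_w == 0:
                    continue
                delta, var, z = direct_log_odds(ci[w], n_i, cj[w], n_j, a_w, a0)
                assert table.loc[w, "delta"] == pytest.approx(delta, abs=1e-10)
                assert table.loc[w, "variance"] == pytest.approx(var, abs=1e-10)
                assert table.loc[w, "z"] == pytest.approx(z, abs=1e-10)

    def test_shrinkage_to_zero_as_prior_dominates(self):
        """With a fixed-proportion prior and alpha0 -> inf, delta -> 0."""
        ci = {"a": 30, "b": 5}
        cj = {"a": 5, "b": 30}
        deltas = [
            weighted_log_odds(ci, cj, alpha0=a0)["delta"].abs().max()
            for a0 in (10.0, 1e3, 1e6)
        ]
        assert deltas[0] > deltas[1] > deltas[2]
        assert deltas[2] < 1e-3

    def test_prior_must_cover_vocabulary(self):
        with pytest.raises(ValueError, match="union vocabulary"):
            weighted_log_odds({"a": 1}, {"b": 1}, prior={"a": 1.0})

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            weighted_log_odds({"a": 1}, {"a": 1}, prior={"a": 0.0})


class TestSelectTopTokens:
    def _table(self, zscores):
        import pandas as pd

        return pd.DataFrame(
            {"z": list(zscores.values())},
            index=pd.Index(list(zscores.keys()), name="token"),
        )

    def test_signed_not_absolute_ranking(self):
        top = select_top_tokens(self._table({"a": 2.0, "b": -3.0, "c": 1.0}),
                                k=1, z_floor=None)
        assert top == ["a"]

    def test_tie_broken_lexicographically(self):
        top = select_top_tokens(self._table({"c": 1.0, "a": 1.0, "b": 1.0}),
                                k=3, z_floor=None)
        assert top == ["a", "b", "c"]

    def test_full_vocabulary_permutation(self):
        table = self._table({"a": 0.5, "b": 2.5, "c": -1.0})
        top = select_top_tokens(table, k=3, z_floor=None)
        assert sorted(top) == ["a", "b", "c"]

    def test_z_floor_excludes_insignificant(self):
        top = select_top_tokens(self._table({"a": 2.5, "b": 0.3, "c": -2.2}),
                                k=10, z_floor=1.96)
        assert top == ["a", "c"]

    def test_oversized_k_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            select_top_tokens(self._table({"a": 1.0}), k=5, z_floor=None)


class TestRestrictCorpus:
    def test_identity_with_full_vocab(self):
        corpus = [TokenizedTweet("t1", ["a", "b"]), TokenizedTweet("t2", ["b"])]
        kept, dropped = restrict_corpus(corpus, ["a", "b"])
        assert dropped == 0
        assert [t.tokens for t in kept] == [["a", "b"], ["b"]]

    def test_tokens_dropped_in_place(self):
        kept, _ = restrict_corpus([TokenizedTweet("t1", ["a", "x", "b"])], ["a", "b"])
        assert kept[0].tokens == ["a", "b"]

    def test_emptied_tweets_counted(self):
        kept, dropped = restrict_corpus(
            [TokenizedTweet("t1", ["x"]), TokenizedTweet("t2", ["a"])], ["a"]
        )
        assert dropped == 1
        assert [t.id for t in kept] == ["t2"]

    def test_empty_vocab_rejected(self):
        with pytest.raises(ValueError):
            restrict_corpus([], [])


@given(
    counts=st.lists(
        st.tuples(st.integers(0, 40), st.integers(0, 40)), min_size=2, max_size=6
    ),
    scale=st.integers(2, 5),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_doubling_counts_and_prior_does_not_shrink_z(counts, scale):
    """Scaling all counts and the prior by c >= 2 keeps |z| non-decreasing
    for tokens whose delta keeps its sign (more data, same effect)."""
    vocab = [f"w{i}" for i in range(len(counts))]
    ci = {w: c[0] for w, c in zip(vocab, counts)}
    cj = {w: c[1] for w, c in zip(vocab, counts)}
    if sum(ci.values()) == 0 or sum(cj.values()) == 0:
        return
    if sum(ci[w] + cj[w] > 0 for w in vocab) < 2:
        return  # single-token vocabulary: odds degenerate by design
    vocab = [w for w in vocab if ci[w] + cj[w] > 0]
    a0 = 10.0
    small = weighted_log_odds(ci, cj, alpha0=a0)
    big = weighted_log_odds(
        {w: c * scale for w, c in ci.items()},
        {w: c * scale for w, c in cj.items()},
        alpha0=a0 * scale,
    )
    for w in vocab:
        d_small, d_big = small.loc[w, "delta"], big.loc[w, "delta"]
        if d_small * d_big > 0:  # fixed-sign delta
            assert abs(big.loc[w, "z"]) >= abs(small.loc[w, "z"]) - 1e-9
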