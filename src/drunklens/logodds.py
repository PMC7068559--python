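"""Weighted log-odds with an informative Dirichlet prior.

Compares token usage across two corpora (drunk vs non-drunk tweets) with the
z-scored log-odds-ratio difference: for token w with counts y_iw, y_jw in
corpora of sizes n_i, n_j and prior counts alpha_w (total alpha_0),

    delta_w = log[(y_iw + a_w) / (n_i + a_0 - y_iw - a_w)]
            - log[(y_jw + a_w) / (n_j + a_0 - y_jw - a_w)]
    var(delta_w) ~= 1/(y_iw + a_w) + 1/(y_jw + a_w)
    z_w = delta_w / sqrt(var)

The prior shrinks rare-token odds toward background frequencies, so the
ranking is not dominated by low-count noise.  By default the prior is the
pooled relative frequency of both corpora scaled to a total prior mass
alpha_0 (500 unless configured otherwise).
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tokenize import TokenizedTweet

__all__ = ["weighted_log_odds", "select_top_tokens", "restrict_corpus"]

DEFAULT_ALPHA0 = 500.0


def _prior_from_background(
    vocab: list[str],
    counts_i: Mapping[str, int],
    counts_j: Mapping[str, int],
    alpha0: float,
) -> pd.Series:
    pooled = np.array(
        [counts_i.get(w, 0) + counts_j.get(w, 0) for w in vocab], dtype=float
    )
    total = pooled.sum()
    if total == 0:
        raise ValueError("both corpora are empty")
    return pd.Series(alpha0 * pooled / total, index=vocab)


def weighted_log_odds(
    counts_drunk: Mapping[str, int],
    counts_background: Mapping[str, int],
    prior: Mapping[str, float] | None = None,
    alpha0: float = DEFAULT_ALPHA0,
) -> pd.DataFrame:
    """Per-token weighted log-odds of corpus i (drunk) vs corpus j (background).

    ``prior`` maps token -> prior count alpha_w over the union vocabulary;
    when omitted it defaults to ``alpha0`` times the pooled relative
    frequency of both corpora.  Returns a DataFrame indexed by token with
    columns ``y_i, y_j, alpha_w, delta, variance, z``, sorted by z
    descending (ties broken lexicographically by token).
    """
    # tokens absent from both corpora carry no information and no defined odds
    vocab = sorted(
        w
        for w in set(counts_drunk) | set(counts_background)
        if counts_drunk.get(w, 0) + counts_background.get(w, 0) > 0
    )
    if not vocab:
        raise ValueError("empty vocabulary")
    if prior is None:
        alpha = _prior_from_background(vocab, counts_drunk, counts_background, alpha0)
    else:
        missing = [w for w in vocab if w not in prior]
        if missing:
            raise ValueError(
                f"prior must cover the union vocabulary; missing e.g. {missing[:3]}"
            )
        alpha = pd.Series({w: float(prior[w]) for w in vocab})
        alpha0 = float(alpha.sum())
    if alpha0 <= 0 or (alpha.to_numpy() < 0).any():
        raise ValueError("prior counts must be nonnegative with positive total")

    y_i = np.array([counts_drunk.get(w, 0) for w in vocab], dtype=float)
    y_j = np.array([counts_background.get(w, 0) for w in vocab], dtype=float)
    n_i, n_j = y_i.sum(), y_j.sum()
    a = alpha.to_numpy()

    num_i = y_i + a
    den_i = n_i + alpha0 - y_i - a
    num_j = y_j + a
    den_j = n_j + alpha0 - y_j - a
    if (num_i <= 0).any() or (den_i <= 0).any() or (num_j <= 0).any() or (den_j <= 0).any():
        raise ValueError("log-odds denominator <= 0; increase the prior mass")
    delta = np.log(num_i / den_i) - np.log(num_j / den_j)
    variance = 1.0 / num_i + 1.0 / num_j
    z = delta / np.sqrt(variance)

    out = pd.DataFrame(
        {"y_i": y_i.astype(int), "y_j": y_j.astype(int), "alpha_w": a,
         "delta": delta, "variance": variance, "z": z},
        index=pd.Index(vocab, name="token"),
    )
    return out.sort_values(["z", "token"], ascending=[False, True], kind="mergesort")


def select_top_tokens(
    results: pd.DataFrame,
    k: int = 5000,
    z_floor: float | None = 1.96,
) -> list[str]:
    """Top-k tokens most associated with the drunk corpus.

    Ranks by signed z descending (drunk-associated tokens first, ties broken
    lexicographically).  With ``z_floor`` set (default 1.96, i.e. two-sided
    5% significance), tokens below the floor are excluded before the top-k
    cut; pass ``z_floor=None`` to rank the whole vocabulary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = results.sort_values(["z", "token"], ascending=[False, True], kind="mergesort")
    if z_floor is not None:
        ranked = ranked[ranked["z"].abs() >= z_floor]
    tokens = list(ranked.index)
    if k > len(tokens):
        warnings.warn(
            f"k={k} exceeds the {len(tokens)} available tokens; returning all",
            stacklevel=2,
        )
    return tokens[:k]


def restrict_corpus(
    corpus: Iterable[TokenizedTweet], vocab: Sequence[str]
) -> tuple[list[TokenizedTweet], int]:
    """Drop tokens outside ``vocab`` in place; drop and count emptied tweets.

    Returns the filtered corpus and the number of tweets removed because no
    token survived.
    """
    vocab_set = set(vocab)
    if not vocab_set:
        raise ValueError("restriction vocabulary must be non-empty")
    kept: list[TokenizedTweet] = []
    n_dropped = 0
    for tweet in corpus:
        toks = [t for t in tweet.tokens if t in vocab_set]
        if toks:
            kept.append(TokenizedTweet(id=tweet.id, tokens=toks))
        else:
            n_dropped += 1
    return kept, n_dropped


def corpus_counts(corpus: Iterable[TokenizedTweet]) -> Counter:
    """Token counts pooled over a corpus."""
    counts: Counter = Counter()
    for tweet in corpus:
        counts.update(tweet.tokens)
    return counts
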