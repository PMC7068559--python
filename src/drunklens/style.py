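"""Pronoun-based style scores and weighted sentiment scoring.

Drinking posts can reference one's own behaviour ("I am drunk ...") or
someone else's ("he was drunk ...").  The self score is the relative
frequency of the token "i"; the other score sums the relative frequencies of
"he", "she" and "they".  A broader personal-pronoun frequency uses a
configurable pronoun word list, and positive sentiment is a weighted-lexicon
score (sum of word weight x count, per token).  Scores are standardized
(z-scored) across groups for comparison between community types.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from .tokenize import TokenizedTweet

__all__ = [
    "pronoun_scores",
    "dictionary_frequency",
    "lexicon_score",
    "standardize",
    "style_table",
    "load_lexicon",
    "load_word_list",
]

SELF_TOKEN = "i"
OTHER_TOKENS = ("he", "she", "they")


def _pooled_counts(corpus: Iterable[TokenizedTweet]) -> tuple[Counter, int]:
    counts: Counter = Counter()
    for tweet in corpus:
        counts.update(tweet.tokens)
    return counts, sum(counts.values())


def pronoun_scores(
    group_corpora: Mapping[str, Iterable[TokenizedTweet]]
) -> pd.DataFrame:
    """Raw self/other pronoun frequencies per group, from pooled counts.

    self = count("i") / total tokens; other = (count("he") + count("she") +
    count("they")) / total tokens.  Tokens are assumed already lowercased by
    the tokenizer, so "I" has been folded into "i".
    """
    rows = []
    for group, corpus in group_corpora.items():
        counts, total = _pooled_counts(corpus)
        if total == 0:
            raise ValueError(f"group {group!r} has an empty corpus")
        rows.append(
            {
                "group": group,
                "self_freq": counts[SELF_TOKEN] / total,
                "other_freq": sum(counts[t] for t in OTHER_TOKENS) / total,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def dictionary_frequency(
    corpus: Iterable[TokenizedTweet], word_list: set[str]
) -> float:
    """Relative frequency of any word in ``word_list`` (e.g. personal pronouns)."""
    if not word_list:
        raise ValueError("word list must be non-empty")
    counts, total = _pooled_counts(corpus)
    if total == 0:
        raise ValueError("empty corpus")
    return sum(counts[w] for w in word_list) / total


def lexicon_score(
    corpus: Iterable[TokenizedTweet], lexicon: Mapping[str, float]
) -> float:
    """Weighted lexicon score per token: sum_w weight(w) count(w) / total.

    Out-of-lexicon tokens contribute zero; the score is linear in the
    lexicon weights.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    counts, total = _pooled_counts(corpus)
    if total == 0:
        raise ValueError("empty corpus")
    return sum(w * counts[word] for word, w in lexicon.items()) / total


def standardize(values: Mapping[str, float] | pd.Series, ddof: int = 1) -> pd.Series:
    """Z-score values across groups: (v - mean) / sd, unbiased sd by default.

    A zero standard deviation is an error (the z-score is undefined), not a
    silent column of zeros.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 groups to standardize")
    sd = s.std(ddof=ddof)
    if sd == 0 or pd.isna(sd):
        raise ValueError("zero standard deviation: z-scores undefined")
    return (s - s.mean()) / sd


def style_table(
    group_corpora: Mapping[str, Iterable[TokenizedTweet]],
    pronoun_list: set[str] | None = None,
    positive_lexicon: Mapping[str, float] | None = None,
    by_county_mean: Mapping[str, Mapping[str, Iterable[TokenizedTweet]]] | None = None,
) -> pd.DataFrame:
    """Full style table per group: raw and standardized scores.

    Default aggregation pools token counts across each group's tweets.  Pass
    ``by_county_mean`` (group -> county -> corpus) to instead average
    county-level frequencies within each group, the alternative aggregation
    when groups are sets of counties.

    Columns: self_freq, other_freq, optional personal_pronoun_freq and
    positive_sentiment, plus a ``*_z`` standardized variant of each.
    """
    corpora = {g: list(c) for g, c in group_corpora.items()}
    if by_county_mean is None:
        table = pronoun_scores(corpora)
        if pronoun_list is not None:
            table["personal_pronoun_freq"] = [
                dictionary_frequency(corpora[g], pronoun_list) for g in table.index
            ]
        if positive_lexicon is not None:
            table["positive_sentiment"] = [
                lexicon_score(corpora[g], positive_lexicon) for g in table.index
            ]
    else:
        rows = []
        for group, by_county in by_county_mean.items():
            sub = {c: list(t) for c, t in by_county.items()}
            per_county = pronoun_scores(sub)
            row = {
                "group": group,
                "self_freq": per_county["self_freq"].mean(),
                "other_freq": per_county["other_freq"].mean(),
            }
            if pronoun_list is not None:
                row["personal_pronoun_freq"] = sum(
                    dictionary_frequency(sub[c], pronoun_list) for c in sub
                ) / len(sub)
            if positive_lexicon is not None:
                row["positive_sentiment"] = sum(
                    lexicon_score(sub[c], positive_lexicon) for c in sub
                ) / len(sub)
            rows.append(row)
        table = pd.DataFrame(rows).set_index("group")
    # z-score each score across groups; a zero-variance column has no
    # defined z-score and is left unstandardized
    for col in list(table.columns):
        if len(table) >= 2 and table[col].std(ddof=1) > 0:
            table[f"{col}_z"] = standardize(table[col])
    return table


def load_lexicon(path) -> dict[str, float]:
    """Two-column delimited lexicon file: word <tab-or-whitespace> weight."""
    lex: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, weight = line.split()[:2]
            lex[word.casefold()] = float(weight)
    if not lex:
        raise ValueError(f"empty lexicon file: {path}")
    return lex


def load_word_list(path) -> set[str]:
    """One lowercase word per line; blanks and ``#`` comments ignored."""
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                words.add(line.casefold())
    if not words:
        raise ValueError(f"empty word list file: {path}")
    return words
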