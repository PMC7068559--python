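"""Social-media-aware tokenization, collocation detection, and county aggregation.

Tweets are split into lowercased tokens with emoticons, hashtags, @-mentions
and URLs kept intact as single tokens; runs of punctuation are split from
words and broken into their pieces (``":)!"`` becomes ``":)"`` and ``"!"``).
Adjacent word pairs that co-occur more often than chance (measured by
pointwise mutual information) can be merged into phrase tokens such as
``"happy birthday"``, and per-county token statistics are accumulated into
:class:`CountyAggregate` records that carry the relative frequencies
P(token | county) used by the topic-loading stage.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TokenizedTweet",
    "CountyAggregate",
    "tokenize",
    "detect_phrases",
    "merge_phrases",
    "aggregate_counties",
]

# Emoticons are matched before generic punctuation so ":)" survives as one
# token.  The list is a compact western-style set, not exhaustive.
_EMOTICON = r"""
    [<>]?
    [:;=8xX]                     # eyes
    [-o*']?                      # optional nose
    [)\](\[dDpP/:}{@|\\oO*3]     # mouth
    |
    [)\](\[dDpP/:}{@|\\]         # reversed mouth
    [-o*']?
    [:;=8xX]
    [<>]?
    |
    <3                           # heart
"""

_TOKEN_RE = re.compile(
    r"""
    (?:https?://\S+|www\.\S+)          # URLs
    |(?:@\w+)                          # @-mentions
    |(?:\#\w+)                         # hashtags
    |(?:%(emoticon)s)                  # emoticons
    |(?:\w+(?:['’]\w+)*)               # words incl. contractions
    |(?:\S)                            # any leftover symbol, one at a time
    """
    % {"emoticon": _EMOTICON},
    re.VERBOSE | re.UNICODE,
)


def tokenize(text: str) -> list[str]:
    """Split ``text`` into lowercased social-media tokens.

    Emoticons, hashtags, @-mentions and URLs are preserved as single tokens;
    punctuation is split from words and emitted one symbol at a time, except
    where it forms an emoticon.  Deterministic; empty input yields ``[]``.

    >>> tokenize(":)!")
    [':)', '!']
    >>> tokenize("SO DRUNK #lastnight :)")
    ['so', 'drunk', '#lastnight', ':)']
    """
    if not text:
        return []
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


@dataclass
class TokenizedTweet:
    """A tweet after tokenization: ordered unigrams plus merged phrases."""

    id: str
    tokens: list[str]


def detect_phrases(
    corpus: Iterable[Sequence[str]],
    min_count: int = 10,
    pmi_threshold: float = 3.0,
) -> set[str]:
    """Find adjacent bigrams that co-occur more often than chance.

    A bigram (a, b) becomes a phrase when its corpus count is at least
    ``min_count`` and its pointwise mutual information

        PMI(a, b) = log[ P(a, b) / (P(a) P(b)) ]

    is at least ``pmi_threshold``, with P(a, b) estimated from adjacent-pair
    counts and P(a), P(b) from unigram counts.  Returns phrases as
    space-joined strings, e.g. ``"happy birthday"``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    unigrams: Counter[str] = Counter()
    bigrams: Counter[tuple[str, str]] = Counter()
    for tokens in corpus:
        unigrams.update(tokens)
        bigrams.update(zip(tokens, tokens[1:]))
    n_uni = sum(unigrams.values())
    n_big = sum(bigrams.values())
    phrases: set[str] = set()
    if n_big == 0:
        return phrases
    for (a, b), c_ab in bigrams.items():
        if c_ab < min_count:
            continue
        p_ab = c_ab / n_big
        p_a = unigrams[a] / n_uni
        p_b = unigrams[b] / n_uni
        pmi = math.log(p_ab / (p_a * p_b))
        if pmi >= pmi_threshold:
            phrases.add(f"{a} {b}")
    return phrases


def merge_phrases(tokens: Sequence[str], phrases: set[str]) -> list[str]:
    """Merge detected bigram phrases left-to-right in a single pass.

    Phrase merging never increases the token count and never crosses tweet
    boundaries (it operates on one token list at a time).
    """
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and f"{tokens[i]} {tokens[i + 1]}" in phrases:
            out.append(f"{tokens[i]} {tokens[i + 1]}")
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


@dataclass
class CountyAggregate:
    """Per-county token statistics.

    ``token_freq`` holds the relative frequency P(token | county), a
    probability distribution over the county's observed vocabulary;
    ``presence_count`` counts the tweets in which a token appears at least
    once.  ``drunk_tweets`` / ``total_tweets`` gives the county's drunk-tweet
    frequency, the quantity correlated with the excessive-drinking outcome.
    """

    county_id: str
    token_count: Counter = field(default_factory=Counter)
    presence_count: Counter = field(default_factory=Counter)
    total_tokens: int = 0
    drunk_tweets: int = 0
    total_tweets: int = 0

    @property
    def token_freq(self) -> dict[str, float]:
        if self.total_tokens == 0:
            return {}
        return {w: c / self.total_tokens for w, c in self.token_count.items()}

    @property
    def drunk_frequency(self) -> float:
        if self.total_tweets == 0:
            raise ValueError(f"county {self.county_id} has zero total tweets")
        return self.drunk_tweets / self.total_tweets


def aggregate_counties(
    corpus: Iterable[TokenizedTweet],
    county_of_tweet: Mapping[str, str],
    all_tweet_counts: Mapping[str, int],
) -> dict[str, CountyAggregate]:
    """Accumulate per-county token statistics from a drunk-tweet corpus.

    ``corpus`` is the stream of (filtered, tokenized) drunk tweets;
    ``county_of_tweet`` maps tweet id -> county id and must cover every
    tweet; ``all_tweet_counts`` maps county id -> total tweet count in that
    county (drunk and non-drunk), the denominator of the drunk-tweet
    frequency.  Order of the input stream does not affect the result.
    """
    aggs: dict[str, CountyAggregate] = {}
    for tweet in corpus:
        try:
            county = county_of_tweet[tweet.id]
        except KeyError:
            raise KeyError(f"tweet {tweet.id!r} has no resolved county") from None
        agg = aggs.get(county)
        if agg is None:
            agg = aggs[county] = CountyAggregate(county_id=county)
        agg.token_count.update(tweet.tokens)
        agg.presence_count.update(set(tweet.tokens))
        agg.total_tokens += len(tweet.tokens)
        agg.drunk_tweets += 1
    for county, agg in aggs.items():
        total = all_tweet_counts.get(county, 0)
        if total <= 0:
            raise ValueError(f"county {county} has zero total tweets")
        if agg.drunk_tweets > total:
            raise ValueError(
                f"county {county}: drunk tweets ({agg.drunk_tweets}) exceed "
                f"total tweets ({total})"
            )
        agg.total_tweets = total
    return aggs
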