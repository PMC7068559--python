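"""Keyword construction, drunk-tweet filtering, language filter, county
resolution and the county word threshold.

The inclusion pipeline mirrors a geolocated-corpus study design: start from a
drinking-keyword list, keep tweets containing the seed keyword "drunk" as a
whole token, drop tweets containing the exclusion phrase "drunk in love"
(a popular song title, not a drinking report), drop non-English tweets via an
injected language predicate, resolve each tweet to a county, and keep only
counties with enough drunk-tweet text to support language analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .tokenize import tokenize

__all__ = [
    "TweetRecord",
    "FilterReport",
    "build_keyword_set",
    "load_keywords",
    "keyword_cooccurrence_screen",
    "filter_drunk_tweets",
    "language_filter",
    "resolve_county",
    "threshold_counties",
    "communities_meeting_threshold",
    "GridGazetteer",
]

DEFAULT_EXCLUSION_PHRASES = ("drunk in love",)


@dataclass
class TweetRecord:
    """One social-media post with optional geolocation fields."""

    id: str
    text: str
    timestamp: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    profile_location: str | None = None
    county_id: str | None = None
    language_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"tweet {self.id!r}: text must be non-empty")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"tweet {self.id!r}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"tweet {self.id!r}: longitude out of range")


@dataclass
class FilterReport:
    """Counts at each stage of the inclusion pipeline (non-increasing)."""

    n_input: int = 0
    n_keyword_matched: int = 0
    n_after_exclusion: int = 0
    n_language_retained: int = 0
    n_geolocated: int = 0
    n_counties: int = 0
    n_counties_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input", self.n_input),
            ("keyword_matched", self.n_keyword_matched),
            ("after_exclusion", self.n_after_exclusion),
            ("language_retained", self.n_language_retained),
            ("geolocated", self.n_geolocated),
            ("counties", self.n_counties),
            ("counties_retained", self.n_counties_retained),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


def build_keyword_set(base_list: Sequence[str], seed_keyword: str) -> list[str]:
    """Union of a base keyword list and the seed keyword, case-folded and
    deduplicated with order preserved (base list order first)."""
    if not base_list:
        raise ValueError("base keyword list must be non-empty")
    out: list[str] = []
    seen: set[str] = set()
    for kw in [*base_list, seed_keyword]:
        folded = kw.casefold().strip()
        if folded and folded not in seen:
            seen.add(folded)
            out.append(folded)
    return out


def load_keywords(path) -> list[str]:
    """Read one keyword per line, ignoring blanks and ``#`` comments."""
    words = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                words.append(line)
    return words


def _contains_token(text: str, keyword: str) -> bool:
    """Whole-token membership under the social-media tokenizer.

    A multi-word keyword matches when its token sequence appears contiguously.
    """
    tokens = tokenize(text)
    kw_tokens = tokenize(keyword)
    if not kw_tokens:
        return False
    if len(kw_tokens) == 1:
        return kw_tokens[0] in tokens
    n = len(kw_tokens)
    return any(tokens[i : i + n] == kw_tokens for i in range(len(tokens) - n + 1))


def keyword_cooccurrence_screen(
    tweets: Sequence[TweetRecord], keywords: Sequence[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Pearson correlations of per-keyword binary indicators.

    Builds one 0/1 indicator per keyword per tweet (whole-token match) and
    returns the keyword x keyword correlation matrix plus per-keyword match
    counts.  Pairs where either indicator is constant across tweets are
    undefined and reported as NaN rather than 0.
    """
    if len(tweets) < 2:
        raise ValueError("need at least 2 tweets for a co-occurrence screen")
    if len(keywords) < 2:
        raise ValueError("need at least 2 keywords for a co-occurrence screen")
    ind = np.zeros((len(tweets), len(keywords)), dtype=float)
    for i, tw in enumerate(tweets):
        toks = set(tokenize(tw.text))
        for j, kw in enumerate(keywords):
            kw_toks = tokenize(kw)
            if len(kw_toks) == 1:
                ind[i, j] = 1.0 if kw_toks[0] in toks else 0.0
            else:
                ind[i, j] = 1.0 if _contains_token(tw.text, kw) else 0.0
    counts = pd.Series(ind.sum(axis=0).astype(int), index=list(keywords), name="count")
    sd = ind.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ind, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    constant = sd == 0
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    return pd.DataFrame(corr, index=list(keywords), columns=list(keywords)), counts


def filter_drunk_tweets(
    tweets: Iterable[TweetRecord],
    keyword: str = "drunk",
    exclusion_phrases: Sequence[str] = DEFAULT_EXCLUSION_PHRASES,
) -> Iterator[TweetRecord]:
    """Retain tweets containing ``keyword`` as a whole token, then drop any
    whose case-folded text contains an exclusion phrase as a substring.

    Inclusion is token-based ("drunkard" does not match "drunk"); exclusion is
    substring-based, matching how a quoted phrase is screened out.
    """
    for phrase in exclusion_phrases:
        if phrase != phrase.casefold():
            raise ValueError(f"exclusion phrase must be lowercase: {phrase!r}")
    kw = keyword.casefold()
    for tweet in tweets:
        if kw not in tokenize(tweet.text):
            continue
        folded = tweet.text.casefold()
        if any(phrase in folded for phrase in exclusion_phrases):
            continue
        yield tweet


def language_filter(
    tweets: Iterable[TweetRecord], is_english: Callable[[str], bool]
) -> Iterator[TweetRecord]:
    """Retain tweets for which the injected language predicate is true.

    The predicate is a contract (a langid-style classifier in production;
    synthetic runs test the ``language_tag`` field).  Predicate failures are
    re-raised with the offending tweet id attached.
    """
    for tweet in tweets:
        try:
            keep = bool(is_english(tweet.text if tweet.language_tag is None else tweet.language_tag))
        except Exception as exc:  # add context, never swallow
            raise RuntimeError(f"language predicate failed on tweet {tweet.id!r}") from exc
        if keep:
            yield tweet


def tag_is_english(tag_or_text: str) -> bool:
    """Default predicate for synthetic corpora: the language tag is ``en``."""
    return tag_or_text == "en"


class Gazetteer(Protocol):
    """Point/name -> county mapping contract."""

    def lookup_point(self, latitude: float, longitude: float) -> str | None: ...

    def lookup_name(self, name: str) -> str | None: ...


@dataclass
class GridGazetteer:
    """Toy gazetteer: a rectangular grid of cells, each one a 'county'.

    Covers latitudes [lat0, lat0 + n_rows*cell) and longitudes
    [lon0, lon0 + n_cols*cell); county ids are ``r{row}c{col}``.  Stands in
    for real county shapefiles, which are out of scope.
    """

    lat0: float = 30.0
    lon0: float = -100.0
    cell: float = 1.0
    n_rows: int = 2
    n_cols: int = 1
    names: dict[str, str] = field(default_factory=dict)

    def lookup_point(self, latitude: float, longitude: float) -> str | None:
        r = int((latitude - self.lat0) // self.cell)
        c = int((longitude - self.lon0) // self.cell)
        if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
            return f"r{r}c{c}"
        return None

    def lookup_name(self, name: str) -> str | None:
        return self.names.get(name.casefold().strip())


def resolve_county(
    tweet: TweetRecord,
    gazetteer: Gazetteer,
    precedence: Sequence[str] = ("county_id", "coordinates", "profile"),
) -> str | None:
    """Resolve a tweet to a county id, or None if unresolvable.

    Default precedence: a pre-resolved ``county_id`` wins, then coordinates,
    then the free-text profile location.
    """
    for source in precedence:
        if source == "county_id" and tweet.county_id is not None:
            return tweet.county_id
        if source == "coordinates":
            if (tweet.latitude is None) != (tweet.longitude is None):
                raise ValueError(f"tweet {tweet.id!r}: incomplete coordinates")
            if tweet.latitude is not None and tweet.longitude is not None:
                county = gazetteer.lookup_point(tweet.latitude, tweet.longitude)
                if county is not None:
                    return county
        if source == "profile" and tweet.profile_location:
            county = gazetteer.lookup_name(tweet.profile_location)
            if county is not None:
                return county
    return None


def threshold_counties(
    word_counts: Mapping[str, int], min_words: int = 1000
) -> set[str]:
    """Counties with at least ``min_words`` drunk-tweet words (inclusive)."""
    for county, count in word_counts.items():
        if count < 0:
            raise ValueError(f"county {county}: negative word count")
    return {county for county, count in word_counts.items() if count >= min_words}


def communities_meeting_threshold(
    community_of_county: Mapping[str, str],
    retained_counties: set[str],
    min_fraction: float = 0.25,
) -> set[str]:
    """Community types in which at least ``min_fraction`` of member counties
    passed the county word threshold.

    Sparse community types (too few counties with enough drunk-tweet text)
    drop out of the community-level analysis automatically.
    """
    members: dict[str, list[str]] = {}
    for county, community in community_of_county.items():
        members.setdefault(community, []).append(county)
    kept = set()
    for community, counties in members.items():
        frac = sum(c in retained_counties for c in counties) / len(counties)
        if frac >= min_fraction:
            kept.add(community)
    return kept
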