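"""Synthetic tweet corpora over synthetic counties and community types.

Real geolocated drinking-tweet corpora and the survey-derived county
prevalence files they are joined to cannot be redistributed, so this module
generates corpora with the statistical structure the analysis assumes,
together with the ground truth needed for recovery tests:

* counties partitioned into community types, with community-level mean shifts
  in the per-county propensity to post a drunk tweet;
* a county outcome ("excessive-drinking prevalence") constructed in closed
  form so that its population correlation with the drunk propensity equals a
  target rho;
* drunk tweets drawn from a latent-topic generative process over a synthetic
  vocabulary ("w0001"...), with the literal token "drunk" injected, and
  non-drunk tweets drawn from a distinct background word distribution so that
  drunk-distinctive tokens exist;
* reserved literal tokens (pronouns, positive-sentiment words, the phrase
  "drunk in love", non-English tags) injected at configurable rates so the
  real filtering and scoring code paths are exercised end to end.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import TweetRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_true_topics",
    "generate_county_profiles",
    "generate_tweets",
    "generate_corpus",
    "write_tweets",
    "read_tweets",
    "write_ground_truth",
]

POSITIVE_WORDS = ("love", "happy", "great", "fun", "best")
OTHER_PRONOUNS = ("he", "she", "they")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe a desk-scale study: 300 counties in 15 community
    types, 200 tweets per county, per-county drunk propensities spanning
    0.05-0.5 with a target propensity/outcome correlation of 0.45, and
    documents of mean length 12 drawn from 5 latent topics over a
    100-symbol vocabulary.
    """

    n_counties: int = 300
    n_communities: int = 15
    tweets_per_county: int | Mapping[str, int] = 200
    drunk_rate_range: tuple[float, float] = (0.05, 0.5)
    target_outcome_correlation: float = 0.45
    n_topics_true: int = 5
    vocab_size: int = 100
    doc_length_mean: float = 12.0
    topic_concentration: float = 0.1
    community_topic_bias: float = 2.0
    pronoun_rate_i: Sequence[float] | None = None       # per community
    pronoun_rate_other: Sequence[float] | None = None   # per community
    positive_word_rate: Sequence[float] | None = None   # per community
    exclusion_phrase_fraction: float = 0.0
    non_english_fraction: float = 0.0
    outcome_mean: float = 0.18
    outcome_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 1 or self.n_communities < 1:
            raise ValueError("county and community counts must be positive")
        if self.n_communities > self.n_counties:
            raise ValueError("n_communities must be <= n_counties")
        lo, hi = self.drunk_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("drunk_rate_range must satisfy 0 <= lo <= hi <= 1")
        rho = self.target_outcome_correlation
        if not -1.0 < rho < 1.0:
            raise ValueError("target correlation must lie strictly in (-1, 1)")
        if self.n_topics_true < 1 or self.vocab_size < self.n_topics_true:
            raise ValueError("need vocab_size >= n_topics_true >= 1")
        if self.doc_length_mean <= 0:
            raise ValueError("doc_length_mean must be positive")
        if self.topic_concentration <= 0:
            raise ValueError("topic concentration must be positive")
        if self.community_topic_bias < 0:
            raise ValueError("community_topic_bias must be nonnegative")
        if not 0.0 <= self.exclusion_phrase_fraction <= 1.0:
            raise ValueError("exclusion_phrase_fraction must be in [0, 1]")
        if not 0.0 <= self.non_english_fraction <= 1.0:
            raise ValueError("non_english_fraction must be in [0, 1]")
        if isinstance(self.tweets_per_county, int) and self.tweets_per_county < 1:
            raise ValueError("tweets_per_county must be positive")

    def county_ids(self) -> list[str]:
        return [f"c{i:04d}" for i in range(self.n_counties)]

    def vocabulary(self) -> list[str]:
        return [f"w{i:04d}" for i in range(self.vocab_size)]

    def n_tweets(self, county: str) -> int:
        if isinstance(self.tweets_per_county, int):
            return self.tweets_per_county
        return int(self.tweets_per_county[county])


@dataclass
class SyntheticGroundTruth:
    """The generator's hidden state: the oracle for recovery tests."""

    true_topic_word: np.ndarray            # [n_topics_true, vocab_size]
    background_word: np.ndarray            # [vocab_size]
    county_drunk_propensity: pd.Series     # county id -> proportion
    county_outcome: pd.Series              # county id -> prevalence
    community_of_county: pd.Series         # county id -> community label
    target_correlation: float
    pronoun_rate_i: np.ndarray             # per community
    pronoun_rate_other: np.ndarray
    positive_word_rate: np.ndarray

    def __post_init__(self) -> None:
        rows = self.true_topic_word.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("each true topic row must sum to 1")
        for series, name in [
            (self.county_drunk_propensity, "propensity"),
            (self.county_outcome, "outcome"),
        ]:
            vals = series.to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{name} values must lie in [0, 1]")


def generate_true_topics(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the true topic-word matrix: independent Dirichlet rows.

    Each of the ``n_topics_true`` rows is a Dirichlet(topic_concentration)
    draw over the synthetic vocabulary.  Small concentrations give peaked
    (low-entropy) topics; large ones give near-uniform topics.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    alpha = np.full(config.vocab_size, config.topic_concentration)
    return rng.dirichlet(alpha, size=config.n_topics_true)


def generate_county_profiles(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Draw county drunk propensities, outcomes and community labels.

    Counties are assigned to communities round-robin.  Community mean
    propensities are evenly spaced across ``drunk_rate_range`` and county
    propensities scatter around their community mean (clipped to the range),
    giving the community-level shifts the group analyses look for.

    The outcome is built in closed form so its correlation with the
    propensity equals the target rho: with s_p the propensity standard
    deviation and s_o the desired outcome scale,

        outcome = mu_o + (rho * s_o / s_p) * (p - mean(p)) + eps,
        eps ~ Normal(0, (1 - rho^2) * s_o^2),

    then clipped to [0, 1] (clipping is negligible at the default location
    mu_o = 0.18, scale s_o = 0.05).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    counties = config.county_ids()
    communities = pd.Series(
        [f"community_{i % config.n_communities:02d}" for i in range(config.n_counties)],
        index=counties,
        name="community",
    )
    lo, hi = config.drunk_rate_range
    width = hi - lo
    comm_means = lo + (np.arange(config.n_communities) + 0.5) / config.n_communities * width
    idx = np.arange(config.n_counties) % config.n_communities
    propensity = comm_means[idx] + rng.normal(0.0, 0.12 * width, size=config.n_counties)
    propensity = np.clip(propensity, lo, hi)
    prop = pd.Series(propensity, index=counties, name="drunk_propensity")

    rho = config.target_outcome_correlation
    s_p = propensity.std()
    if s_p == 0:
        # constant propensities: correlation is undefined; pure-noise outcome
        slope, noise_sd = 0.0, config.outcome_sd
    else:
        slope = rho * config.outcome_sd / s_p
        noise_sd = np.sqrt(1.0 - rho**2) * config.outcome_sd
    outcome = (
        config.outcome_mean
        + slope * (propensity - propensity.mean())
        + rng.normal(0.0, noise_sd, size=config.n_counties)
    )
    outcome = np.clip(outcome, 0.0, 1.0)
    out = pd.Series(outcome, index=counties, name="excessive_drinking")
    return prop, out, communities


def _community_rates(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-community injection rates for "i", he/she/they, and positive words."""
    m = config.n_communities
    rate_i = (
        np.asarray(config.pronoun_rate_i, dtype=float)
        if config.pronoun_rate_i is not None
        else rng.uniform(0.02, 0.10, size=m)
    )
    rate_other = (
        np.asarray(config.pronoun_rate_other, dtype=float)
        if config.pronoun_rate_other is not None
        else rng.uniform(0.005, 0.04, size=m)
    )
    rate_pos = (
        np.asarray(config.positive_word_rate, dtype=float)
        if config.positive_word_rate is not None
        else rng.uniform(0.01, 0.08, size=m)
    )
    for arr, name in [(rate_i, "pronoun_rate_i"), (rate_other, "pronoun_rate_other"), (rate_pos, "positive_word_rate")]:
        if arr.shape != (m,):
            raise ValueError(f"{name} must have one rate per community")
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"{name} rates must lie in [0, 1]")
    return rate_i, rate_other, rate_pos


def make_ground_truth(config: SyntheticConfig) -> SyntheticGroundTruth:
    """Draw all hidden state for a corpus: topics, profiles, injection rates.

    The background word distribution (non-drunk tweets) is a separate
    Dirichlet draw, so drunk and non-drunk corpora differ and the
    distinctive-term stage has signal to find.
    """
    rng = np.random.default_rng(config.seed)
    topics = generate_true_topics(config, rng)
    background = rng.dirichlet(np.full(config.vocab_size, config.topic_concentration))
    prop, outcome, communities = generate_county_profiles(
        config, np.random.default_rng(config.seed + 1)
    )
    rate_i, rate_other, rate_pos = _community_rates(
        config, np.random.default_rng(config.seed + 2)
    )
    return SyntheticGroundTruth(
        true_topic_word=topics,
        background_word=background,
        county_drunk_propensity=prop,
        county_outcome=outcome,
        community_of_county=communities,
        target_correlation=config.target_outcome_correlation,
        pronoun_rate_i=rate_i,
        pronoun_rate_other=rate_other,
        positive_word_rate=rate_pos,
    )


def _sample_documents(
    rng: np.random.Generator,
    n_docs: int,
    word_dist_rows: np.ndarray,   # [n_topics, V] topic-word cdfs not yet computed
    theta: np.ndarray | None,     # [n_docs, n_topics] doc-topic mixtures, or None
    lengths: np.ndarray,
    vocab: np.ndarray,
) -> list[list[str]]:
    """Vectorised LDA-style document sampling.

    When ``theta`` is None all tokens come from ``word_dist_rows[0]``
    (single background distribution); otherwise each token's topic is drawn
    from its document's mixture and the word from that topic's distribution.
    """
    total = int(lengths.sum())
    doc_idx = np.repeat(np.arange(n_docs), lengths)
    if theta is None:
        topic_idx = np.zeros(total, dtype=np.int64)
    else:
        u = rng.random(total)
        cdf = np.cumsum(theta, axis=1)
        topic_idx = (cdf[doc_idx] > u[:, None]).argmax(axis=1)
    word_cdf = np.cumsum(word_dist_rows, axis=1)
    u = rng.random(total)
    word_idx = np.empty(total, dtype=np.int64)
    for k in range(word_dist_rows.shape[0]):
        mask = topic_idx == k
        if mask.any():
            word_idx[mask] = np.searchsorted(word_cdf[k], u[mask], side="right")
    word_idx = np.clip(word_idx, 0, len(vocab) - 1)
    words = vocab[word_idx]
    docs: list[list[str]] = []
    starts = np.concatenate([[0], np.cumsum(lengths)])
    for d in range(n_docs):
        docs.append(list(words[starts[d] : starts[d + 1]]))
    return docs


def generate_tweets(
    config: SyntheticConfig,
    truth: SyntheticGroundTruth,
    rng: np.random.Generator | None = None,
) -> list[TweetRecord]:
    """Generate the tweet stream for every county.

    Per county: each tweet is drunk with probability equal to the county's
    drunk propensity.  Drunk tweets carry the literal token "drunk" plus a
    document drawn from the latent-topic process, with the document-topic
    prior biased toward the county's community-preferred topic
    (``community_topic_bias`` added to topic ``community mod K``).  Non-drunk
    tweets are drawn from the background word distribution.  Tokens are
    replaced in place by "i", "he"/"she"/"they" or a positive-sentiment word
    at the community's injection rates.  A configurable fraction of tweets has
    "drunk in love" appended, and a configurable fraction is tagged "es"
    (non-English).  Document lengths are Poisson(doc_length_mean), min 1.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    vocab = np.asarray(config.vocabulary())
    K = config.n_topics_true
    tweets: list[TweetRecord] = []
    counties = config.county_ids()
    comm_index = {c: i for i, c in enumerate(sorted(truth.community_of_county.unique()))}

    for ci, county in enumerate(counties):
        n = config.n_tweets(county)
        p_drunk = float(truth.county_drunk_propensity[county])
        comm = truth.community_of_county[county]
        cj = comm_index[comm]
        drunk = rng.random(n) < p_drunk
        lengths = np.maximum(rng.poisson(config.doc_length_mean, size=n), 1)

        n_drunk = int(drunk.sum())
        n_plain = n - n_drunk
        docs: list[list[str] | None] = [None] * n
        if n_drunk:
            alpha = np.ones(K)
            alpha[cj % K] += config.community_topic_bias
            theta = rng.dirichlet(alpha, size=n_drunk)
            drunk_docs = _sample_documents(
                rng, n_drunk, truth.true_topic_word, theta, lengths[drunk], vocab
            )
        if n_plain:
            plain_docs = _sample_documents(
                rng, n_plain, truth.background_word[None, :], None, lengths[~drunk], vocab
            )
        di = pi = 0
        for t in range(n):
            if drunk[t]:
                docs[t] = drunk_docs[di]
                di += 1
            else:
                docs[t] = plain_docs[pi]
                pi += 1

        rate_i = truth.pronoun_rate_i[cj]
        rate_other = truth.pronoun_rate_other[cj]
        rate_pos = truth.positive_word_rate[cj]
        total_len = int(lengths.sum())
        u = rng.random(total_len)
        other_choice = rng.integers(0, len(OTHER_PRONOUNS), size=total_len)
        pos_choice = rng.integers(0, len(POSITIVE_WORDS), size=total_len)
        exclude = rng.random(n) < config.exclusion_phrase_fraction
        non_en = rng.random(n) < config.non_english_fraction

        offset = 0
        for t in range(n):
            doc = docs[t]
            for j in range(len(doc)):
                uj = u[offset + j]
                if uj < rate_i:
                    doc[j] = "i"
                elif uj < rate_i + rate_other:
                    doc[j] = OTHER_PRONOUNS[other_choice[offset + j]]
                elif uj < rate_i + rate_other + rate_pos:
                    doc[j] = POSITIVE_WORDS[pos_choice[offset + j]]
            offset += len(doc)
            if drunk[t]:
                doc.insert(0, "drunk")
            text = " ".join(doc)
            if exclude[t]:
                text += " drunk in love"
            tweets.append(
                TweetRecord(
                    id=f"{county}-t{t:06d}",
                    text=text,
                    county_id=county,
                    language_tag="es" if non_en[t] else "en",
                )
            )
    return tweets


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[TweetRecord], SyntheticGroundTruth]:
    """Ground truth plus tweet stream for a config, deterministic in its seed."""
    truth = make_ground_truth(config)
    tweets = generate_tweets(config, truth)
    return tweets, truth


# ---------------------------------------------------------------------------
# serialization: line-delimited records and delimited ground-truth tables

def _open_text(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def write_tweets(path, tweets: Iterable[TweetRecord]) -> None:
    """One JSON object per line (gzip-transparent by file extension)."""
    with _open_text(path, "w") as fh:
        for tw in tweets:
            rec = {"id": tw.id, "text": tw.text}
            for key in ("latitude", "longitude", "profile_location", "county_id", "language_tag"):
                val = getattr(tw, key)
                if val is not None:
                    rec[key] = val
            fh.write(json.dumps(rec) + "\n")


def read_tweets(path) -> list[TweetRecord]:
    with _open_text(path, "r") as fh:
        return [TweetRecord(**json.loads(line)) for line in fh if line.strip()]


def write_ground_truth(dirpath, truth: SyntheticGroundTruth) -> None:
    """County table and topic-word matrix as delimited tables."""
    import os

    os.makedirs(dirpath, exist_ok=True)
    county = pd.DataFrame(
        {
            "drunk_propensity": truth.county_drunk_propensity,
            "excessive_drinking": truth.county_outcome,
            "community": truth.community_of_county,
        }
    )
    county.index.name = "county_id"
    county.to_csv(os.path.join(dirpath, "counties.csv"))
    pd.DataFrame(truth.true_topic_word).to_csv(
        os.path.join(dirpath, "true_topics.csv"), index_label="topic"
    )
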