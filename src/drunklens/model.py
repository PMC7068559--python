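"""The end-to-end model object: drunk-tweet language vs a county outcome.

:class:`DrunkTweetsModel` is built from a tweet stream, a county outcome
table (excessive-drinking prevalence) and a county -> community-type
labeling.  ``fit()`` runs the full analysis —

  filter -> tokenize/phrases -> distinctive terms -> topic model
         -> county topic loadings -> associations -> style scores

— and returns a :class:`DrunkTweetsResults` carrying every table: the filter
report, the distinctive-token table, the fitted topic model, the
frequency-outcome correlations at county/state/community level, the
differential-language-analysis table with FDR control, topic-community
contrasts, and the pronoun/sentiment style table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from . import logodds, style
from .ingest import (
    DEFAULT_EXCLUSION_PHRASES,
    FilterReport,
    Gazetteer,
    TweetRecord,
    communities_meeting_threshold,
    language_filter,
    resolve_county,
    tag_is_english,
    threshold_counties,
)
from .lda import LdaGibbs, LdaResults, county_topic_loadings
from .tokenize import (
    TokenizedTweet,
    aggregate_counties,
    detect_phrases,
    merge_phrases,
    tokenize,
)

__all__ = ["DrunkTweetsModel", "DrunkTweetsResults", "default_pronouns", "default_lexicon"]


def default_pronouns() -> set[str]:
    path = resources.files("drunklens.data") / "pronouns.txt"
    with resources.as_file(path) as p:
        return style.load_word_list(p)


def default_lexicon() -> dict[str, float]:
    path = resources.files("drunklens.data") / "sentiment_toy_synthetic.tsv"
    with resources.as_file(path) as p:
        return style.load_lexicon(p)


@dataclass
class DrunkTweetsResults:
    """Everything the fitted pipeline produced."""

    filter_report: FilterReport
    distinctive: pd.DataFrame                 # token-level log-odds table
    lda: LdaResults | None
    loadings: pd.DataFrame                    # county x topic
    county_table: pd.DataFrame                # drunk_frequency, outcome, community
    correlations: pd.DataFrame                # spatial unit level r/CI/p
    dla: pd.DataFrame | None                  # topic vs outcome regressions
    community_associations: pd.DataFrame | None
    style_table: pd.DataFrame | None
    retained_counties: list[str] = field(default_factory=list)
    retained_communities: list[str] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Drunk-tweet language analysis", "=" * 34]
        fr = self.filter_report
        lines.append(
            f"tweets: {fr.n_input} in -> {fr.n_after_exclusion} drunk "
            f"-> {fr.n_language_retained} English -> {fr.n_geolocated} geolocated"
        )
        lines.append(
            f"counties: {fr.n_counties} with drunk tweets, "
            f"{fr.n_counties_retained} past the word threshold; "
            f"{len(self.retained_communities)} community types retained"
        )
        lines.append("")
        lines.append("Drunk-tweet frequency vs outcome (Pearson r):")
        for unit, row in self.correlations.iterrows():
            lines.append(
                f"  {unit:<10} N={int(row['n']):>5}  r={row['r']:+.3f} "
                f"[{row['ci_low']:+.3f}, {row['ci_high']:+.3f}]  p={row['p']:.3g}"
            )
        if self.dla is not None and len(self.dla):
            top = self.dla.iloc[0]
            lines.append("")
            lines.append(
                f"DLA: {int(self.dla['significant'].sum())}/{len(self.dla)} topics "
                f"significant after FDR control; "
                f"top topic {self.dla.index[0]} (r={top['r']:+.3f}, "
                f"p_adj={top['p_adjusted']:.3g})"
            )
        return "\n".join(lines)

    def to_dir(self, dirpath) -> None:
        """Persist every table as a delimited file plus a manifest echo."""
        import json
        import os

        os.makedirs(dirpath, exist_ok=True)
        self.filter_report.to_frame().to_csv(
            os.path.join(dirpath, "filter_report.csv"), index=False
        )
        self.distinctive.to_csv(os.path.join(dirpath, "distinctive_tokens.csv"))
        self.county_table.to_csv(os.path.join(dirpath, "county_table.csv"))
        self.correlations.to_csv(os.path.join(dirpath, "correlations.csv"))
        self.loadings.to_csv(os.path.join(dirpath, "topic_loadings.csv"))
        if self.lda is not None:
            self.lda.to_frame().to_csv(os.path.join(dirpath, "topic_word.csv"))
            self.lda.summary().to_csv(os.path.join(dirpath, "topic_summary.csv"))
        if self.dla is not None:
            self.dla.to_csv(os.path.join(dirpath, "dla.csv"))
        if self.community_associations is not None:
            self.community_associations.to_csv(
                os.path.join(dirpath, "community_associations.csv"), index=False
            )
        if self.style_table is not None:
            self.style_table.to_csv(os.path.join(dirpath, "style.csv"))
        with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
            json.dump(self.config_echo, fh, indent=2, default=str)


class DrunkTweetsModel:
    """Fit the drunk-tweet language pipeline to a corpus and county tables.

    Parameters mirror the analysis stages.  ``min_county_words=1000``,
    ``top_k=5000``, ``n_topics=100`` and ``fdr_q=0.05`` are the full-scale
    settings; desk-scale runs lower ``top_k``, ``n_topics`` and
    ``lda_iterations``.
    """

    def __init__(
        self,
        tweets: Sequence[TweetRecord],
        outcome: Mapping[str, float] | pd.Series,
        community_of_county: Mapping[str, str] | pd.Series | None = None,
        state_of_county: Mapping[str, str] | pd.Series | None = None,
        *,
        keyword: str = "drunk",
        exclusion_phrases: Sequence[str] = DEFAULT_EXCLUSION_PHRASES,
        is_english: Callable[[str], bool] = tag_is_english,
        gazetteer: Gazetteer | None = None,
        min_county_words: int = 1000,
        phrase_min_count: int = 10,
        phrase_pmi_threshold: float = 3.0,
        detect_phrases_enabled: bool = True,
        alpha0: float = logodds.DEFAULT_ALPHA0,
        top_k: int = 5000,
        z_floor: float | None = 1.96,
        comparison_sample: int | None = None,
        n_topics: int = 100,
        lda_alpha: float | None = None,
        lda_beta: float = 0.01,
        lda_iterations: int = 1000,
        fdr_q: float = 0.05,
        community_min_fraction: float = 0.25,
        pronoun_list: set[str] | None = None,
        positive_lexicon: Mapping[str, float] | None = None,
        fit_topics: bool = True,
    ) -> None:
        self.tweets = list(tweets)
        self.outcome = pd.Series(outcome, dtype=float)
        if ((self.outcome < 0) | (self.outcome > 1)).any():
            raise ValueError("outcome prevalences must lie in [0, 1]")
        self.community_of_county = (
            pd.Series(community_of_county) if community_of_county is not None else None
        )
        self.state_of_county = (
            pd.Series(state_of_county) if state_of_county is not None else None
        )
        self.keyword = keyword
        self.exclusion_phrases = tuple(exclusion_phrases)
        self.is_english = is_english
        self.gazetteer = gazetteer
        self.min_county_words = int(min_county_words)
        self.phrase_min_count = int(phrase_min_count)
        self.phrase_pmi_threshold = float(phrase_pmi_threshold)
        self.detect_phrases_enabled = bool(detect_phrases_enabled)
        self.alpha0 = float(alpha0)
        self.top_k = int(top_k)
        self.z_floor = z_floor
        self.comparison_sample = comparison_sample
        self.n_topics = int(n_topics)
        self.lda_alpha = lda_alpha
        self.lda_beta = float(lda_beta)
        self.lda_iterations = int(lda_iterations)
        self.fdr_q = float(fdr_q)
        self.community_min_fraction = float(community_min_fraction)
        self.pronoun_list = pronoun_list if pronoun_list is not None else default_pronouns()
        self.positive_lexicon = (
            dict(positive_lexicon) if positive_lexicon is not None else default_lexicon()
        )
        self.fit_topics = bool(fit_topics)

    # -- stages -----------------------------------------------------------

    def _resolve(self, tweet: TweetRecord) -> str | None:
        if self.gazetteer is None:
            return tweet.county_id
        return resolve_county(tweet, self.gazetteer)

    def fit(self, seed: int = 0) -> DrunkTweetsResults:
        rng = np.random.default_rng(seed)
        report = FilterReport(n_input=len(self.tweets))

        # tokenize the whole stream once; every later stage reuses these
        tokens_of: dict[str, list[str]] = {tw.id: tokenize(tw.text) for tw in self.tweets}
        kw = self.keyword.casefold()

        # inclusion pipeline
        matched = [tw for tw in self.tweets if kw in tokens_of[tw.id]]
        report.n_keyword_matched = len(matched)
        drunk = [
            tw
            for tw in matched
            if not any(ph in tw.text.casefold() for ph in self.exclusion_phrases)
        ]
        report.n_after_exclusion = len(drunk)
        drunk = list(language_filter(drunk, self.is_english))
        report.n_language_retained = len(drunk)
        county_of_tweet: dict[str, str] = {}
        geolocated: list[TweetRecord] = []
        for tw in drunk:
            county = self._resolve(tw)
            if county is not None:
                county_of_tweet[tw.id] = county
                geolocated.append(tw)
        report.n_geolocated = len(geolocated)

        # background corpus: English tweets without the keyword
        background = [
            tw
            for tw in language_filter(self.tweets, self.is_english)
            if kw not in tokens_of[tw.id]
        ]
        if self.comparison_sample is not None:
            k = self.comparison_sample
            if len(geolocated) > k:
                geolocated_sample = [geolocated[i] for i in rng.choice(len(geolocated), k, replace=False)]
            else:
                geolocated_sample = geolocated
            if len(background) > k:
                background = [background[i] for i in rng.choice(len(background), k, replace=False)]
        else:
            geolocated_sample = geolocated

        # phrase detection (on the drunk corpus)
        drunk_tok = [TokenizedTweet(tw.id, list(tokens_of[tw.id])) for tw in geolocated]
        back_tok = [TokenizedTweet(tw.id, list(tokens_of[tw.id])) for tw in background]
        if self.detect_phrases_enabled:
            phrases = detect_phrases(
                (t.tokens for t in drunk_tok),
                min_count=self.phrase_min_count,
                pmi_threshold=self.phrase_pmi_threshold,
            )
            if phrases:
                drunk_tok = [
                    TokenizedTweet(t.id, merge_phrases(t.tokens, phrases)) for t in drunk_tok
                ]
                back_tok = [
                    TokenizedTweet(t.id, merge_phrases(t.tokens, phrases)) for t in back_tok
                ]

        # county word threshold
        word_counts: dict[str, int] = {}
        for t in drunk_tok:
            county = county_of_tweet[t.id]
            word_counts[county] = word_counts.get(county, 0) + len(t.tokens)
        report.n_counties = len(word_counts)
        retained = threshold_counties(word_counts, self.min_county_words)
        retained &= set(self.outcome.index)
        report.n_counties_retained = len(retained)
        if self.community_of_county is not None:
            retained_communities = communities_meeting_threshold(
                self.community_of_county.to_dict(), retained, self.community_min_fraction
            )
        else:
            retained_communities = set()

        drunk_tok = [t for t in drunk_tok if county_of_tweet[t.id] in retained]

        # total tweets per retained county (denominator of drunk frequency)
        all_counts: dict[str, int] = {}
        for tw in self.tweets:
            county = self._resolve(tw)
            if county in retained:
                all_counts[county] = all_counts.get(county, 0) + 1

        aggregates = aggregate_counties(drunk_tok, county_of_tweet, all_counts)

        # distinctive terms: drunk vs background
        drunk_sample_ids = {tw.id for tw in geolocated_sample}
        counts_drunk = logodds.corpus_counts(
            t for t in drunk_tok if t.id in drunk_sample_ids
        )
        counts_back = logodds.corpus_counts(back_tok)
        distinctive = logodds.weighted_log_odds(
            counts_drunk, counts_back, alpha0=self.alpha0
        )
        vocab = logodds.select_top_tokens(distinctive, k=self.top_k, z_floor=self.z_floor)
        restricted, n_emptied = logodds.restrict_corpus(drunk_tok, vocab)

        # topic model + loadings
        lda_results: LdaResults | None = None
        loadings = pd.DataFrame()
        excluded: list[str] = []
        if self.fit_topics and restricted:
            model_vocab = sorted({w for t in restricted for w in t.tokens})
            lda = LdaGibbs(
                restricted,
                n_topics=self.n_topics,
                alpha=self.lda_alpha,
                beta=self.lda_beta,
                n_iter=self.lda_iterations,
                vocabulary=model_vocab,
            )
            lda_results = lda.fit(seed=int(rng.integers(0, 2**31 - 1)))
            loadings, excluded = county_topic_loadings(lda_results, aggregates)

        # county table and frequency-outcome correlations
        county_ids = sorted(aggregates)
        county_table = pd.DataFrame(
            {
                "drunk_frequency": [aggregates[c].drunk_frequency for c in county_ids],
                "outcome": [self.outcome.get(c, np.nan) for c in county_ids],
            },
            index=pd.Index(county_ids, name="county_id"),
        )
        if self.community_of_county is not None:
            county_table["community"] = self.community_of_county.reindex(county_ids)
        correlations = self._correlation_table(county_table, retained_communities)

        # DLA and community contrasts over topic loadings
        dla = None
        comm_assoc = None
        if lda_results is not None and len(loadings) >= 3:
            dla = assoc.dla_regression(loadings, self.outcome, fdr_q=self.fdr_q)
            if self.community_of_county is not None and retained_communities:
                labels = self.community_of_county[
                    self.community_of_county.isin(retained_communities)
                ]
                comm_assoc = assoc.community_contrasts(loadings, labels, fdr_q=self.fdr_q)

        # style scores per community
        style_tab = None
        if self.community_of_county is not None and len(retained_communities) >= 2:
            group_corpora: dict[str, list[TokenizedTweet]] = {}
            for t in drunk_tok:
                comm = self.community_of_county.get(county_of_tweet[t.id])
                if comm in retained_communities:
                    group_corpora.setdefault(comm, []).append(t)
            if len(group_corpora) >= 2:
                style_tab = style.style_table(
                    group_corpora,
                    pronoun_list=self.pronoun_list,
                    positive_lexicon=self.positive_lexicon,
                )

        echo = {
            "seed": seed,
            "keyword": self.keyword,
            "exclusion_phrases": list(self.exclusion_phrases),
            "min_county_words": self.min_county_words,
            "alpha0": self.alpha0,
            "top_k": self.top_k,
            "z_floor": self.z_floor,
            "n_topics": self.n_topics,
            "lda_beta": self.lda_beta,
            "lda_iterations": self.lda_iterations,
            "fdr_q": self.fdr_q,
            "n_restricted_tweets": len(restricted),
            "n_tweets_emptied_by_restriction": n_emptied,
            "counties_excluded_from_loadings": excluded,
        }
        return DrunkTweetsResults(
            filter_report=report,
            distinctive=distinctive,
            lda=lda_results,
            loadings=loadings,
            county_table=county_table,
            correlations=correlations,
            dla=dla,
            community_associations=comm_assoc,
            style_table=style_tab,
            retained_counties=sorted(retained),
            retained_communities=sorted(retained_communities),
            config_echo=echo,
        )

    def _correlation_table(
        self, county_table: pd.DataFrame, retained_communities: set[str]
    ) -> pd.DataFrame:
        """Drunk-tweet frequency vs outcome at each spatial level.

        State- and community-level variables are county-level averages; the
        correlation at each level needs at least 3 non-constant units.
        """
        rows = []
        valid = county_table.dropna(subset=["outcome"])
        freq = valid["drunk_frequency"]
        out = valid["outcome"]

        def _row(unit: str, x: pd.Series, y: pd.Series) -> None:
            if len(x) >= 3 and x.std() > 0 and y.std() > 0:
                r, lo, hi, p = assoc.pearson_with_ci(x.to_numpy(), y.to_numpy())
                rows.append({"unit": unit, "n": len(x), "r": r, "ci_low": lo,
                             "ci_high": hi, "p": p})
            else:
                rows.append({"unit": unit, "n": len(x), "r": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})

        _row("county", freq, out)
        if self.state_of_county is not None:
            g = assoc.aggregate_to_groups(freq, self.state_of_county)
            h = assoc.aggregate_to_groups(out, self.state_of_county)
            common = g.index.intersection(h.index)
            _row("state", g.loc[common, "mean"], h.loc[common, "mean"])
        if self.community_of_county is not None and retained_communities:
            labels = self.community_of_county[
                self.community_of_county.isin(retained_communities)
            ]
            g = assoc.aggregate_to_groups(freq, labels)
            h = assoc.aggregate_to_groups(out, labels)
            common = g.index.intersection(h.index)
            _row("community", g.loc[common, "mean"], h.loc[common, "mean"])
        return pd.DataFrame(rows).set_index("unit")
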