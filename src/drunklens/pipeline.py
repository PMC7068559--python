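"""Pipeline orchestration from a single config file, plus fixture packaging.

A :class:`PipelineConfig` names the input files (tweet stream, county outcome
table, community labeling, keyword list, lexica) and all stage parameters;
:func:`run_pipeline` loads everything, fits :class:`~drunklens.model.DrunkTweetsModel`
and writes the report bundle.  :func:`make_fixture` writes a self-contained
synthetic dataset (corpus + tables + ground truth) that loads through every
reader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from importlib import resources

import pandas as pd
import yaml

from . import style, synthetic
from .ingest import build_keyword_set, load_keywords
from .model import DrunkTweetsModel, DrunkTweetsResults

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "packaged_keywords"]


def packaged_keywords() -> list[str]:
    """The shipped synthetic drinking-keyword base list (46 entries)."""
    path = resources.files("drunklens.data") / "keywords_synthetic.txt"
    with resources.as_file(path) as p:
        return load_keywords(p)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run; YAML-loadable."""

    tweets: str = "tweets.jsonl"
    outcome: str = "counties.csv"
    communities: str | None = None          # defaults to outcome table column
    keywords: str | None = None             # defaults to the packaged list
    pronouns: str | None = None
    lexicon: str | None = None
    out_dir: str = "report"
    min_county_words: int = 1000
    top_k: int = 5000
    z_floor: float | None = 1.96
    alpha0: float = 500.0
    n_topics: int = 100
    lda_iterations: int = 1000
    phrase_min_count: int = 10
    phrase_pmi_threshold: float = 3.0
    fdr_q: float = 0.05
    community_min_fraction: float = 0.25
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)


def _load_county_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "county_id" in df.columns:
        df = df.set_index("county_id")
    else:
        df = df.set_index(df.columns[0])
    return df


def run_pipeline(config: PipelineConfig) -> DrunkTweetsResults:
    """Execute filter -> tokenize -> distinctive -> topics -> loadings ->
    associations -> style from a config; persist all tables to ``out_dir``.

    Rerunning with the same config and seed reproduces every table.
    """
    tweets = synthetic.read_tweets(config.tweets)
    county = _load_county_table(config.outcome)
    outcome_col = "excessive_drinking" if "excessive_drinking" in county.columns else county.columns[0]
    outcome = county[outcome_col].astype(float)
    if config.communities:
        communities = _load_county_table(config.communities).iloc[:, -1]
    elif "community" in county.columns:
        communities = county["community"]
    else:
        communities = None
    pronouns = style.load_word_list(config.pronouns) if config.pronouns else None
    lexicon = style.load_lexicon(config.lexicon) if config.lexicon else None

    model = DrunkTweetsModel(
        tweets,
        outcome,
        communities,
        min_county_words=config.min_county_words,
        top_k=config.top_k,
        z_floor=config.z_floor,
        alpha0=config.alpha0,
        n_topics=config.n_topics,
        lda_iterations=config.lda_iterations,
        phrase_min_count=config.phrase_min_count,
        phrase_pmi_threshold=config.phrase_pmi_threshold,
        fdr_q=config.fdr_q,
        community_min_fraction=config.community_min_fraction,
        pronoun_list=pronouns,
        positive_lexicon=lexicon,
    )
    results = model.fit(seed=config.seed)
    results.config_echo.update(asdict(config))
    results.to_dir(config.out_dir)
    return results


def make_fixture(seed: int, out_dir: str = "fixture") -> synthetic.SyntheticConfig:
    """Write a packaged synthetic dataset for demos and end-to-end runs.

    150 counties in 15 community types, 300 tweets each (~45k tweets), target
    propensity/outcome correlation 0.45 — large enough that the county-level
    drunk-frequency/outcome correlation is recoverable to within ~0.15.
    Writes the tweet stream, county table (outcome + community), keyword
    list, toy lexica and the generator's ground truth.
    """
    config = synthetic.SyntheticConfig(
        n_counties=150,
        n_communities=15,
        tweets_per_county=300,
        target_outcome_correlation=0.45,
        seed=seed,
    )
    tweets, truth = synthetic.generate_corpus(config)
    os.makedirs(out_dir, exist_ok=True)
    synthetic.write_tweets(os.path.join(out_dir, "tweets.jsonl"), tweets)
    county = pd.DataFrame(
        {
            "excessive_drinking": truth.county_outcome,
            "community": truth.community_of_county,
        }
    )
    county.index.name = "county_id"
    county.to_csv(os.path.join(out_dir, "counties.csv"))
    with open(os.path.join(out_dir, "keywords.txt"), "w") as fh:
        fh.write("\n".join(build_keyword_set(packaged_keywords(), "drunk")) + "\n")
    for name in ("pronouns.txt", "sentiment_toy_synthetic.tsv"):
        src = resources.files("drunklens.data") / name
        with resources.as_file(src) as p, open(p) as rf:
            with open(os.path.join(out_dir, name), "w") as wf:
                wf.write(rf.read())
    synthetic.write_ground_truth(os.path.join(out_dir, "ground_truth"), truth)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "tweets": os.path.join(out_dir, "tweets.jsonl"),
                "outcome": os.path.join(out_dir, "counties.csv"),
                "min_county_words": 200,
                "top_k": 500,
                "n_topics": 8,
                "lda_iterations": 150,
                "seed": seed,
            },
            fh,
        )
    return config
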