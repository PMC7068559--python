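import numpy as np
import pytest

from drunklens.ingest import TweetRecord
from drunklens.synthetic import SyntheticConfig, generate_corpus
from drunklens.tokenize import TokenizedTweet


@pytest.fixture(scope="session")
def tiny_corpus():
    """9 counties / 3 communities: the smoke-scale synthetic corpus."""
    config = SyntheticConfig(
        n_counties=9,
        n_communities=3,
        tweets_per_county=120,
        drunk_rate_range=(0.1, 0.9),
        target_outcome_correlation=0.45,
        doc_length_mean=8.0,
        seed=11,
    )
    tweets, truth = generate_corpus(config)
    return config, tweets, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tweet(i, text, **kw):
    return TweetRecord(id=f"t{i}", text=text, **kw)


def tok(i, tokens):
    return TokenizedTweet(id=f"t{i}", tokens=list(tokens))
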