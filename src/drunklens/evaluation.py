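"""Validation experiments and independent reference implementations.

These routines quantify how well the pipeline recovers known ground truth
from synthetic corpora:

* topic recovery — fit the Gibbs sampler to corpora drawn from known topics
  and measure the greedily matched total-variation distance;
* end-to-end correlation calibration — generate counties with a known
  propensity/outcome correlation, push the tweets through the real filter and
  aggregation stages, and compare the estimated county-level correlation with
  the target;
* null false-discovery calibration — run the differential language analysis
  on outcome-independent topic loadings and measure the realized
  false-discovery proportion under BH control.

The module also carries deliberately naive reference implementations (direct
formula evaluation, step-up enumeration) used to cross-check the vectorized
production code; they are written independently of the code they check.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .association import benjamini_hochberg, dla_regression
from .lda import LdaGibbs
from .model import DrunkTweetsModel
from .synthetic import SyntheticConfig, generate_corpus
from .tokenize import TokenizedTweet

__all__ = [
    "greedy_tv_match",
    "sample_lda_corpus",
    "lda_recovery_trial",
    "end_to_end_correlation",
    "null_fdr_replicates",
    "direct_log_odds",
    "stepup_bh_reference",
]


# ---------------------------------------------------------------------------
# topic recovery

def greedy_tv_match(true_topics: np.ndarray, fitted_phi: np.ndarray) -> float:
    """Mean total-variation distance under greedy one-to-one topic matching.

    Repeatedly pairs the (true, fitted) topic pair with the smallest TV
    distance among the unmatched, then averages the matched distances.
    """
    K = true_topics.shape[0]
    tv = 0.5 * np.abs(true_topics[:, None, :] - fitted_phi[None, :, :]).sum(axis=2)
    used_true: set[int] = set()
    used_fit: set[int] = set()
    total = 0.0
    for _ in range(K):
        best: tuple[float, int, int] | None = None
        for i in range(K):
            if i in used_true:
                continue
            for j in range(K):
                if j in used_fit:
                    continue
                if best is None or tv[i, j] < best[0]:
                    best = (float(tv[i, j]), i, j)
        assert best is not None
        total += best[0]
        used_true.add(best[1])
        used_fit.add(best[2])
    return total / K


def sample_lda_corpus(
    rng: np.random.Generator,
    topics: np.ndarray,
    n_docs: int,
    doc_length_mean: float,
    doc_topic_alpha: float = 0.3,
) -> list[TokenizedTweet]:
    """Draw documents from the LDA generative process over known topics."""
    K, V = topics.shape
    vocab = np.array([f"w{i:04d}" for i in range(V)])
    word_cdf = np.cumsum(topics, axis=1)
    lengths = np.maximum(rng.poisson(doc_length_mean, size=n_docs), 1)
    total = int(lengths.sum())
    theta = rng.dirichlet(np.full(K, doc_topic_alpha), size=n_docs)
    doc_idx = np.repeat(np.arange(n_docs), lengths)
    u = rng.random(total)
    topic_idx = (np.cumsum(theta, axis=1)[doc_idx] > u[:, None]).argmax(axis=1)
    u = rng.random(total)
    word_idx = np.empty(total, dtype=np.int64)
    for k in range(K):
        mask = topic_idx == k
        if mask.any():
            word_idx[mask] = np.searchsorted(word_cdf[k], u[mask], side="right")
    word_idx = np.clip(word_idx, 0, V - 1)
    words = vocab[word_idx]
    starts = np.concatenate([[0], np.cumsum(lengths)])
    return [
        TokenizedTweet(str(d), list(words[starts[d] : starts[d + 1]]))
        for d in range(n_docs)
    ]


def lda_recovery_trial(
    seed: int,
    n_topics: int = 5,
    vocab_size: int = 100,
    n_docs: int = 2000,
    doc_length_mean: float = 20.0,
    topic_concentration: float = 0.1,
    n_iter: int = 500,
    fit_alpha: float = 0.5,
) -> float:
    """One topic-recovery trial: generate, fit, return the matched mean TV.

    The fitting document-topic prior defaults to a sparse ``alpha=0.5``,
    appropriate for short documents (tweets) where the heavyweight
    long-document default 50/K would swamp the per-document counts.
    """
    rng = np.random.default_rng(seed)
    topics = rng.dirichlet(np.full(vocab_size, topic_concentration), size=n_topics)
    corpus = sample_lda_corpus(rng, topics, n_docs, doc_length_mean)
    vocab = [f"w{i:04d}" for i in range(vocab_size)]
    results = LdaGibbs(
        corpus, n_topics=n_topics, alpha=fit_alpha, n_iter=n_iter, vocabulary=vocab
    ).fit(seed=seed)
    return greedy_tv_match(topics, results.phi)


# ---------------------------------------------------------------------------
# end-to-end correlation calibration

def end_to_end_correlation(
    seed: int,
    n_counties: int = 300,
    tweets_per_county: int = 200,
    target_correlation: float = 0.45,
    doc_length_mean: float = 8.0,
    min_county_words: int = 30,
) -> float:
    """Estimated county-level drunk-frequency/outcome correlation, one seed.

    Generates a synthetic corpus at the target correlation and runs the real
    frequency pipeline (keyword filter, language filter, county aggregation,
    Pearson correlation).  The desk-scale word threshold (30) keeps
    essentially every county; the full-scale threshold of 1000 words assumes
    far larger per-county streams.
    """
    config = SyntheticConfig(
        n_counties=n_counties,
        n_communities=15,
        tweets_per_county=tweets_per_county,
        target_outcome_correlation=target_correlation,
        doc_length_mean=doc_length_mean,
        seed=seed,
    )
    tweets, truth = generate_corpus(config)
    model = DrunkTweetsModel(
        tweets,
        truth.county_outcome,
        truth.community_of_county,
        min_county_words=min_county_words,
        top_k=100,
        z_floor=None,
        detect_phrases_enabled=False,
        fit_topics=False,
    )
    results = model.fit(seed=seed)
    return float(results.correlations.loc["county", "r"])


# ---------------------------------------------------------------------------
# null false-discovery calibration

def null_fdr_replicates(
    n_replicates: int = 200,
    n_counties: int = 300,
    n_topics: int = 100,
    q: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Realized false-discovery proportion per replicate under a global null.

    Topic loadings are Dirichlet county mixtures independent of the outcome,
    so every rejection by the BH-controlled DLA is a false discovery; the
    returned FDP is (#discoveries > 0) ? discoveries/discoveries : 0, which
    under an all-null configuration equals 1 whenever anything is rejected.
    The quantity of interest is its mean, the empirical FDR.
    """
    rng = np.random.default_rng(seed)
    fdps = np.empty(n_replicates)
    for rep in range(n_replicates):
        loadings = pd.DataFrame(
            rng.dirichlet(np.ones(n_topics), size=n_counties),
            index=[f"c{i:04d}" for i in range(n_counties)],
            columns=[f"topic_{k:03d}" for k in range(n_topics)],
        )
        outcome = pd.Series(
            rng.normal(0.2, 0.05, size=n_counties), index=loadings.index
        ).clip(0, 1)
        table = dla_regression(loadings, outcome, fdr_q=q)
        n_discoveries = int(table["significant"].sum())
        fdps[rep] = 1.0 if n_discoveries > 0 else 0.0
    return fdps


# ---------------------------------------------------------------------------
# naive reference implementations (oracles)

def direct_log_odds(
    y_i: float, n_i: float, y_j: float, n_j: float, a_w: float, a0: float
) -> tuple[float, float, float]:
    """Scalar, formula-by-formula weighted log-odds for one token.

    delta = log[(y_i + a_w)/(n_i + a0 - y_i - a_w)]
          - log[(y_j + a_w)/(n_j + a0 - y_j - a_w)];
    var = 1/(y_i + a_w) + 1/(y_j + a_w); z = delta/sqrt(var).
    """
    delta = math.log((y_i + a_w) / (n_i + a0 - y_i - a_w)) - math.log(
        (y_j + a_w) / (n_j + a0 - y_j - a_w)
    )
    var = 1.0 / (y_i + a_w) + 1.0 / (y_j + a_w)
    return delta, var, delta / math.sqrt(var)


def stepup_bh_reference(
    p_values: Sequence[float], q: float
) -> tuple[list[bool], list[float]]:
    """Literal step-up enumeration of the BH procedure, one comparison at a
    time, plus the definitional adjusted p (min over j >= i of m p_(j)/j)."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
            break
    reject = [False] * m
    for idx in range(k_star):
        reject[order[idx]] = True
    adjusted = [0.0] * m
    for rank, i in enumerate(order, start=1):
        candidates = []
        for rank_j, j in enumerate(order, start=1):
            if rank_j >= rank:
                candidates.append(m * p[j] / rank_j)
        adjusted[i] = min(1.0, min(candidates))
    return reject, adjusted


def pearson_reference(x: Sequence[float], y: Sequence[float]) -> float:
    """Textbook Pearson formula, accumulated term by term."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
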