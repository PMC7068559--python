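"""Latent Dirichlet allocation by collapsed Gibbs sampling, and county topic
loadings.

The model is the standard smoothed LDA: each document d draws a topic mixture
theta_d ~ Dirichlet(alpha), each token draws a topic from theta_d and a word
from that topic's distribution phi_k ~ Dirichlet(beta).  Collapsed Gibbs
sampling integrates theta and phi out and resamples each token's topic
assignment from

    p(z = k | rest)  ∝  (n_dk + alpha) * (n_kw + beta) / (n_k + V*beta)

with all counts excluding the current position.  phi is read off the final
counts, (n_kw + beta) / (n_k + V*beta); a single final sample is used (no
averaging across iterations).

County topic loadings follow the mixture identity

    P(topic | county) = sum_w P(topic | w) * P(w | county)

where P(topic | w) is the Bayes inversion of phi under the empirical topic
prevalence and P(w | county) is the county's relative token frequency
renormalized over the model vocabulary.  Because P(topic | w) rows sum to one
and P(w | county) is a distribution, each county's loading vector sums to one.

The sampler inner loop is JIT-compiled with numba; a fit is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .tokenize import CountyAggregate, TokenizedTweet

__all__ = ["LdaGibbs", "LdaResults", "county_topic_loadings"]


@njit(cache=True)
def _gibbs_sample(tokens, doc_of_token, n_docs, K, V, alpha, beta, n_iter, seed):
    np.random.seed(seed)
    N = tokens.shape[0]
    n_kw = np.zeros((K, V), dtype=np.int64)
    n_k = np.zeros(K, dtype=np.int64)
    n_dk = np.zeros((n_docs, K), dtype=np.int64)
    z = np.empty(N, dtype=np.int64)
    for i in range(N):
        k = np.random.randint(0, K)
        z[i] = k
        n_kw[k, tokens[i]] += 1
        n_k[k] += 1
        n_dk[doc_of_token[i], k] += 1

    probs = np.empty(K, dtype=np.float64)
    vbeta = V * beta
    for _ in range(n_iter):
        for i in range(N):
            w = tokens[i]
            d = doc_of_token[i]
            k = z[i]
            n_kw[k, w] -= 1
            n_k[k] -= 1
            n_dk[d, k] -= 1
            total = 0.0
            for kk in range(K):
                p = (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (n_k[kk] + vbeta)
                probs[kk] = p
                total += p
            u = np.random.random() * total
            acc = 0.0
            k_new = K - 1
            for kk in range(K):
                acc += probs[kk]
                if u < acc:
                    k_new = kk
                    break
            z[i] = k_new
            n_kw[k_new, w] += 1
            n_k[k_new] += 1
            n_dk[d, k_new] += 1
    return z, n_kw, n_k, n_dk


@dataclass
class LdaResults:
    """A fitted topic model: topic-word distributions and derived posteriors."""

    vocabulary: list[str]
    phi: np.ndarray                 # [K, V], rows sum to 1
    topic_prevalence: np.ndarray    # [K], empirical assignment shares
    assignments: np.ndarray         # final topic of each token position
    n_topics: int
    alpha: float
    beta: float
    n_iter: int
    seed: int

    @property
    def topic_given_token(self) -> np.ndarray:
        """P(topic | token), shape [V, K]: Bayes inversion of phi.

        P(k | w) = phi[k, w] P(k) / sum_k' phi[k', w] P(k'), with P(k) the
        empirical prevalence of topic assignments.  Rows sum to one.
        """
        joint = self.phi.T * self.topic_prevalence[None, :]   # [V, K]
        denom = joint.sum(axis=1, keepdims=True)
        if (denom <= 0).any():
            raise ValueError("token with zero posterior mass")
        return joint / denom

    def top_words(self, topic: int, n: int = 10) -> list[str]:
        order = np.argsort(-self.phi[topic])[:n]
        return [self.vocabulary[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.phi, columns=self.vocabulary,
            index=pd.Index(range(self.n_topics), name="topic"),
        )

    def summary(self, n_words: int = 8) -> pd.DataFrame:
        rows = [
            {
                "topic": k,
                "prevalence": self.topic_prevalence[k],
                "top_words": " ".join(self.top_words(k, n_words)),
            }
            for k in range(self.n_topics)
        ]
        return pd.DataFrame(rows).set_index("topic")


class LdaGibbs:
    """Collapsed-Gibbs LDA over a tokenized corpus (one tweet = one document).

    Parameters
    ----------
    corpus:
        Tokenized tweets; every token must be in ``vocabulary`` (pass an
        explicit vocabulary to enforce a restricted token set, otherwise it
        is inferred from the corpus).
    n_topics:
        Number of topics K (>= 2).
    alpha, beta:
        Dirichlet hyperparameters for the document-topic and topic-word
        distributions; ``alpha`` defaults to 50/K, ``beta`` to 0.01 (the
        conventional Gibbs-LDA defaults).
    n_iter:
        Gibbs sweeps over the corpus; the final sweep's assignments are the
        fitted state.
    """

    def __init__(
        self,
        corpus: Sequence[TokenizedTweet],
        n_topics: int,
        alpha: float | None = None,
        beta: float = 0.01,
        n_iter: int = 1000,
        vocabulary: Sequence[str] | None = None,
    ) -> None:
        if n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        if alpha is None:
            alpha = 50.0 / n_topics
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        docs = [t for t in corpus if t.tokens]
        if not docs:
            raise ValueError("corpus is empty")
        if vocabulary is None:
            vocabulary = sorted({w for t in docs for w in t.tokens})
        self.vocabulary = list(vocabulary)
        index = {w: i for i, w in enumerate(self.vocabulary)}
        token_ids: list[int] = []
        doc_ids: list[int] = []
        for d, tweet in enumerate(docs):
            for w in tweet.tokens:
                if w not in index:
                    raise ValueError(f"token {w!r} outside the model vocabulary")
                token_ids.append(index[w])
                doc_ids.append(d)
        self._tokens = np.asarray(token_ids, dtype=np.int64)
        self._docs = np.asarray(doc_ids, dtype=np.int64)
        self.n_docs = len(docs)
        self.n_topics = int(n_topics)
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.n_iter = int(n_iter)

    def fit(self, seed: int = 0) -> LdaResults:
        """Run the sampler and read off phi and the topic prevalence."""
        V = len(self.vocabulary)
        z, n_kw, n_k, _ = _gibbs_sample(
            self._tokens, self._docs, self.n_docs,
            self.n_topics, V, self.alpha, self.beta, self.n_iter, int(seed),
        )
        phi = (n_kw + self.beta) / (n_k[:, None] + V * self.beta)
        prevalence = n_k / n_k.sum()
        return LdaResults(
            vocabulary=self.vocabulary,
            phi=phi,
            topic_prevalence=prevalence,
            assignments=z,
            n_topics=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            n_iter=self.n_iter,
            seed=int(seed),
        )


def county_topic_loadings(
    results: LdaResults,
    aggregates: Mapping[str, CountyAggregate] | Iterable[CountyAggregate],
) -> tuple[pd.DataFrame, list[str]]:
    """County topic loadings P(topic | county) via the mixture identity.

    Each county's token frequencies are renormalized over the model
    vocabulary before mixing, so loadings are comparable across counties with
    different out-of-vocabulary fractions.  Counties with zero mass on the
    model vocabulary cannot be scored; they are excluded and returned in the
    second element.

    Returns a (county x topic) DataFrame whose rows sum to one, plus the list
    of excluded county ids.
    """
    if isinstance(aggregates, Mapping):
        aggs = list(aggregates.values())
    else:
        aggs = list(aggregates)
    p_topic_token = results.topic_given_token                   # [V, K]
    index = {w: i for i, w in enumerate(results.vocabulary)}
    rows = []
    county_ids = []
    excluded: list[str] = []
    for agg in aggs:
        p_w = np.zeros(len(results.vocabulary))
        for w, c in agg.token_count.items():
            i = index.get(w)
            if i is not None:
                p_w[i] = c
        mass = p_w.sum()
        if mass == 0:
            excluded.append(agg.county_id)
            continue
        p_w /= mass
        rows.append(p_w @ p_topic_token)
        county_ids.append(agg.county_id)
    loadings = pd.DataFrame(
        rows,
        index=pd.Index(county_ids, name="county_id"),
        columns=[f"topic_{k:03d}" for k in range(results.n_topics)],
    )
    return loadings, excluded
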