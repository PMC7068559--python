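# Methods

This note documents the statistical machinery in `drunklens`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Inclusion pipeline

A post is a *drunk tweet* when the token `drunk` appears in its tokenized
form. Inclusion is **whole-token**: "drunkard" does not match. Exclusion of
the phrase "drunk in love" is **substring** matching on case-folded text,
because a quoted phrase (a song title) should be screened out wherever it
appears, including inside longer sentences. The language filter is an
injected predicate (`text -> bool`); production use would plug in a language
classifier, synthetic runs test the generator's language tag. County
resolution is likewise an injected gazetteer contract (pre-resolved id →
coordinates → profile string, in that precedence); the repository ships only
a toy grid gazetteer because real county boundary data is out of scope.
Counties need at least `min_words` (default 1000) tokens of drunk-tweet text
to enter the analysis; the threshold is inclusive and counts post-tokenization
unigram tokens, before phrase merging. A community type stays in the
community-level analyses when at least 25% of its counties pass the word
threshold.

The shipped keyword list (`data/keywords_synthetic.txt`) is a synthetic
46-entry stand-in for a published drinking-keyword list that cannot be
redistributed; with the seed keyword "drunk" the constructed set has 47
entries. The keyword co-occurrence screen builds one binary indicator per
keyword per post and reports all pairwise Pearson correlations; pairs
involving a constant indicator are reported as undefined (NaN), never as 0.

## Tokenization and phrases

The tokenizer is rule-based and deterministic: lowercase; URLs, @-mentions,
hashtags and a western emoticon set survive as single tokens; remaining
punctuation is emitted one symbol at a time. Collocations are adjacent
bigrams with count ≥ `min_count` (default 10) and pointwise mutual
information ≥ `pmi_threshold` (default 3.0, in nats); merging is a single
left-to-right pass and never crosses post boundaries. PMI was chosen as the
minimal statistic expressing "co-occurs more than chance"; both knobs are
explicit configuration.

## Weighted log-odds with informative Dirichlet prior

For token w with counts y_iw (drunk corpus, total n_i) and y_jw (background
corpus, total n_j) and prior counts α_w summing to α_0:

    δ_w  = log[(y_iw + α_w) / (n_i + α_0 − y_iw − α_w)]
         − log[(y_jw + α_w) / (n_j + α_0 − y_jw − α_w)]
    var(δ_w) ≈ 1/(y_iw + α_w) + 1/(y_jw + α_w)
    z_w  = δ_w / sqrt(var)

The prior defaults to the pooled relative frequency of both corpora scaled
to α_0 = 500 — the background-shrinkage role of the prior with a scale large
enough to tame rare-token variance but small against desk-scale corpora.
Both the prior and α_0 are configurable because no canonical scale exists.
Vocabulary restriction ranks by signed z (drunk-associated first, ties
lexicographic) with an optional |z| ≥ 1.96 floor (on by default) before the
top-K cut (K = 5000 at full scale). Tokens absent from both corpora have no
defined odds and are dropped from the union vocabulary.

## Topic model

Standard smoothed LDA fit by collapsed Gibbs sampling with the usual full
conditional p(z=k|rest) ∝ (n_dk + α)(n_kw + β)/(n_k + Vβ), counts excluding
the current position. One tweet is one document. φ is read off the final
sweep's counts ((n_kw+β)/(n_k+Vβ)); a single final sample is used, no
averaging, no thinning, single chain. Defaults α = 50/K, β = 0.01, 1000
iterations, K = 100 at full scale — the conventional defaults of
Gibbs-sampling LDA toolkits. The sampler inner loop is numba-compiled and
deterministic given the seed.

P(topic|token) is the Bayes inversion of φ under the empirical assignment
prevalence. County loadings follow

    P(topic|county) = Σ_w P(topic|w) · P(w|county)

summed over the **full** model vocabulary ("membership" of a token in a
topic is soft under smoothing; restricting to top-N topic words is exposed
as an option but off by default). County frequency vectors are renormalized
over the model vocabulary first, so each loading vector sums to exactly 1;
counties with zero mass on the model vocabulary are excluded and reported.

### Topic-recovery experiment

Corpora are drawn from K_true = 5 Dirichlet(0.1) topics over V = 100
symbols, 2000 documents, Poisson(20) lengths, document mixtures
Dirichlet(0.3). Fitted with 500 Gibbs iterations and document-topic prior
**α = 0.5**: the long-document default 50/K is a poor prior for ~20-token
documents (it swamps the per-document counts and blurs the fitted topics),
while a sparse prior matches how practitioners configure LDA for short
social-media text. Recovery is scored by greedy one-to-one matching of
(true, fitted) topic pairs on total-variation distance; the validation
requires mean matched TV < 0.15 in ≥ 90% of 20 seeds. Observed values are
typically ~0.05.

## Association layer

* County-level correlation: Pearson r between drunk-tweet frequency
  (drunk posts / all posts in the county) and the outcome; p from the t
  transform, CI from the Fisher z transform. State- and community-level
  variables are unweighted county-level means.
* Differential language analysis: each topic loading is regressed (OLS)
  against the outcome independently; for a single predictor the OLS t-test
  p equals the correlation-test p (checked numerically). Constant loading
  columns are excluded and reported. Counties missing outcome values are
  dropped pairwise.
* Community contrasts: for each community's dummy outcome, Cohen's d
  ((mean_in − mean_out)/pooled sd, unbiased variances) ranks topics and a
  single-predictor logistic regression Wald p tests them. Perfect
  separation is detected by the threshold criterion on the sorted feature
  and reported as a NaN sentinel with a flag — the MLE does not exist there.
* Benjamini–Hochberg: step-up over the m raw p-values, rejecting 1..k for
  the largest k with p_(k) ≤ kq/m; adjusted p_(i) = min_{j≥i} m·p_(j)/j
  capped at 1, q = 0.05 by default.

### Calibration experiments

*End-to-end correlation.* 300 counties in 15 community types, 200 tweets
per county, documents of mean length 8, drunk propensities in [0.05, 0.5]
with community mean shifts, outcome built in closed form at ρ = 0.45
(outcome = μ_o + ρ(σ_o/σ_p)(p − p̄) + ε with ε ~ N(0, (1−ρ²)σ_o²), location
0.18 and scale 0.05 so clipping to [0,1] is negligible). The full filter and
aggregation stack runs with a desk-scale word threshold of 30 — at ~1600
expected tokens per county the 1000-word threshold would drop exactly the
low-propensity counties and truncate the propensity range, which is a
corpus-size artifact, not part of the method. The estimated county-level
correlation must fall within ±0.10 of ρ in ≥ 90% of 50 seeds (binomial
measurement noise slightly attenuates the estimate; at these sizes the
attenuation factor is ≈ 0.97).

*Null FDR.* Topic loadings independent of the outcome (Dirichlet county
mixtures), 100 topics × 300 counties, 200 replicates. Under a global null
every rejection is false, so the per-replicate false-discovery proportion is
1 if anything is rejected, else 0; the mean over replicates (the empirical
FDR) must be ≤ q + 0.03.

## Style and sentiment

Self score = relative frequency of "i"; other score = summed relative
frequency of "he", "she", "they". Group-level frequencies **pool token
counts** across the group's posts by default; a `by_county_mean` mode
averages county-level frequencies instead (the aggregation is genuinely
ambiguous when groups are sets of counties — both are implemented, pooled is
the default because it weights communities by their actual text volume).
Standardization uses the unbiased (n−1) sd; the population-sd variant is
available via `ddof=0`. A zero-variance column has no defined z-score:
`standardize` raises, and the table builder skips the column.

The personal-pronoun list is an open 31-entry English pronoun list
(proprietary category dictionaries cannot be shipped; the list is a config
input so licensed users can substitute their own). The positive-sentiment
lexicon is a 20-word synthetic toy in the pluggable two-column (word,
weight) format; the score is Σ weight(w)·count(w) / total tokens and is
linear in the weights.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
county-varying drunk propensities, community-level shifts, a latent-topic
document process with a distinct background distribution for non-drunk
posts (so drunk-distinctive tokens exist for the log-odds stage), literal
reserved tokens injected at per-community rates, and configurable fractions
of "drunk in love" posts and non-English posts. It does **not** attempt
real orthography, user networks, bots, or temporal dynamics; passing tests
therefore demonstrate correctness of the pipeline's statistics and string
logic on corpora satisfying the model's assumptions, not robustness to real
Twitter noise. Documents are Poisson-length (minimum 1); vocabulary is
synthetic symbols `w0000…` so that tokenizer behaviour on reserved literal
tokens is exactly testable. Everything is deterministic given the config
seed; per-county document sampling is vectorized.

`make_fixture` packages a 150-county × 300-tweet corpus (~45k posts) — the
smallest scale at which the county-level correlation is recoverable to
within ~0.15 of the target with high probability (at 9 counties the sampling
sd of r alone is ~0.3).

## Numerical choices and degenerate inputs

* Log-odds guards: denominators ≤ 0 (a token owning the entire corpus and
  prior) raise rather than return ±inf.
* |r| = 1 in the DLA reports p = 0 (below the machine-representable range of
  the t transform); the convention is documented rather than silent.
* Undefined correlations (constant vectors) raise; undefined co-occurrence
  pairs are NaN.
* Ranking ties in token selection are broken lexicographically so runs are
  reproducible across platforms.
* Gibbs determinism holds for a fixed numba version; φ rows, posterior rows
  and loading vectors are validated to sum to 1 at 1e-9/1e-6 tolerances.

## Problem sizes

Desk-scale defaults used throughout the tests and validation script: ≤ 300
counties, ≤ 60k posts per run, K ≤ 10 topics, ≤ 500 Gibbs iterations. The
full-scale settings (K = 100, top-5000 vocabulary, 1000-word county
threshold, millions of posts) are configuration, not code changes.
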