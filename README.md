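# drunklens

Regional and cultural analysis of excessive-drinking language on social
media.

## The problem

County-level rates of excessive alcohol consumption (binge and heavy
drinking) are traditionally monitored through large phone surveys. Social
media offers a complementary signal: people post about being drunk, and both
*how often* and *how* they do so varies across regions and community types.
`drunklens` implements an end-to-end pipeline for this kind of digital
epidemiology:

1. **Filter** — keep English posts containing the token `drunk` (whole-token
   match, so "drunkard" does not count), drop posts containing the phrase
   "drunk in love" (a song title), resolve each post to a county, and keep
   counties with at least 1000 words of drunk-post text.
2. **Tokenize** — social-media-aware tokenization (emoticons, hashtags,
   @-mentions and URLs survive as single tokens; `":)!"` → `":)"`, `"!"`)
   plus PMI-based collocation detection ("happy birthday" → one token).
3. **Distinctive terms** — weighted log-odds with an informative Dirichlet
   prior comparing drunk vs non-drunk corpora:
   δ_w = log[(y_iw+α_w)/(n_i+α_0−y_iw−α_w)] − log[(y_jw+α_w)/(n_j+α_0−y_jw−α_w)],
   var(δ_w) ≈ 1/(y_iw+α_w) + 1/(y_jw+α_w), ranked by z = δ/√var; the corpus
   is then restricted to the top-K drunk-associated tokens.
4. **Topics** — LDA fit by collapsed Gibbs sampling (numba-compiled), and
   county topic loadings via the mixture identity
   P(topic|county) = Σ_token P(topic|token) · P(token|county).
5. **Associations** — Pearson correlations of drunk-post frequency with the
   county outcome at county / state / community level; differential language
   analysis (per-topic OLS regressions) with Benjamini–Hochberg FDR control;
   topic–community contrasts via Cohen's *d* and logistic Wald tests.
6. **Style** — self ("i") vs other ("he"/"she"/"they") pronoun frequencies,
   personal-pronoun dictionary counts and weighted positive-sentiment
   scores, z-scored across community types.

Raw geolocated tweet corpora and survey-derived county prevalence files are
not redistributable, so the package ships a first-class **synthetic data
generator**: counties partitioned into community types, per-county drunk
propensities, an outcome variable constructed in closed form to hit a target
correlation ρ, and tweets drawn from a latent-topic generative process with
reserved literal tokens ("drunk", pronouns, sentiment words, "drunk in
love") so every real filtering code path is exercised against known ground
truth.

## Worked example

```python
from drunklens import SyntheticConfig, DrunkTweetsModel, generate_corpus

config = SyntheticConfig(n_counties=60, n_communities=6, tweets_per_county=400,
                         target_outcome_correlation=0.45, seed=7)
tweets, truth = generate_corpus(config)

model = DrunkTweetsModel(
    tweets, truth.county_outcome, truth.community_of_county,
    min_county_words=200, top_k=80, n_topics=6, lda_iterations=200,
)
results = model.fit(seed=7)
print(results.summary())
```

```
Drunk-tweet language analysis
==================================
tweets: 24000 in -> 6455 drunk -> 6455 English -> 6455 geolocated
counties: 60 with drunk tweets, 60 past the word threshold; 6 community types retained

Drunk-tweet frequency vs outcome (Pearson r):
  county     N=   60  r=+0.562 [+0.359, +0.714]  p=2.97e-06
  community  N=    6  r=+0.799 [-0.035, +0.977]  p=0.0563

DLA: 3/6 topics significant after FDR control; top topic topic_000 (r=+0.380, p_adj=0.0164)
```

The county row says that across the 60 synthetic counties the fraction of
posts mentioning "drunk" correlates r = 0.56 with the simulated
excessive-drinking prevalence (generated at target ρ = 0.45; the small-n
estimate overshoots within its confidence interval). The community row is
the same correlation over community-type means. The DLA line reports how
many topic loadings survive FDR control when regressed against the outcome.
Style scores come out of the same results object:

```python
print(results.style_table[["self_freq_z", "other_freq_z"]].round(2))
```

```
              self_freq_z  other_freq_z
group
community_00         0.83          1.14
community_01        -1.83          1.20
community_02        -0.27         -1.10
community_03         0.28         -0.21
community_04         0.08         -0.04
community_05         0.91         -1.00
```

— standardized self/other pronoun frequencies per community type (mean 0,
sd 1 across rows): positive self-z communities talk about their *own*
drinking more than the average community does.

A command-line interface wraps the same stages:

```sh
drunklens simulate --seed 1 --out-dir fixture
drunklens run fixture/config.yaml
drunklens keywords | wc -l     # 47
```

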