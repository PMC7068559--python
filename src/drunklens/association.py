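"""Statistical layer: frequency-outcome correlations, differential language
analysis (DLA), community contrasts, and false-discovery-rate control.

DLA treats each language feature (a county-level topic loading) as an
independent predictor: an ordinary least-squares regression of the outcome on
the feature yields a slope, a Pearson r and a two-sided p-value (for a single
predictor the OLS t-test and the correlation test coincide).  Community
contrasts use Cohen's d for ranking and a single-predictor logistic
regression Wald p for testing.  Multiple comparisons across features are
controlled with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "pearson_with_ci",
    "aggregate_to_groups",
    "dla_regression",
    "cohens_d",
    "logistic_pvalue",
    "benjamini_hochberg",
    "community_contrasts",
]

SEPARATION_P = np.nan  # sentinel p for perfectly separated logistic fits


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float, float]:
    """Pearson r with a Fisher-z confidence interval and a t-test p-value.

    Returns ``(r, ci_low, ci_high, p)``.  The two-sided p comes from the
    t transform t = r sqrt((n-2)/(1-r^2)); the CI from z = atanh(r) with
    standard error 1/sqrt(n-3).  Constant input vectors have no defined
    correlation and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    if abs(r) == 1.0:
        return float(r), float(r), float(r), float(p)
    zcrit = stats.norm.ppf(0.5 + confidence / 2)
    se = 1.0 / np.sqrt(n - 3) if n > 3 else np.inf
    zr = np.arctanh(r)
    lo, hi = np.tanh(zr - zcrit * se), np.tanh(zr + zcrit * se)
    return float(r), float(lo), float(hi), float(p)


def aggregate_to_groups(
    county_values: Mapping[str, float] | pd.Series,
    grouping: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Unweighted county-level means per group (state or community type).

    Every county must belong to exactly one group; returns a frame indexed by
    group with columns ``mean`` and ``n`` (group size).
    """
    values = pd.Series(county_values, dtype=float)
    groups = pd.Series(grouping)
    common = values.index.intersection(groups.index)
    if len(common) == 0:
        raise ValueError("no counties shared between values and grouping")
    df = pd.DataFrame({"value": values[common], "group": groups[common]})
    out = df.groupby("group")["value"].agg(mean="mean", n="size")
    if (out["n"] == 0).any():
        raise ValueError("empty group")
    return out


def dla_regression(
    loadings: pd.DataFrame,
    outcome: Mapping[str, float] | pd.Series,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Differential language analysis: one OLS fit per topic loading.

    For each feature column, regresses the county outcome on the loading and
    reports slope, Pearson r, raw two-sided p, BH-adjusted p and the
    significance flag at ``fdr_q``.  Counties missing from either input are
    dropped pairwise; constant loading columns are flagged and excluded from
    testing.  Results are ordered by r descending.
    """
    outcome = pd.Series(outcome, dtype=float)
    common = loadings.index.intersection(outcome.index)
    if len(common) < 3:
        raise ValueError("need at least 3 counties common to loadings and outcome")
    X = loadings.loc[common]
    y = outcome[common].to_numpy()
    n = len(common)
    y_c = y - y.mean()
    sy = y_c.std(ddof=0)
    if sy == 0:
        raise ValueError("outcome is constant across counties")

    rows = []
    skipped = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        sx = x.std(ddof=0)
        if sx == 0:
            skipped.append(col)
            continue
        x_c = x - x.mean()
        r = float(np.dot(x_c, y_c) / (n * sx * sy))
        slope = r * sy / sx
        r_clip = min(max(r, -1.0), 1.0)
        if abs(r_clip) == 1.0:
            p = 0.0  # below machine-representable under the t transform
        else:
            t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        rows.append({"feature": col, "slope": slope, "r": r, "p_raw": p})
    if not rows:
        raise ValueError("no non-constant features to test")
    out = pd.DataFrame(rows).set_index("feature")
    reject, p_adj = benjamini_hochberg(out["p_raw"].to_numpy(), q=fdr_q)
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    out["n"] = n
    out.attrs["skipped_constant"] = skipped
    return out.sort_values("r", ascending=False)


def cohens_d(values: Sequence[float], membership: Sequence[bool]) -> float:
    """Standardized in-group vs out-group mean difference.

    d = (mean_in - mean_out) / s_pooled with the pooled standard deviation
    computed from unbiased group variances.  Both groups need >= 2 members.
    """
    values = np.asarray(values, dtype=float)
    member = np.asarray(membership, dtype=bool)
    if values.shape != member.shape:
        raise ValueError("values and membership must align")
    a, b = values[member], values[~member]
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 members")
    s2a, s2b = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * s2a + (b.size - 1) * s2b) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class LogisticTestResult:
    p: float
    coef: float
    converged: bool
    separated: bool


def logistic_pvalue(
    feature: Sequence[float], membership: Sequence[bool]
) -> LogisticTestResult:
    """Wald p-value for the slope of a single-predictor logistic regression.

    Fit by iteratively reweighted least squares (Newton).  Perfect separation
    means the MLE does not exist; it is flagged and the p reported as the
    documented NaN sentinel rather than a number.
    """
    x = np.asarray(feature, dtype=float)
    yb = np.asarray(membership, dtype=bool).astype(float)
    if x.std() == 0:
        raise ValueError("feature is constant")
    if yb.min() == yb.max():
        raise ValueError("both classes must be present")
    # standardize the predictor for numerical stability; Wald p is invariant
    xs = (x - x.mean()) / x.std()
    X = sm.add_constant(xs)
    # perfect separation: some threshold on x splits the classes exactly
    order = np.argsort(xs)
    ys = yb[order]
    first_one = np.argmax(ys == 1) if (ys == 1).any() else len(ys)
    last_one = len(ys) - 1 - np.argmax(ys[::-1] == 1)
    separated = bool((ys[first_one:] == 1).all() or (ys[: last_one + 1] == 1).all())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(yb, X).fit(disp=0, maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            return LogisticTestResult(p=SEPARATION_P, coef=np.nan, converged=False,
                                      separated=True)
    if separated:
        return LogisticTestResult(p=SEPARATION_P, coef=float(fit.params[1]),
                                  converged=converged, separated=True)
    return LogisticTestResult(
        p=float(fit.pvalues[1]), coef=float(fit.params[1]),
        converged=converged, separated=False,
    )


def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Sort the m p-values ascending; reject hypotheses 1..k for the largest k
    with p_(k) <= k q / m.  Adjusted p_(i) = min_{j >= i} m p_(j) / j, capped
    at 1.  Returns ``(rejection mask, adjusted p)`` in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    below = p_sorted <= ranks * q / m
    reject_sorted = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0]) + 1
        reject_sorted[:k] = True
    adj_sorted = np.minimum.accumulate((m * p_sorted / ranks)[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    reject = np.empty(m, dtype=bool)
    adjusted = np.empty(m, dtype=float)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


def community_contrasts(
    loadings: pd.DataFrame,
    community_of_county: Mapping[str, str] | pd.Series,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Topic-community associations: Cohen's d and logistic Wald p per pair.

    For every community type, builds the county-level dummy outcome (1 if the
    county belongs to the community) and scores every topic against it.
    Cohen's d ranks the topics; the logistic p, BH-corrected across all
    topic-community pairs, tests them.  Separated fits keep their d but have
    NaN p and are excluded from the correction.
    """
    communities = pd.Series(community_of_county)
    common = loadings.index.intersection(communities.index)
    X = loadings.loc[common]
    labels = communities[common]
    rows = []
    for community in sorted(labels.unique()):
        member = (labels == community).to_numpy()
        if member.sum() < 2 or (~member).sum() < 2:
            continue
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)
            if x.std() == 0:
                continue
            d = cohens_d(x, member)
            lt = logistic_pvalue(x, member)
            rows.append(
                {"community": community, "feature": col, "cohens_d": d,
                 "p_raw": lt.p, "separated": lt.separated}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    testable = ~out["p_raw"].isna()
    out["p_adjusted"] = np.nan
    out["significant"] = False
    if testable.any():
        reject, p_adj = benjamini_hochberg(out.loc[testable, "p_raw"].to_numpy(), q=fdr_q)
        out.loc[testable, "p_adjusted"] = p_adj
        out.loc[testable, "significant"] = reject
    return out.sort_values(["community", "cohens_d"], ascending=[True, False]).reset_index(drop=True)
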