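"""Convergent and criterion validity: NVS scoring, correlations, logistic
regressions with odds ratios, and AUC -> Cohen's d effect sizes.

The Newest Vital Sign (NVS) is a 6-item functional health-literacy screener
whose summed score is banded 0-1 (high likelihood of limited literacy),
2-3 (possibility of limited literacy), >=4 (adequate literacy).  Criterion
validity regresses a binary health-literacy behavior on the assessment score
(plus demographic covariates) and reports the per-point odds ratio with Wald
95% CI; the discrimination of the score for the behavior is summarized as
the ROC area, converted to Cohen's d through the equal-variance binormal
relation d = sqrt(2) * Phi^{-1}(AUC) that generates the published conversion
tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

__all__ = [
    "NVSResult",
    "CriterionResult",
    "score_nvs",
    "convergent_correlation",
    "criterion_logistic",
    "auc",
    "auc_to_cohens_d",
    "crosstab_categories",
]

NVS_CATEGORIES = ("high_likelihood_limited", "possibility_limited", "adequate")


@dataclass(frozen=True)
class NVSResult:
    summed_score: int
    category: str


@dataclass
class CriterionResult:
    outcome_name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    auc: float
    cohens_d: float
    n: int
    converged: bool = True
    separation_detected: bool = False


def score_nvs(item_corrections) -> NVSResult:
    """Score the 6 NVS items (booleans; missing counts as incorrect, flagged)."""
    items = list(item_corrections)
    if len(items) != 6:
        raise ValueError("the NVS has exactly 6 items")
    clean = []
    for v in items:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            warnings.warn("missing NVS response treated as incorrect")
            clean.append(False)
        else:
            clean.append(bool(v))
    total = int(sum(clean))
    if total <= 1:
        cat = "high_likelihood_limited"
    elif total <= 3:
        cat = "possibility_limited"
    else:
        cat = "adequate"
    return NVSResult(total, cat)


def convergent_correlation(scores_a, scores_b) -> tuple[float, float]:
    """Pearson r and two-sided p between two summed scores, pairwise-complete."""
    a = pd.Series(np.asarray(scores_a, dtype=float))
    b = pd.Series(np.asarray(scores_b, dtype=float))
    use = a.notna() & b.notna()
    if use.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    r, p = stats.pearsonr(a[use], b[use])
    return float(r), float(p)


def auc(outcome, score) -> float:
    """Area under the ROC curve, Mann-Whitney formulation with tie correction.

    Equals P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg).
    """
    outcome = np.asarray(outcome).astype(int)
    score = np.asarray(score, dtype=float)
    pos = score[outcome == 1]
    neg = score[outcome == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("outcome must contain both classes")
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def auc_to_cohens_d(value: float, table_snap: bool = False) -> float:
    """Equal-variance binormal conversion d = sqrt(2) * Phi^{-1}(AUC).

    ``table_snap`` rounds to 2 decimals, mimicking lookup in the published
    conversion tables.
    """
    if not 0 < value < 1:
        raise ValueError("AUC must be strictly between 0 and 1")
    d = math.sqrt(2.0) * float(ndtri(value))
    return round(d, 2) if table_snap else d


def criterion_logistic(
    outcome,
    hl_score,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "behavior",
) -> CriterionResult:
    """Logistic regression of a binary behavior on the assessment score.

    Covariates enter additively; the reported OR (with Wald 95% CI) is per
    one raw-score point.  Complete separation is detected and flagged rather
    than silently reported.
    """
    import statsmodels.api as sm

    y = pd.Series(np.asarray(outcome).astype(float)).reset_index(drop=True)
    x = pd.DataFrame({"hl_score": np.asarray(hl_score, dtype=float)})
    if covariates is not None:
        cov = covariates.reset_index(drop=True).apply(pd.to_numeric, errors="raise")
        x = pd.concat([x, cov], axis=1)
    use = y.notna() & x.notna().all(axis=1)
    y, x = y[use], x[use]
    if y.nunique() < 2:
        raise ValueError("outcome must contain both classes")
    design = sm.add_constant(x, has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = sm.Logit(y, design).fit(disp=0)
    if any("Separation" in w.category.__name__ for w in caught):
        separation = True
    converged = bool(fit.mle_retvals.get("converged", True))
    beta = float(fit.params["hl_score"])
    if abs(beta) > 15:
        separation = True
    lo, hi = fit.conf_int().loc["hl_score"]
    a = auc(y.to_numpy().astype(int), x["hl_score"].to_numpy())
    return CriterionResult(
        outcome_name=outcome_name,
        odds_ratio=_safe_exp(beta),
        ci_low=_safe_exp(float(lo)),
        ci_high=_safe_exp(float(hi)),
        auc=a,
        cohens_d=auc_to_cohens_d(min(max(a, 1e-9), 1 - 1e-9)),
        n=int(use.sum()),
        converged=converged,
        separation_detected=separation,
    )


def _safe_exp(x: float) -> float:
    if math.isnan(x):
        return math.nan
    return math.exp(x) if x < 700 else math.inf


def crosstab_categories(cat_a: pd.Series, cat_b: pd.Series) -> pd.DataFrame:
    """Convenience crosstab of two categorizations (no inferential claims)."""
    return pd.crosstab(cat_a, cat_b)
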