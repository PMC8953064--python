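"""Uniform differential item functioning across two-level person groupings.

Anchored two-stage design: persons are measured once from the pooled
calibration; then, holding those measures (and any partial-credit threshold
spacing) fixed, each item's overall difficulty is re-estimated separately
within each group.  Uniform DIF is the contrast between the two group
difficulties; significance is a Welch-style t on the two anchored estimates
with Satterthwaite degrees of freedom.  An item is flagged only when the
shift is both substantial (|contrast| >= 0.5 logits) and significant
(p < 0.01) -- the joint rule controls the many tests performed.

A Mantel-Haenszel common-odds-ratio cross-check is provided for dichotomous
items (stratified by raw total score); it is a corroborating statistic, not
the flag source.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import DICHOTOMOUS, ResponseMatrix
from .model import EstimationSettings, RaschCalibration, _steps_of, estimate_jmle

__all__ = [
    "DIFResult",
    "dif_flag",
    "uniform_dif",
    "dif_screen",
    "mantel_haenszel_dif",
    "make_age_bands",
]

DIF_CONTRAST_FLOOR = 0.5  # logits
DIF_ALPHA = 0.01
MIN_GROUP_N = 100


def dif_flag(contrast: float, p_value: float) -> bool:
    """Joint flag rule: substantial (|contrast| >= 0.5 logits) AND significant (p < 0.01)."""
    return bool(abs(contrast) >= DIF_CONTRAST_FLOOR and p_value < DIF_ALPHA)


@dataclass
class DIFResult:
    item_id: str
    group_a: str
    group_b: str
    difficulty_a: float
    difficulty_b: float
    contrast: float
    joint_se: float
    t_statistic: float
    df: float
    p_value: float
    flagged: bool
    estimable: bool = True


def _anchored_item_difficulty(
    responses: ResponseMatrix,
    calibration: RaschCalibration,
    item_id: str,
    person_ids: list[str],
) -> tuple[float, float, int]:
    """Re-estimate one item's location for a person subset, abilities fixed.

    The item's threshold spacing stays anchored at the pooled values; only a
    uniform shift of all steps is estimated (Newton on the concave profile).
    Returns (difficulty, se, n_responses); NaNs when inestimable.
    """
    j = responses.item_ids.index(item_id)
    pidx = {p: n for n, p in enumerate(responses.person_ids)}
    rows = [pidx[p] for p in person_ids]
    theta = np.array([calibration.person_measure[calibration.person_ids.index(p)] for p in person_ids])
    obs = responses.observed()[rows, j] & np.isfinite(theta)
    x = responses.scores[rows, j][obs].astype(float)
    theta = theta[obs]
    n = int(obs.sum())
    m = responses.item_specs[j].max_score
    if n == 0 or len(np.unique(x)) < 2:
        return math.nan, math.nan, n
    steps0 = _steps_of(calibration, item_id)
    tau = steps0 - steps0.mean()  # anchored spacing
    b = float(steps0.mean())
    cats = np.arange(m + 1, dtype=float)
    jj = np.arange(1, m + 1)
    s_obs = (x[:, None] >= jj[None, :]).astype(float).sum(axis=0)  # counts >= step
    for _ in range(100):
        steps = b + tau
        cum = np.concatenate(([0.0], np.cumsum(steps)))
        expo = theta[:, None] * cats[None, :] - cum[None, :]
        expo -= expo.max(axis=1, keepdims=True)
        p = np.exp(expo)
        p /= p.sum(axis=1, keepdims=True)
        g = np.flip(np.cumsum(np.flip(p[:, 1:], axis=1), axis=1), axis=1)  # P(x>=j)
        grad = g.sum(axis=0).sum() - s_obs.sum()
        info = (g * (1 - g)).sum()
        if info <= 1e-12:
            return math.nan, math.nan, n
        step = np.clip(grad / info, -1.0, 1.0)
        b += step
        if abs(step) < 1e-8:
            break
    # information for the uniform shift is the model score variance sum
    steps = b + tau
    cum = np.concatenate(([0.0], np.cumsum(steps)))
    expo = theta[:, None] * cats[None, :] - cum[None, :]
    expo -= expo.max(axis=1, keepdims=True)
    p = np.exp(expo)
    p /= p.sum(axis=1, keepdims=True)
    e = p @ cats
    w = (p * (cats[None, :] - e[:, None]) ** 2).sum(axis=1)
    se = 1.0 / math.sqrt(max(w.sum(), 1e-12))
    return b, se, n


def uniform_dif(
    responses: ResponseMatrix,
    grouping: pd.Series,
    calibration: RaschCalibration | None = None,
    settings: EstimationSettings | None = None,
) -> list[DIFResult]:
    """Anchored uniform-DIF contrasts for every item across a 2-level grouping.

    ``grouping`` maps person_id -> group label; exactly two labels must be
    present among persons with measures.  Labels are compared in sorted order
    (a, b) and the contrast is difficulty_a - difficulty_b.
    """
    grouping = grouping.dropna()
    if calibration is None:
        calibration = estimate_jmle(responses, settings)
    measured = set(calibration.retained_person_ids)
    grouping = grouping[grouping.index.isin(measured)]
    labels = sorted(grouping.unique())
    if len(labels) != 2:
        raise ValueError(f"grouping must have exactly 2 levels, got {labels}")
    a, b = (str(x) for x in labels)
    ids_a = list(grouping.index[grouping == labels[0]])
    ids_b = list(grouping.index[grouping == labels[1]])
    if not ids_a or not ids_b:
        raise ValueError("both groups must be non-empty")
    for lab, ids in ((a, ids_a), (b, ids_b)):
        if len(ids) < MIN_GROUP_N:
            warnings.warn(
                f"group {lab!r} has {len(ids)} persons (<{MIN_GROUP_N}); DIF of "
                ">=0.5 logits may not be reliably detectable"
            )
    results = []
    for iid in responses.item_ids:
        if iid in calibration.excluded_items:
            continue
        da, sa, na = _anchored_item_difficulty(responses, calibration, iid, ids_a)
        db, sb, nb = _anchored_item_difficulty(responses, calibration, iid, ids_b)
        if math.isnan(da) or math.isnan(db):
            results.append(
                DIFResult(iid, a, b, da, db, math.nan, math.nan, math.nan, math.nan,
                          math.nan, False, estimable=False)
            )
            continue
        contrast = da - db
        joint_se = math.sqrt(sa**2 + sb**2)
        t = contrast / joint_se
        df = (sa**2 + sb**2) ** 2 / (sa**4 / max(na - 1, 1) + sb**4 / max(nb - 1, 1))
        p = float(2 * stats.t.sf(abs(t), df))
        results.append(
            DIFResult(iid, a, b, da, db, contrast, joint_se, t, df, p, dif_flag(contrast, p))
        )
    return results


def dif_results_frame(results: list[DIFResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("item_id")


def make_age_bands(age: pd.Series) -> pd.Series:
    """Band integer ages into the two DIF groups 12-15 and 16-18."""
    age = pd.to_numeric(age, errors="coerce")
    out = pd.Series(pd.NA, index=age.index, dtype=object)
    out[(age >= 12) & (age <= 15)] = "12-15"
    out[(age >= 16) & (age <= 18)] = "16-18"
    return out


def dif_screen(
    responses: ResponseMatrix,
    covariates: pd.DataFrame,
    calibration: RaschCalibration | None = None,
    settings: EstimationSettings | None = None,
    groupings: dict[str, str] | None = None,
) -> dict[str, list[DIFResult]]:
    """Run uniform DIF for gender, age band (12-15 vs 16-18) and ethnicity.

    ``covariates`` is indexed by person id.  ``groupings`` maps analysis name
    -> covariate column (defaults: gender, age, ethnicity).  Columns with a
    single observed level are skipped with a warning; persons with missing
    labels are excluded per grouping; gender/ethnicity columns with more than
    two levels are reduced to their two most frequent.
    """
    groupings = groupings or {"gender": "gender", "age": "age", "ethnicity": "ethnicity"}
    if calibration is None:
        calibration = estimate_jmle(responses, settings)
    out: dict[str, list[DIFResult]] = {}
    for name, col in groupings.items():
        if col not in covariates.columns:
            raise KeyError(f"unknown grouping column {col!r}")
        series = covariates[col]
        if name == "age" or pd.api.types.is_numeric_dtype(series):
            series = make_age_bands(series)
        series = series.dropna()
        levels = series.value_counts()
        if len(levels) < 2:
            warnings.warn(f"grouping {name!r} has no variation; skipped")
            continue
        if len(levels) > 2:
            keep = list(levels.index[:2])
            warnings.warn(f"grouping {name!r} reduced to its two largest levels {keep}")
            series = series[series.isin(keep)]
        out[name] = uniform_dif(responses, series, calibration)
    return out


def mantel_haenszel_dif(
    responses: ResponseMatrix, item_id: str, grouping: pd.Series
) -> dict:
    """Mantel-Haenszel common odds ratio for a dichotomous item.

    Strata are total raw scores on the remaining items.  Returns the pooled
    odds ratio, its log (positive log-OR means the first sorted group found
    the item easier) and the chi-square p-value.  Cross-check statistic only.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    j = responses.item_ids.index(item_id)
    if responses.item_specs[j].family != DICHOTOMOUS:
        raise ValueError("Mantel-Haenszel cross-check applies to dichotomous items")
    grouping = grouping.dropna()
    labels = sorted(grouping.unique())
    if len(labels) != 2:
        raise ValueError("grouping must have exactly 2 levels")
    pidx = {p: n for n, p in enumerate(responses.person_ids)}
    rows = [pidx[p] for p in grouping.index if p in pidx]
    ids = [p for p in grouping.index if p in pidx]
    obs = responses.observed()
    x_item = responses.scores[rows, j]
    ok = obs[rows, j]
    rest = np.where(obs[rows], responses.scores[rows], 0).sum(axis=1) - np.where(ok, x_item, 0)
    in_a = (grouping.loc[ids] == labels[0]).to_numpy()
    tables = []
    for s in np.unique(rest[ok]):
        sel = ok & (rest == s)
        t = np.array(
            [
                [(x_item[sel] == 1)[in_a[sel]].sum(), (x_item[sel] == 0)[in_a[sel]].sum()],
                [(x_item[sel] == 1)[~in_a[sel]].sum(), (x_item[sel] == 0)[~in_a[sel]].sum()],
            ],
            dtype=float,
        )
        if t.sum() > 0:
            tables.append(t)
    st = StratifiedTable(tables)
    orp = float(st.oddsratio_pooled)
    return {
        "item_id": item_id,
        "group_a": str(labels[0]),
        "group_b": str(labels[1]),
        "odds_ratio_mh": orp,
        "log_odds_ratio_mh": math.log(orp) if orp > 0 else math.nan,
        "p_value": float(st.test_null_odds(correction=True).pvalue),
    }
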