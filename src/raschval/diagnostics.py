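"""Residual-based fit statistics and Rasch assumption checks.

Standardized residual ``z = (x - E) / sqrt(W)`` underlies everything here.
Per unit (item column or person row):

* outfit mean-square — unweighted mean of ``z^2``; sensitive to outlying
  responses far from the unit's location;
* infit mean-square — information-weighted ``sum(W z^2) / sum(W)``;
* ZSTD — the Wilson-Hilferty cube-root normalization of a mean-square, which
  is approximately standard normal under model fit;
* point-measure correlation (items) — Pearson r between item scores and
  person measures; negative values indicate reversed polarity.

The three Rasch assumptions are screened as in conventional practice:
unidimensionality by the first eigenvalue of the principal-component
decomposition of the item residual correlations (< 2 items-worth passes),
local independence by the largest absolute pairwise residual correlation
(< 0.50 passes), monotonicity by a strictly ascending test characteristic
curve on a theta grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ResponseMatrix
from .model import RaschCalibration, _cell_moments, _pad_steps, _steps_of, _retained_steps, _tcc

__all__ = [
    "FitReport",
    "DimensionalityReport",
    "standardized_residuals",
    "item_fit",
    "person_fit",
    "point_measure_correlation",
    "residual_pca_first_contrast",
    "local_independence",
    "check_tcc_monotonicity",
    "assess_assumptions",
]


@dataclass
class FitReport:
    """Per-unit fit records; ``unit`` is 'item' or 'person'.

    ``table`` is indexed by id with columns infit_mnsq, outfit_mnsq,
    infit_zstd, outfit_zstd and (items only) pmc.
    """

    unit: str
    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit,
            "records": self.table.reset_index().to_dict(orient="records"),
            "excluded": list(self.excluded),
        }


@dataclass
class DimensionalityReport:
    first_contrast_eigenvalue: float
    unidimensional: bool
    max_abs_residual_correlation: float
    max_residual_correlation: float
    min_residual_correlation: float
    locally_independent: bool
    tcc_monotone: bool | None = None
    rank_deficient: bool = False

    def to_dict(self) -> dict:
        return {
            "first_contrast_eigenvalue": self.first_contrast_eigenvalue,
            "unidimensional": self.unidimensional,
            "max_abs_residual_correlation": self.max_abs_residual_correlation,
            "max_residual_correlation": self.max_residual_correlation,
            "min_residual_correlation": self.min_residual_correlation,
            "locally_independent": self.locally_independent,
            "tcc_monotone": self.tcc_monotone,
            "rank_deficient": self.rank_deficient,
        }


# ---------------------------------------------------------------------------
# cell-level moments aligned to a response matrix
# ---------------------------------------------------------------------------

def _aligned_moments(calibration: RaschCalibration, responses: ResponseMatrix):
    """E, W, C arrays shaped like ``responses`` (NaN where inestimable)."""
    if calibration.item_ids != responses.item_ids or calibration.person_ids != responses.person_ids:
        cal_items = set(calibration.item_ids)
        cal_persons = set(calibration.person_ids)
        if not set(responses.item_ids) <= cal_items or not set(responses.person_ids) <= cal_persons:
            raise ValueError("calibration does not cover the response matrix")
    theta = np.array(
        [calibration.person_measure[calibration.person_ids.index(p)] for p in responses.person_ids]
    )
    steps_list = [_steps_of(calibration, iid) for iid in responses.item_ids]
    steps, _ = _pad_steps(steps_list)
    ok = np.isfinite(theta)
    e = np.full(responses.scores.shape, np.nan)
    w = np.full(responses.scores.shape, np.nan)
    c = np.full(responses.scores.shape, np.nan)
    if ok.any():
        e[ok], w[ok], c[ok] = _cell_moments(theta[ok], steps)
    usable = responses.observed() & np.isfinite(e)
    e[~usable] = np.nan
    w[~usable] = np.nan
    c[~usable] = np.nan
    return e, w, c, theta


def standardized_residuals(
    calibration: RaschCalibration, responses: ResponseMatrix
) -> pd.DataFrame:
    """Persons x items matrix of z = (x - E)/sqrt(W); NaN where missing."""
    e, w, _, _ = _aligned_moments(calibration, responses)
    with np.errstate(invalid="ignore"):
        z = (responses.scores - e) / np.sqrt(w)
    return pd.DataFrame(z, index=responses.person_ids, columns=responses.item_ids)


def _wilson_hilferty(mnsq: float, q2: float) -> float:
    """Cube-root standardization of a mean-square with sampling variance q2."""
    if q2 <= 0 or not np.isfinite(q2):
        return 0.0
    q = np.sqrt(q2)
    return float((mnsq ** (1.0 / 3.0) - 1.0) * (3.0 / q) + q / 3.0)


def _fit_along(
    x: np.ndarray, e: np.ndarray, w: np.ndarray, c: np.ndarray, axis: int
) -> pd.DataFrame:
    """Mean-square fit statistics aggregated along ``axis`` (0=items, 1=persons)."""
    usable = np.isfinite(e)
    z2 = np.where(usable, (x - e) ** 2 / np.where(usable, w, 1.0), 0.0)
    n_use = usable.sum(axis=axis)
    sum_w = np.where(usable, w, 0.0).sum(axis=axis)
    outfit = z2.sum(axis=axis) / np.maximum(n_use, 1)
    infit = np.where(usable, (x - e) ** 2, 0.0).sum(axis=axis) / np.maximum(sum_w, 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        q2_out = (
            np.where(usable, c / np.maximum(w, 1e-12) ** 2, 0.0).sum(axis=axis)
            / np.maximum(n_use, 1) ** 2
            - 1.0 / np.maximum(n_use, 1)
        )
        q2_in = np.where(usable, c - w**2, 0.0).sum(axis=axis) / np.maximum(sum_w, 1e-12) ** 2
    out = pd.DataFrame(
        {
            "infit_mnsq": infit,
            "outfit_mnsq": outfit,
            "infit_zstd": [_wilson_hilferty(m, q) for m, q in zip(infit, q2_in)],
            "outfit_zstd": [_wilson_hilferty(m, q) for m, q in zip(outfit, q2_out)],
            "n_responses": n_use,
        }
    )
    return out


def item_fit(calibration: RaschCalibration, responses: ResponseMatrix) -> FitReport:
    """Infit/outfit mean-squares, ZSTDs and PMC for every estimable item."""
    e, w, c, theta = _aligned_moments(calibration, responses)
    tab = _fit_along(responses.scores.astype(float), e, w, c, axis=0)
    tab.index = pd.Index(responses.item_ids, name="item_id")
    excluded = [iid for iid, n in zip(responses.item_ids, tab["n_responses"]) if n < 2]
    pmc = point_measure_correlation(responses, calibration)
    tab["pmc"] = pmc
    keep = tab["n_responses"] >= 2
    if excluded:
        warnings.warn(f"items with <2 usable responses excluded from fit: {excluded}")
    return FitReport("item", tab[keep].drop(columns="n_responses"), excluded)


def person_fit(calibration: RaschCalibration, responses: ResponseMatrix) -> FitReport:
    """Row-wise mirror of :func:`item_fit` (no PMC).

    Persons without a finite measure (extreme scores) are excluded silently;
    persons with fewer than 2 administered responses draw a warning.
    """
    e, w, c, theta = _aligned_moments(calibration, responses)
    tab = _fit_along(responses.scores.astype(float), e, w, c, axis=1)
    tab.index = pd.Index(responses.person_ids, name="person_id")
    keep = tab["n_responses"] >= 2
    excluded = [pid for pid, k in zip(responses.person_ids, keep) if not k]
    too_few = [
        pid
        for pid, k, nobs in zip(responses.person_ids, keep, responses.observed().sum(axis=1))
        if not k and nobs < 2
    ]
    if too_few:
        warnings.warn(f"persons with <2 usable responses excluded from fit: {too_few}")
    return FitReport("person", tab[keep].drop(columns="n_responses"), excluded)


def point_measure_correlation(
    responses: ResponseMatrix, calibration: RaschCalibration
) -> pd.Series:
    """Pearson correlation of each item's scores with the person measures."""
    theta = np.array(
        [calibration.person_measure[calibration.person_ids.index(p)] for p in responses.person_ids]
    )
    out = {}
    for i, iid in enumerate(responses.item_ids):
        use = responses.observed()[:, i] & np.isfinite(theta)
        xs = responses.scores[use, i].astype(float)
        th = theta[use]
        if use.sum() < 3 or xs.std() == 0 or th.std() == 0:
            out[iid] = np.nan
            if use.sum() >= 3 and xs.std() == 0:
                warnings.warn(f"item {iid} has zero score variance; PMC undefined")
        else:
            out[iid] = float(np.corrcoef(xs, th)[0, 1])
    return pd.Series(out, name="pmc")


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def residual_pca_first_contrast(residuals: pd.DataFrame) -> tuple[float, bool, bool]:
    """First eigenvalue of the item residual correlation matrix.

    Returns (eigenvalue, unidimensional verdict, rank_deficient flag).  The
    eigenvalue is in item units; < 2 items-worth of shared residual variance
    is taken as unidimensional.
    """
    if residuals.shape[1] < 3:
        raise ValueError("residual PCA needs at least 3 items")
    corr = residuals.corr()  # pairwise-complete Pearson
    rank_deficient = bool(corr.isna().any().any())
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    eig = float(np.linalg.eigvalsh(corr.to_numpy()).max())
    return eig, eig < 2.0, rank_deficient


def local_independence(residuals: pd.DataFrame) -> dict:
    """Extreme pairwise residual correlations; independent iff max |r| < 0.50."""
    corr = residuals.corr().to_numpy()
    k = corr.shape[0]
    off = corr[~np.eye(k, dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        raise ValueError("no estimable residual correlations")
    return {
        "max_abs_residual_correlation": float(np.abs(off).max()),
        "max_residual_correlation": float(off.max()),
        "min_residual_correlation": float(off.min()),
        "locally_independent": bool(np.abs(off).max() < 0.50),
    }


def check_tcc_monotonicity(
    calibration: RaschCalibration, grid: np.ndarray | None = None
) -> tuple[bool, pd.DataFrame]:
    """Strictly ascending test characteristic curve on a theta grid."""
    if grid is None:
        grid = np.linspace(-6.0, 6.0, 201)
    steps = _retained_steps(calibration)
    tcc = _tcc(np.asarray(grid, dtype=float), steps)
    curve = pd.DataFrame({"theta": grid, "expected_total": tcc})
    return bool(np.all(np.diff(tcc) > 0)), curve


def assess_assumptions(
    calibration: RaschCalibration, responses: ResponseMatrix
) -> DimensionalityReport:
    """Run all three assumption screens and bundle the verdicts."""
    z = standardized_residuals(calibration, responses)
    eig, unidim, rank_def = residual_pca_first_contrast(z)
    li = local_independence(z)
    mono, _ = check_tcc_monotonicity(calibration)
    return DimensionalityReport(
        first_contrast_eigenvalue=eig,
        unidimensional=unidim,
        max_abs_residual_correlation=li["max_abs_residual_correlation"],
        max_residual_correlation=li["max_residual_correlation"],
        min_residual_correlation=li["min_residual_correlation"],
        locally_independent=li["locally_independent"],
        tcc_monotone=mono,
        rank_deficient=rank_def,
    )
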