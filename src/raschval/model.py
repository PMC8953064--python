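"""Rasch probability machinery and joint maximum likelihood calibration.

Two response models on a common logit scale:

* dichotomous Rasch: ``P(x=1) = exp(theta - b) / (1 + exp(theta - b))``
* Masters partial credit model (PCM): ``P(x=k) \\propto exp(sum_{j<=k} (theta - b - tau_j))``
  with ``tau_0 == 0`` and the item's step thresholds ``tau_1..tau_m`` centred to sum to 0,
  so ``b`` carries the item's overall location.

Persons and items are estimated jointly (JMLE) by alternating damped
one-parameter Newton-Raphson sweeps.  The joint log-likelihood is concave, so
the alternating scheme converges to the joint maximiser; identification is by
centring the mean item difficulty at zero.  Persons (items) with zero or
perfect totals carry no information about their own parameter and are removed
before estimation; measures for extreme raw scores are extrapolated in the
score-to-measure table by adjusting the extreme score by a fraction of a
score point (0.3 by default, the conventional Winsteps-style adjustment).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import PARTIAL_CREDIT, ItemSpec, ResponseMatrix

__all__ = [
    "EstimationSettings",
    "RaschCalibration",
    "dichotomous_prob",
    "pcm_category_probs",
    "expected_score",
    "score_variance",
    "estimate_jmle",
    "score_to_measure_table",
]


class EstimationError(RuntimeError):
    """Raised when a response matrix cannot be calibrated."""


@dataclass(frozen=True)
class EstimationSettings:
    """Knobs of the JMLE iteration.

    convergence_tol: stop when the largest absolute parameter change in a full
        sweep falls below this (logits).
    max_iterations: sweep budget; exceeding it returns converged=False.
    extreme_score_adjustment: fraction of a score point by which extreme raw
        scores are pulled inward when extrapolating their measures.
    bias_correction: optionally shrink centred difficulties by (k-1)/k to
        counter JMLE's known outward bias (off by default).
    """

    convergence_tol: float = 1e-4
    max_iterations: int = 200
    extreme_score_adjustment: float = 0.3
    bias_correction: bool = False
    damping: float = 1.0  # max |update| per Newton step, logits

    def __post_init__(self) -> None:
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if not (0 < self.extreme_score_adjustment < 0.5):
            raise ValueError("extreme_score_adjustment must be in (0, 0.5)")


# ---------------------------------------------------------------------------
# probability primitives
# ---------------------------------------------------------------------------

def dichotomous_prob(theta: float, b: float):
    """P(correct) under the dichotomous Rasch model; elementwise on arrays."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(b))):
        raise ValueError("theta and b must be finite")
    out = 1.0 / (1.0 + np.exp(-(theta - b)))
    return float(out) if out.ndim == 0 else out


def pcm_category_probs(theta: float, b: float, tau) -> np.ndarray:
    """Category probabilities 0..m of a partial-credit item.

    ``tau`` holds the m step thresholds relative to the item location ``b``;
    with m == 1 and tau == [0] this reduces to the dichotomous model.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if tau.size == 0:
        raise ValueError("a partial-credit item needs at least one step threshold")
    if not (math.isfinite(theta) and math.isfinite(b) and np.all(np.isfinite(tau))):
        raise ValueError("theta, b, tau must be finite")
    # cumulative exponent for category k: sum_{j<=k} (theta - b - tau_j)
    expo = np.concatenate(([0.0], np.cumsum(theta - b - tau)))
    expo -= expo.max()
    p = np.exp(expo)
    return p / p.sum()


def _steps_of(calibration: "RaschCalibration", item_id: str) -> np.ndarray:
    """Absolute step difficulties b + tau_j (length m)."""
    i = calibration.item_index(item_id)
    b = calibration.item_difficulty[i]
    tau = calibration.thresholds.get(item_id)
    if tau is None:
        return np.array([b])
    return b + np.asarray(tau, dtype=float)


def _probs_from_steps(theta: float, steps: np.ndarray) -> np.ndarray:
    expo = np.concatenate(([0.0], np.cumsum(theta - steps)))
    expo -= expo.max()
    p = np.exp(expo)
    return p / p.sum()


def expected_score(theta: float, calibration: "RaschCalibration", item_id: str) -> float:
    """Model-expected score E[x] of one item at ability theta."""
    p = _probs_from_steps(theta, _steps_of(calibration, item_id))
    return float(np.dot(np.arange(p.size), p))


def score_variance(theta: float, calibration: "RaschCalibration", item_id: str) -> float:
    """Model variance W = E[x^2] - E[x]^2 of one item at ability theta."""
    p = _probs_from_steps(theta, _steps_of(calibration, item_id))
    k = np.arange(p.size)
    e = float(np.dot(k, p))
    return float(np.dot(k * k, p) - e * e)


# ---------------------------------------------------------------------------
# calibration result
# ---------------------------------------------------------------------------

@dataclass
class RaschCalibration:
    """Estimated item and person parameters on the logit scale.

    Arrays are aligned with ``item_ids`` / ``person_ids``.  Persons or items
    excluded for extreme (zero/perfect) totals keep their ids with NaN
    parameters and are listed in ``excluded_persons`` / ``excluded_items``.
    """

    item_ids: list[str]
    item_specs: list[ItemSpec]
    item_difficulty: np.ndarray
    item_se: np.ndarray
    thresholds: dict[str, np.ndarray]
    threshold_se: dict[str, np.ndarray]
    person_ids: list[str]
    person_measure: np.ndarray
    person_se: np.ndarray
    excluded_persons: list[str]
    excluded_items: list[str]
    converged: bool
    n_iterations: int
    max_residual_change: float
    settings: EstimationSettings = field(default_factory=EstimationSettings)

    def item_index(self, item_id: str) -> int:
        return self.item_ids.index(item_id)

    @property
    def retained_item_ids(self) -> list[str]:
        ex = set(self.excluded_items)
        return [i for i in self.item_ids if i not in ex]

    @property
    def retained_person_ids(self) -> list[str]:
        ex = set(self.excluded_persons)
        return [p for p in self.person_ids if p not in ex]

    def person_measure_of(self, person_id: str) -> float:
        return float(self.person_measure[self.person_ids.index(person_id)])

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item_id": iid,
                    "family": spec.family,
                    "max_score": spec.max_score,
                    "difficulty": _none_if_nan(self.item_difficulty[i]),
                    "se": _none_if_nan(self.item_se[i]),
                    "thresholds": [float(t) for t in self.thresholds.get(iid, [])] or None,
                    "threshold_se": [float(t) for t in self.threshold_se.get(iid, [])] or None,
                }
                for i, (iid, spec) in enumerate(zip(self.item_ids, self.item_specs))
            ],
            "persons": [
                {
                    "person_id": pid,
                    "measure": _none_if_nan(self.person_measure[n]),
                    "se": _none_if_nan(self.person_se[n]),
                }
                for n, pid in enumerate(self.person_ids)
            ],
            "excluded_persons": list(self.excluded_persons),
            "excluded_items": list(self.excluded_items),
            "convergence": {
                "converged": bool(self.converged),
                "n_iterations": int(self.n_iterations),
                "max_residual_change": float(self.max_residual_change),
                "tol": self.settings.convergence_tol,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "RaschCalibration":
        items = d["items"]
        specs = [ItemSpec(r["item_id"], r["family"], r["max_score"]) for r in items]
        thresholds = {
            r["item_id"]: np.asarray(r["thresholds"], dtype=float)
            for r in items
            if r.get("thresholds")
        }
        threshold_se = {
            r["item_id"]: np.asarray(r["threshold_se"], dtype=float)
            for r in items
            if r.get("threshold_se")
        }
        conv = d["convergence"]
        return cls(
            item_ids=[r["item_id"] for r in items],
            item_specs=specs,
            item_difficulty=np.array(
                [np.nan if r["difficulty"] is None else r["difficulty"] for r in items]
            ),
            item_se=np.array([np.nan if r["se"] is None else r["se"] for r in items]),
            thresholds=thresholds,
            threshold_se=threshold_se,
            person_ids=[r["person_id"] for r in d["persons"]],
            person_measure=np.array(
                [np.nan if r["measure"] is None else r["measure"] for r in d["persons"]]
            ),
            person_se=np.array(
                [np.nan if r["se"] is None else r["se"] for r in d["persons"]]
            ),
            excluded_persons=list(d["excluded_persons"]),
            excluded_items=list(d["excluded_items"]),
            converged=conv["converged"],
            n_iterations=conv["n_iterations"],
            max_residual_change=conv["max_residual_change"],
        )

    @classmethod
    def read_json(cls, path) -> "RaschCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _none_if_nan(x: float):
    x = float(x)
    return None if math.isnan(x) else x


# ---------------------------------------------------------------------------
# vectorized PCM engine used by the estimator and diagnostics
# ---------------------------------------------------------------------------

def _pad_steps(steps_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-item step arrays into (k, m_max) with +inf padding."""
    m_max = max(len(s) for s in steps_list)
    steps = np.full((len(steps_list), m_max), np.inf)
    for i, s in enumerate(steps_list):
        steps[i, : len(s)] = s
    m = np.array([len(s) for s in steps_list])
    return steps, m


def _cell_probs(theta: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Category probabilities, shape (n, k, m_max + 1).

    ``steps`` is (k, m_max) absolute step difficulties padded with +inf; the
    padding sends out-of-range categories to probability zero.
    """
    n = theta.shape[0]
    k, m_max = steps.shape
    # exponent[n,i,c] = c*theta_n - cumsum(steps_i)[c]  (0 for c=0)
    cum = np.concatenate([np.zeros((k, 1)), np.cumsum(steps, axis=1)], axis=1)  # (k, m+1)
    cats = np.arange(m_max + 1)
    expo = theta[:, None, None] * cats[None, None, :] - cum[None, :, :]
    expo = np.where(np.isfinite(expo), expo, -np.inf)
    expo -= expo.max(axis=2, keepdims=True)
    with np.errstate(under="ignore"):
        p = np.exp(expo)
    return p / p.sum(axis=2, keepdims=True)


def _cell_moments(theta: np.ndarray, steps: np.ndarray):
    """Per-cell expected score E, variance W and 4th central moment C."""
    p = _cell_probs(theta, steps)
    cats = np.arange(p.shape[2], dtype=float)
    e = p @ cats
    dev = cats[None, None, :] - e[:, :, None]
    w = np.einsum("nic,nic->ni", p, dev**2)
    c = np.einsum("nic,nic->ni", p, dev**4)
    return e, w, c


# ---------------------------------------------------------------------------
# JMLE
# ---------------------------------------------------------------------------

def _trim_extremes(responses: ResponseMatrix):
    """Iteratively drop persons/items whose totals carry no information."""
    rm = responses
    dropped_persons: list[str] = []
    dropped_items: list[str] = []
    while True:
        obs = rm.observed()
        totals = rm.person_totals()
        maxima = rm.person_max_totals()
        n_obs = obs.sum(axis=1)
        bad_p = (totals <= 0) | (totals >= maxima) | (n_obs < 2)
        it_tot = rm.item_totals()
        it_obs = obs.sum(axis=0)
        it_max = it_obs * rm.max_scores
        # an item also needs >= 2 distinct observed scores
        distinct = np.array(
            [
                len(np.unique(rm.scores[obs[:, i], i])) if it_obs[i] else 0
                for i in range(rm.n_items)
            ]
        )
        bad_i = (it_tot <= 0) | (it_tot >= it_max) | (distinct < 2)
        if not bad_p.any() and not bad_i.any():
            return rm, dropped_persons, dropped_items
        if bad_p.sum() >= rm.n_persons - 1 or bad_i.sum() >= rm.n_items - 1:
            raise EstimationError("all (or all but one) rows/columns are extreme")
        dropped_persons += [p for p, b in zip(rm.person_ids, bad_p) if b]
        dropped_items += [s.item_id for s, b in zip(rm.item_specs, bad_i) if b]
        rm = ResponseMatrix(
            [p for p, b in zip(rm.person_ids, bad_p) if not b],
            [s for s, b in zip(rm.item_specs, bad_i) if not b],
            rm.scores[~bad_p][:, ~bad_i],
            rm.missing_mask[~bad_p][:, ~bad_i],
        )


def estimate_jmle(
    responses: ResponseMatrix, settings: EstimationSettings | None = None
) -> RaschCalibration:
    """Joint maximum likelihood calibration of persons and items.

    Alternates damped Newton sweeps over person measures and item step
    difficulties until the largest parameter change falls below the tolerance.
    Identification: mean item difficulty fixed at 0 (the person scale shifts
    with it); each partial-credit item's thresholds are centred around its
    location.  Standard errors are inverse square roots of the corresponding
    information sums.
    """
    settings = settings or EstimationSettings()
    core, dropped_p, dropped_i = _trim_extremes(responses)

    obs = core.observed()
    x = np.where(obs, core.scores, 0).astype(float)
    n, k = core.scores.shape
    maxima = core.max_scores

    # initial values from logits of relative totals
    pt = core.person_totals() / core.person_max_totals()
    theta = np.log(pt / (1 - pt))
    it = core.item_totals() / (obs.sum(axis=0) * maxima)
    b0 = np.log((1 - it) / it)
    steps_list = [np.full(m, b) for m, b in zip(maxima, b0)]
    steps, m_per_item = _pad_steps(steps_list)
    step_valid = np.isfinite(steps)

    damp = settings.damping
    max_change = np.inf
    it_count = 0
    for it_count in range(1, settings.max_iterations + 1):
        max_change = 0.0
        # person sweep
        e, w, _ = _cell_moments(theta, steps)
        num = ((x - e) * obs).sum(axis=1)
        den = (w * obs).sum(axis=1)
        d_theta = np.clip(num / np.maximum(den, 1e-10), -damp, damp)
        theta = theta + d_theta
        max_change = max(max_change, float(np.abs(d_theta).max()))

        # item sweep: one Newton step per step difficulty
        p = _cell_probs(theta, steps)
        m_max = steps.shape[1]
        # G[n,i,j] = P(x_ni >= j+1); observed indicator S[n,i,j] = 1{x_ni >= j+1}
        g = np.flip(np.cumsum(np.flip(p[:, :, 1:], axis=2), axis=2), axis=2)
        s_obs = (x[:, :, None] >= np.arange(1, m_max + 1)[None, None, :]).astype(float)
        grad = ((g - s_obs) * obs[:, :, None]).sum(axis=0)  # dL/d step (ascent dir = -grad)
        info = (g * (1 - g) * obs[:, :, None]).sum(axis=0)
        d_step = np.clip(grad / np.maximum(info, 1e-10), -damp, damp)
        d_step = np.where(step_valid, d_step, 0.0)
        steps = steps + d_step
        max_change = max(max_change, float(np.abs(d_step).max()))

        # recenter: mean item difficulty 0 (shift persons identically)
        b = np.array([steps[i, : m_per_item[i]].mean() for i in range(k)])
        shift = b.mean()
        steps = np.where(step_valid, steps - shift, steps)
        theta = theta - shift

        if max_change < settings.convergence_tol:
            break
    converged = max_change < settings.convergence_tol

    b = np.array([steps[i, : m_per_item[i]].mean() for i in range(k)])
    if settings.bias_correction and k > 1:
        b_corr = b * (k - 1) / k
        steps = np.where(step_valid, steps + (b_corr - b)[:, None], steps)
        b = b_corr

    # standard errors
    e, w, _ = _cell_moments(theta, steps)
    person_se_core = 1.0 / np.sqrt(np.maximum((w * obs).sum(axis=1), 1e-12))
    item_se_core = 1.0 / np.sqrt(np.maximum((w * obs).sum(axis=0), 1e-12))
    p = _cell_probs(theta, steps)
    g = np.flip(np.cumsum(np.flip(p[:, :, 1:], axis=2), axis=2), axis=2)
    step_info = (g * (1 - g) * obs[:, :, None]).sum(axis=0)
    step_se = np.where(step_valid, 1.0 / np.sqrt(np.maximum(step_info, 1e-12)), np.nan)

    # assemble full-size result aligned to the input ids
    all_pids = list(responses.person_ids)
    all_specs = list(responses.item_specs)
    all_iids = [s.item_id for s in all_specs]
    pm = np.full(len(all_pids), np.nan)
    ps = np.full(len(all_pids), np.nan)
    core_p_index = {pid: j for j, pid in enumerate(core.person_ids)}
    for j, pid in enumerate(all_pids):
        if pid in core_p_index:
            pm[j] = theta[core_p_index[pid]]
            ps[j] = person_se_core[core_p_index[pid]]
    bd = np.full(len(all_iids), np.nan)
    bs = np.full(len(all_iids), np.nan)
    thresholds: dict[str, np.ndarray] = {}
    threshold_se: dict[str, np.ndarray] = {}
    core_i_index = {iid: j for j, iid in enumerate(core.item_ids)}
    for j, (iid, spec) in enumerate(zip(all_iids, all_specs)):
        if iid in core_i_index:
            i = core_i_index[iid]
            bd[j] = b[i]
            bs[j] = item_se_core[i]
            if spec.family == PARTIAL_CREDIT:
                tau = steps[i, : m_per_item[i]] - b[i]
                thresholds[iid] = tau
                threshold_se[iid] = step_se[i, : m_per_item[i]]

    return RaschCalibration(
        item_ids=all_iids,
        item_specs=all_specs,
        item_difficulty=bd,
        item_se=bs,
        thresholds=thresholds,
        threshold_se=threshold_se,
        person_ids=all_pids,
        person_measure=pm,
        person_se=ps,
        excluded_persons=dropped_p,
        excluded_items=dropped_i,
        converged=converged,
        n_iterations=it_count,
        max_residual_change=float(max_change),
        settings=settings,
    )


# ---------------------------------------------------------------------------
# score-to-measure table
# ---------------------------------------------------------------------------

def _retained_steps(calibration: RaschCalibration) -> np.ndarray:
    steps_list = [
        _steps_of(calibration, iid) for iid in calibration.retained_item_ids
    ]
    steps, _ = _pad_steps(steps_list)
    return steps


def _tcc(theta: np.ndarray, steps: np.ndarray) -> np.ndarray:
    e, _, _ = _cell_moments(np.atleast_1d(theta), steps)
    return e.sum(axis=1)


def score_to_measure_table(
    calibration: RaschCalibration, adjustment: float | None = None
):
    """Measure and SE for every attainable raw score on the retained items.

    Non-extreme scores solve TCC(theta) = raw score; the extreme scores 0 and
    max are pulled inward by ``adjustment`` score points before solving, which
    extrapolates finite measures for them.  SE(theta) = 1/sqrt(test
    information at theta).
    """
    if adjustment is None:
        adjustment = calibration.settings.extreme_score_adjustment
    steps = _retained_steps(calibration)
    r_max = int(sum(np.isfinite(steps).sum(axis=1)))
    rows = []
    for raw in range(r_max + 1):
        target = float(raw)
        if raw == 0:
            target = adjustment
        elif raw == r_max:
            target = r_max - adjustment

        def f(th):
            return float(_tcc(np.array([th]), steps)[0]) - target

        theta = brentq(f, -40, 40, xtol=1e-10)
        _, w, _ = _cell_moments(np.array([theta]), steps)
        info = float(w.sum())
        rows.append({"raw_score": raw, "measure": theta, "se": 1.0 / math.sqrt(info)})
    table = pd.DataFrame(rows)
    if not np.all(np.diff(table["measure"]) > 0):  # pragma: no cover - model guarantee
        warnings.warn("score-to-measure table is not strictly increasing")
    return table
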