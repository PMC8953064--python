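"""Synthetic study-like cohorts with known ground truth.

Emulates the kind of sample the pipeline was designed for: ~355 adolescents
answering a 23-item battery of three health-literacy assessments — 6
dichotomous functional (FHL) items, 10 dichotomous interactive (IHL) items,
and 7 critical (CHL) items of which 2 are dichotomous and 5 partial-credit
(score ceilings 2,2,2,3,3, so the CHL raw range is 0–14 and the composite
0–30).  Default true difficulties span roughly −2.05…2.91 logits and person
ability is negatively skewed (a health-class sample enriched for interested
students), modelled as a two-component normal mixture.

Optional injections with recorded truth: uniform DIF shifts on chosen items,
noise items (responses independent of ability), reverse-keyed items,
misfitting persons (random responders or careless tails), missing cells,
two criterion behaviors generated from a logistic link on the summed score,
and a parallel 6-item NVS-like convergent measure driven by the same ability
plus independent noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import PARTIAL_CREDIT, ItemSpec, ResponseMatrix

__all__ = [
    "TrueItem",
    "AbilityDist",
    "DifEffect",
    "BehaviorLink",
    "CohortConfig",
    "CohortData",
    "default_item_bank",
    "generate_cohort",
    "generate_criterion_behaviors",
    "generate_convergent_measure",
    "true_cell_probs",
]


@dataclass(frozen=True)
class TrueItem:
    spec: ItemSpec
    difficulty: float
    thresholds: tuple[float, ...] = ()  # centred step thresholds, PCM only

    def __post_init__(self) -> None:
        if self.spec.family == PARTIAL_CREDIT and len(self.thresholds) != self.spec.max_score:
            raise ValueError("PCM item needs max_score thresholds")


@dataclass(frozen=True)
class AbilityDist:
    """Two-component normal mixture; the default is negatively skewed."""

    weights: tuple[float, float] = (0.9, 0.1)
    means: tuple[float, float] = (1.9, 0.5)
    sds: tuple[float, float] = (0.95, 2.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.random(n) < self.weights[0]
        out = np.where(
            comp,
            rng.normal(self.means[0], self.sds[0], n),
            rng.normal(self.means[1], self.sds[1], n),
        )
        return out


@dataclass(frozen=True)
class DifEffect:
    item_id: str
    column: str  # covariate column carrying the grouping
    level: str  # persons at this level get the shifted difficulty
    shift: float  # logits added to the item difficulty for that level


@dataclass(frozen=True)
class BehaviorLink:
    name: str
    slope: float  # log-odds per raw-score point
    intercept: float


def default_item_bank() -> list[TrueItem]:
    """23-item bank on the −2.05…2.91 logit span of a realistic battery."""
    fhl = [0.98, 0.73, 0.62, -0.12, -0.94, -1.28]
    ihl = [2.91, 2.02, 0.64, 0.35, -0.02, -0.26, -0.50, -1.21, -1.87, -2.05]
    chl_dich = [0.81, 0.47]
    chl_poly = [
        (0.36, 2, (-0.5, 0.5)),
        (-0.04, 2, (-0.5, 0.5)),
        (-0.05, 2, (-0.5, 0.5)),
        (-0.65, 3, (-0.7, 0.0, 0.7)),
        (-0.89, 3, (-0.7, 0.0, 0.7)),
    ]
    bank = [
        TrueItem(ItemSpec(f"FHL{i+1:02d}"), b) for i, b in enumerate(fhl)
    ] + [
        TrueItem(ItemSpec(f"IHL{i+1:02d}"), b) for i, b in enumerate(ihl)
    ] + [
        TrueItem(ItemSpec(f"CHL{i+1:02d}"), b) for i, b in enumerate(chl_dich)
    ] + [
        TrueItem(ItemSpec(f"CHL{i+3:02d}", PARTIAL_CREDIT, m), b, tau)
        for i, (b, m, tau) in enumerate(chl_poly)
    ]
    return bank


DEFAULT_NVS_DIFFICULTIES = (1.3, 2.0, 2.3, 2.6, 3.0, 3.6)
DEFAULT_BEHAVIORS = (
    BehaviorLink("questions_online_info", slope=0.14, intercept=-2.5),
    BehaviorLink("reads_medicine_instructions", slope=0.14, intercept=-2.0),
)
# empirical age mix of the motivating sample (12-14 pooled, split evenly)
AGE_PROBS = {12: 0.0623, 13: 0.0623, 14: 0.0623, 15: 0.1639, 16: 0.2066, 17: 0.3311, 18: 0.1115}


@dataclass(frozen=True)
class CohortConfig:
    seed: int
    n_persons: int = 355
    item_bank: tuple[TrueItem, ...] = field(default_factory=lambda: tuple(default_item_bank()))
    ability: AbilityDist = field(default_factory=AbilityDist)
    dif_effects: tuple[DifEffect, ...] = ()
    n_misfit_persons: int = 0
    misfit_mechanism: str = "random_responder"  # or "careless_tail"
    noise_items: tuple[str, ...] = ()  # responses independent of ability
    noise_rate: float = 0.25  # flat success rate of dichotomous noise items
    reversed_items: tuple[str, ...] = ()  # negatively discriminating
    reversed_slope: float = -0.5
    behaviors: tuple[BehaviorLink, ...] = DEFAULT_BEHAVIORS
    convergent_noise_sd: float = 1.0
    nvs_difficulties: tuple[float, ...] = DEFAULT_NVS_DIFFICULTIES
    missing_rate: float = 0.0
    girl_fraction: float = 0.548
    hispanic_fraction: float = 0.505

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.misfit_mechanism not in ("random_responder", "careless_tail"):
            raise ValueError("unknown misfit mechanism")
        if not all(np.isfinite(e.shift) for e in self.dif_effects):
            raise ValueError("DIF shifts must be finite")


@dataclass
class CohortData:
    responses: ResponseMatrix
    covariates: pd.DataFrame
    truth: dict


def _draw_pcm(theta: np.ndarray, steps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one response per person from cumulative-step category probabilities."""
    expo = np.concatenate(
        [np.zeros((theta.size, 1)), np.cumsum(theta[:, None] - steps[None, :], axis=1)], axis=1
    )
    expo -= expo.max(axis=1, keepdims=True)
    p = np.exp(expo)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(theta.size)
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def generate_cohort(config: CohortConfig) -> CohortData:
    """Draw a full cohort (responses, covariates, truth record) from the config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    person_ids = [f"P{i+1:04d}" for i in range(n)]
    theta = config.ability.sample(n, rng)

    gender = np.where(rng.random(n) < config.girl_fraction, "female", "male")
    age = rng.choice(list(AGE_PROBS), size=n, p=np.array(list(AGE_PROBS.values())) / sum(AGE_PROBS.values()))
    ethnicity = np.where(rng.random(n) < config.hispanic_fraction, "hispanic", "non-hispanic")
    cov = pd.DataFrame(
        {"gender": gender, "age": age.astype(int), "ethnicity": ethnicity},
        index=pd.Index(person_ids, name="person_id"),
    )

    mean_b = float(np.mean([it.difficulty for it in config.item_bank]))
    if any(abs(it.difficulty - np.mean(theta)) > 6 for it in config.item_bank):
        warnings.warn("item difficulties far from the ability mass; extreme columns likely")

    specs = [it.spec for it in config.item_bank]
    scores = np.zeros((n, len(specs)), dtype=int)
    for j, item in enumerate(config.item_bank):
        b_eff = np.full(n, item.difficulty)
        for eff in config.dif_effects:
            if eff.item_id == item.spec.item_id:
                b_eff = b_eff + np.where(cov[eff.column].astype(str) == eff.level, eff.shift, 0.0)
        iid = item.spec.item_id
        if iid in config.noise_items:
            if item.spec.max_score == 1:
                # flat guessing-style success rate, independent of ability
                scores[:, j] = (rng.random(n) < config.noise_rate).astype(int)
            else:
                scores[:, j] = rng.integers(0, item.spec.max_score + 1, size=n)
            continue
        if iid in config.reversed_items:
            # negatively discriminating dichotomous response law
            p1 = 1.0 / (1.0 + np.exp(-config.reversed_slope * (theta - b_eff)))
            scores[:, j] = (rng.random(n) < p1).astype(int)
            continue
        tau = np.asarray(item.thresholds) if item.thresholds else np.zeros(1)
        for vals in np.unique(b_eff):
            sel = b_eff == vals
            scores[sel, j] = _draw_pcm(theta[sel], vals + tau, rng)

    misfit_ids: list[str] = []
    if config.n_misfit_persons:
        pick = rng.choice(n, size=config.n_misfit_persons, replace=False)
        misfit_ids = [person_ids[i] for i in sorted(pick)]
        for i in pick:
            if config.misfit_mechanism == "random_responder":
                cols = range(len(specs))
            else:  # careless_tail: second half of the battery answered at random
                cols = range(len(specs) // 2, len(specs))
            for j in cols:
                scores[i, j] = rng.integers(0, specs[j].max_score + 1)

    missing = np.zeros(scores.shape, dtype=bool)
    if config.missing_rate > 0:
        missing = rng.random(scores.shape) < config.missing_rate

    responses = ResponseMatrix(person_ids, specs, scores, missing)

    totals = responses.person_totals().astype(float)
    for link in config.behaviors:
        cov[link.name] = generate_criterion_behaviors(totals, link, rng)
    cov["nvs_score"] = generate_convergent_measure(
        theta, config.convergent_noise_sd, config.nvs_difficulties, rng
    )

    truth = {
        "theta": theta,
        "difficulties": {it.spec.item_id: it.difficulty for it in config.item_bank},
        "thresholds": {
            it.spec.item_id: list(it.thresholds)
            for it in config.item_bank
            if it.thresholds
        },
        "mean_difficulty": mean_b,
        "dif_effects": [e.__dict__ for e in config.dif_effects],
        "noise_items": list(config.noise_items),
        "reversed_items": list(config.reversed_items),
        "reversed_slope": config.reversed_slope,
        "misfit_person_ids": misfit_ids,
        "behavior_links": [l.__dict__ for l in config.behaviors],
        "nvs_difficulties": list(config.nvs_difficulties),
        "convergent_noise_sd": config.convergent_noise_sd,
        "seed": config.seed,
    }
    return CohortData(responses, cov, truth)


def generate_criterion_behaviors(
    total_scores: np.ndarray, link: BehaviorLink, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli behavior draws from logistic(intercept + slope * summed score)."""
    from scipy.special import expit

    eta = link.intercept + link.slope * np.asarray(total_scores, dtype=float)
    p = expit(eta)
    return (rng.random(p.size) < p).astype(int)


def generate_convergent_measure(
    theta: np.ndarray,
    noise_sd: float,
    difficulties=DEFAULT_NVS_DIFFICULTIES,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Summed 0-6 scores on an NVS-like screener sharing the cohort's ability.

    The screener's effective ability is theta plus independent normal noise,
    so the correlation with the main battery is tunable through ``noise_sd``.
    """
    rng = rng or np.random.default_rng(0)
    theta = np.asarray(theta, dtype=float)
    theta_nvs = theta + rng.normal(0.0, noise_sd, theta.size)
    total = np.zeros(theta.size, dtype=int)
    for b in difficulties:
        p = 1.0 / (1.0 + np.exp(-(theta_nvs - b)))
        total += (rng.random(theta.size) < p).astype(int)
    if np.var(total) < 0.05:
        warnings.warn("convergent measure has near-zero variance (floor/ceiling effect)")
    return total


def true_cell_probs(truth: dict, person_index: int, item_id: str, covariates=None) -> np.ndarray:
    """Recompute the generating category probabilities for one cell.

    Closure property of the truth record: everything needed to rebuild the
    response law is stored.  ``covariates`` is only needed when DIF effects
    were injected.
    """
    theta = float(truth["theta"][person_index])
    b = float(truth["difficulties"][item_id])
    for eff in truth["dif_effects"]:
        if eff["item_id"] == item_id:
            if covariates is None:
                raise ValueError("covariates required to resolve DIF-shifted probabilities")
            if str(covariates.iloc[person_index][eff["column"]]) == eff["level"]:
                b += eff["shift"]
    tau = np.asarray(truth["thresholds"].get(item_id, [0.0]))
    expo = np.concatenate(([0.0], np.cumsum(theta - (b + tau))))
    expo -= expo.max()
    p = np.exp(expo)
    return p / p.sum()
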