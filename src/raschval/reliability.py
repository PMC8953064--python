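"""Separation reliability, KR-20, and Wright strata / cutoff scores.

Wright's sample-independent reliability replaces person-sample reliability
for skewed samples: once the test is calibrated, the score-to-measure table
alone determines how many statistically distinct performance levels (strata)
the raw scores can separate, and the reliability is ``n^2 / (1 + n^2)`` for
``n`` levels.  The strata walk inflates the raw-score SEs by 10%, anchors at
the lowest attainable score, and opens a new level at the first score whose
measure clears the anchor by at least twice the joint (inflated) SE; the
anchor then resets to that score.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd

from .model import RaschCalibration

__all__ = [
    "StrataReport",
    "item_separation_reliability",
    "person_separation_reliability",
    "kr20",
    "wright_strata",
    "sample_independent_reliability",
    "categorize",
    "published_cutoffs",
    "PUBLISHED_CUTOFF_NAMES",
]

SE_INFLATION = 1.10


@dataclass
class StrataReport:
    score_table: pd.DataFrame  # raw_score, measure, se, inflated_se, level
    n_levels: int
    level_cutoffs: list[tuple[str, int, int]]  # (label, min raw, max raw)
    sample_independent_reliability: float
    se_inflation_factor: float
    anchors: list[int]  # raw scores at which each level opened

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "level_cutoffs": [list(c) for c in self.level_cutoffs],
            "sample_independent_reliability": self.sample_independent_reliability,
            "se_inflation_factor": self.se_inflation_factor,
            "anchors": self.anchors,
            "score_table": self.score_table.to_dict(orient="records"),
        }


def item_separation_reliability(calibration: RaschCalibration) -> float:
    """Share of item-difficulty variance not attributable to estimation error.

    (observed variance - mean squared SE) / observed variance, floored at 0;
    population-variance convention.
    """
    keep = np.isfinite(calibration.item_difficulty) & np.isfinite(calibration.item_se)
    b = calibration.item_difficulty[keep]
    se = calibration.item_se[keep]
    if b.size < 2:
        raise ValueError("need at least 2 calibrated items")
    var = float(np.var(b))
    if var == 0:
        warnings.warn("zero variance in item difficulties; separation reliability is 0")
        return 0.0
    return max(0.0, (var - float(np.mean(se**2))) / var)


def person_separation_reliability(calibration: RaschCalibration) -> float:
    """Sample-dependent analogue over person measures (secondary statistic)."""
    keep = np.isfinite(calibration.person_measure) & np.isfinite(calibration.person_se)
    th = calibration.person_measure[keep]
    se = calibration.person_se[keep]
    if th.size < 2:
        raise ValueError("need at least 2 measured persons")
    var = float(np.var(th))
    if var == 0:
        return 0.0
    return max(0.0, (var - float(np.mean(se**2))) / var)


def kr20(responses) -> float:
    """KR-20 / coefficient alpha internal consistency on complete cases.

    ``(k/(k-1)) * (1 - sum(item variance) / variance(total))`` with
    population variances; for dichotomous items the item variance is p*q, so
    this is exactly the Kuder-Richardson formula.
    """
    df = responses.to_dataframe().dropna()
    if df.shape[1] < 2:
        raise ValueError("KR-20 needs at least 2 items")
    if df.shape[0] < 2:
        raise ValueError("KR-20 needs at least 2 complete-case persons")
    k = df.shape[1]
    total_var = float(np.var(df.sum(axis=1)))
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_var = float(np.var(df, axis=0).sum())
    return (k / (k - 1)) * (1.0 - item_var / total_var)


def sample_independent_reliability(n_levels: int) -> float:
    """Wright's statistic: n^2 / (1 + n^2) for n distinguishable levels."""
    if n_levels < 1:
        raise ValueError("number of levels must be a positive integer")
    return n_levels**2 / (1 + n_levels**2)


def wright_strata(
    score_table: pd.DataFrame,
    inflation: float = SE_INFLATION,
    labels: list[str] | None = None,
) -> StrataReport:
    """Walk the score-to-measure table into statistically distinct levels.

    A new level opens at the first raw score whose measure exceeds the level
    anchor's measure by at least ``2 * sqrt(se_infl(anchor)^2 + se_infl(s)^2)``
    (both endpoint SEs inflated); the anchor resets to that score.  Cutoffs
    are reported as inclusive raw-score ranges.
    """
    tab = score_table.sort_values("raw_score").reset_index(drop=True).copy()
    if not np.all(np.diff(tab["measure"]) >= 0):
        raise ValueError("score table measures must be monotone non-decreasing")
    if not np.all(tab["se"] > 0):
        raise ValueError("score table SEs must be positive")
    tab["inflated_se"] = tab["se"] * inflation
    anchors = [int(tab.loc[0, "raw_score"])]
    level_idx = [0]
    a = 0
    for i in range(1, len(tab)):
        gap = tab.loc[i, "measure"] - tab.loc[a, "measure"]
        joint = 2.0 * math.sqrt(
            tab.loc[a, "inflated_se"] ** 2 + tab.loc[i, "inflated_se"] ** 2
        )
        if gap >= joint:
            a = i
            anchors.append(int(tab.loc[i, "raw_score"]))
        level_idx.append(len(anchors) - 1)
    n_levels = len(anchors)
    if labels is None:
        labels = _default_level_labels(n_levels)
    tab["level"] = [labels[j] for j in level_idx]
    cutoffs = []
    for j in range(n_levels):
        scores = tab.loc[[k == j for k in level_idx], "raw_score"]
        cutoffs.append((labels[j], int(scores.min()), int(scores.max())))
    return StrataReport(
        score_table=tab,
        n_levels=n_levels,
        level_cutoffs=cutoffs,
        sample_independent_reliability=sample_independent_reliability(n_levels),
        se_inflation_factor=inflation,
        anchors=anchors,
    )


def _default_level_labels(n: int) -> list[str]:
    named = {
        1: ["Emerging"],
        2: ["Emerging", "Expanding"],
        3: ["Emerging", "Expanding", "Bridging"],
        4: ["Emerging", "Expanding", "Lower Bridging", "Upper Bridging"],
    }
    return named.get(n, [f"Level {i + 1}" for i in range(n)])


# ---------------------------------------------------------------------------
# published cutoff presets
# ---------------------------------------------------------------------------

def _load_presets() -> dict:
    text = (
        importlib_resources.files("raschval").joinpath("resources/cutoffs.json").read_text()
    )
    return json.loads(text)["presets"]


_PRESETS = _load_presets()
PUBLISHED_CUTOFF_NAMES = tuple(_PRESETS)


def published_cutoffs(name: str) -> list[tuple[str, int, int]]:
    """Published Emerging/Expanding/Bridging raw-score bands by assessment name.

    Names: fhl, ihl, chl, composite, composite_younger.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown cutoff preset {name!r}; know {sorted(_PRESETS)}")
    return [(lab, int(lo), int(hi)) for lab, lo, hi in _PRESETS[name]["levels"]]


def categorize(score: int, cutoffs: list[tuple[str, int, int]] | str) -> str:
    """Map a raw score to its performance level (boundaries inclusive)."""
    if isinstance(cutoffs, str):
        cutoffs = published_cutoffs(cutoffs)
    if score != int(score):
        raise ValueError("raw score must be an integer")
    score = int(score)
    for label, lo, hi in cutoffs:
        if lo <= score <= hi:
            return label
    raise ValueError(f"score {score} outside the attainable range of the cutoff set")
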