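"""Response-matrix container and CSV interchange.

The pipeline's universal input is a rectangular persons x items table of
integer scores.  Dichotomous items are scored 0/1; partial-credit items are
scored 0..max_score.  Missing responses (item not administered / skipped)
are carried in an explicit mask and treated as "not administered" by every
downstream computation -- they are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DICHOTOMOUS = "dichotomous"
PARTIAL_CREDIT = "partial_credit"


@dataclass(frozen=True)
class ItemSpec:
    """Per-item scoring model: family, score ceiling, optional category labels."""

    item_id: str
    family: str = DICHOTOMOUS
    max_score: int = 1
    category_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.family not in (DICHOTOMOUS, PARTIAL_CREDIT):
            raise ValueError(f"unknown item family {self.family!r}")
        if self.max_score < 1:
            raise ValueError("max_score must be >= 1")
        if (self.family == DICHOTOMOUS) != (self.max_score == 1):
            raise ValueError(
                "dichotomous items must have max_score 1 and polytomous items > 1"
            )
        if self.category_labels is not None and len(self.category_labels) != self.max_score + 1:
            raise ValueError("category_labels must have max_score + 1 entries")


@dataclass
class ResponseMatrix:
    """Persons x items integer scores with a missing-value mask.

    ``scores[n, i]`` is only meaningful where ``missing_mask[n, i]`` is False.
    """

    person_ids: list[str]
    item_specs: list[ItemSpec]
    scores: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.scores.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, k = self.scores.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 persons and 2 items")
        if len(self.person_ids) != n or len(self.item_specs) != k:
            raise ValueError("id/spec lengths do not match the score matrix")
        if len(set(self.person_ids)) != n:
            raise ValueError("duplicate person ids")
        if len({s.item_id for s in self.item_specs}) != k:
            raise ValueError("duplicate item ids")
        if self.missing_mask.shape != self.scores.shape:
            raise ValueError("missing_mask shape mismatch")
        obs = ~self.missing_mask
        lo_ok = (self.scores >= 0) | ~obs
        hi_ok = (self.scores <= self.max_scores[None, :]) | ~obs
        if not (lo_ok.all() and hi_ok.all()):
            raise ValueError("observed score outside its item's 0..max_score range")

    # -- basic geometry -------------------------------------------------
    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return [s.item_id for s in self.item_specs]

    @property
    def max_scores(self) -> np.ndarray:
        return np.array([s.max_score for s in self.item_specs], dtype=int)

    def observed(self) -> np.ndarray:
        """Boolean matrix of administered (non-missing) cells."""
        return ~self.missing_mask

    def person_totals(self) -> np.ndarray:
        return np.where(self.observed(), self.scores, 0).sum(axis=1)

    def person_max_totals(self) -> np.ndarray:
        """Maximum attainable total per person given which items were administered."""
        return (self.observed() * self.max_scores[None, :]).sum(axis=1)

    def item_totals(self) -> np.ndarray:
        return np.where(self.observed(), self.scores, 0).sum(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_persons(self, keep: Sequence[str]) -> "ResponseMatrix":
        keep_set = set(keep)
        idx = [i for i, pid in enumerate(self.person_ids) if pid in keep_set]
        if len(idx) != len(keep_set):
            raise KeyError("unknown person id in subset")
        return ResponseMatrix(
            [self.person_ids[i] for i in idx],
            list(self.item_specs),
            self.scores[idx],
            self.missing_mask[idx],
        )

    def subset_items(self, keep: Sequence[str]) -> "ResponseMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.item_specs) if s.item_id in keep_set]
        if len(idx) != len(keep_set):
            raise KeyError("unknown item id in subset")
        return ResponseMatrix(
            list(self.person_ids),
            [self.item_specs[i] for i in idx],
            self.scores[:, idx],
            self.missing_mask[:, idx],
        )

    def drop_items(self, drop: Iterable[str]) -> "ResponseMatrix":
        drop_set = set(drop)
        return self.subset_items([i for i in self.item_ids if i not in drop_set])

    def drop_persons(self, drop: Iterable[str]) -> "ResponseMatrix":
        drop_set = set(drop)
        return self.subset_persons([p for p in self.person_ids if p not in drop_set])

    # -- interchange -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores.astype(float), index=self.person_ids, columns=self.item_ids
        )
        df[self.missing_mask] = np.nan
        df.index.name = "person_id"
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, item_specs: Sequence[ItemSpec] | None = None
    ) -> "ResponseMatrix":
        if item_specs is None:
            item_specs = infer_item_specs(df)
        spec_by_id = {s.item_id: s for s in item_specs}
        specs = [spec_by_id[c] for c in df.columns]
        values = df.to_numpy(dtype=float)
        missing = np.isnan(values)
        scores = np.where(missing, 0, values).astype(int)
        return cls([str(p) for p in df.index], specs, scores, missing)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, float_format="%.0f")

    @classmethod
    def read_csv(cls, path, item_specs: Sequence[ItemSpec] | None = None) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls.from_dataframe(df, item_specs)


def infer_item_specs(df: pd.DataFrame) -> list[ItemSpec]:
    """Infer item families from observed score ranges (max 1 -> dichotomous)."""
    specs = []
    for col in df.columns:
        vals = df[col].dropna()
        mx = int(vals.max()) if len(vals) else 1
        mx = max(mx, 1)
        family = DICHOTOMOUS if mx == 1 else PARTIAL_CREDIT
        specs.append(ItemSpec(str(col), family, mx))
    return specs


def read_item_specs_csv(path) -> list[ItemSpec]:
    """Item spec CSV: columns item_id, family, max_score."""
    df = pd.read_csv(path)
    return [
        ItemSpec(str(r.item_id), str(r.family), int(r.max_score))
        for r in df.itertuples(index=False)
    ]


def write_item_specs_csv(specs: Sequence[ItemSpec], path) -> None:
    pd.DataFrame(
        {
            "item_id": [s.item_id for s in specs],
            "family": [s.family for s in specs],
            "max_score": [s.max_score for s in specs],
        }
    ).to_csv(path, index=False)
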