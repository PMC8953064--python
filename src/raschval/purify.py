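"""Iterative item purification and the one-round person-misfit check.

Item removal follows the conventional outfit-driven screen: an item is a
removal candidate when its outfit mean-square exceeds 1.5 AND its
standardized outfit exceeds 2 (both gates must fire), or when its
point-measure correlation is negative (reversed polarity).  One item -- the
worst candidate -- is removed per round, the test is recalibrated, and the
assumption screens rerun, until no candidates remain.  Mean-squares below
0.5 are noted but never trigger removal (overfit is unproductive, not
degrading).

Person misfit is handled once, after the item set stabilizes: persons with
outfit mean-square above 2.0 are removed in a single round and the purified
model refit.  The reduced dataset is adopted only if item fit improves --
operationalized as a strict decrease in the number of items with outfit
outside [0.5, 1.5], with mean |outfit ZSTD| as the tie-breaker -- otherwise
the original responses are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import ResponseMatrix
from .diagnostics import DimensionalityReport, FitReport, assess_assumptions, item_fit, person_fit
from .model import EstimationSettings, RaschCalibration, estimate_jmle

__all__ = [
    "PurificationRules",
    "PurificationRound",
    "PersonMisfitRecord",
    "PurificationTrace",
    "flag_removal_candidates",
    "purify_items",
    "person_misfit_round",
]

log = logging.getLogger("raschval.purify")

MIN_ITEMS = 3
MIN_PERSONS = 30


class PurificationError(RuntimeError):
    """Raised when purification would leave too few items to calibrate."""


@dataclass(frozen=True)
class PurificationRules:
    outfit_mnsq_removal_floor: float = 1.5
    zstd_removal_floor: float = 2.0
    low_mnsq_note_floor: float = 0.5
    person_outfit_removal_floor: float = 2.0
    drop_negative_pmc: bool = True
    recheck_assumptions_each_round: bool = True

    def __post_init__(self) -> None:
        if min(
            self.outfit_mnsq_removal_floor,
            self.zstd_removal_floor,
            self.low_mnsq_note_floor,
            self.person_outfit_removal_floor,
        ) <= 0:
            raise ValueError("rule floors must be positive")


@dataclass
class PurificationRound:
    round_number: int
    removed_item_id: str | None
    trigger: str | None  # "outfit" | "negative_pmc" | None
    trigger_value: float | None
    fit: FitReport
    assumptions: DimensionalityReport | None
    low_mnsq_notes: list[str] = field(default_factory=list)


@dataclass
class PersonMisfitRecord:
    removed_person_ids: list[str]
    verdict: str  # "no candidates" | "improved, reduced dataset adopted" |
    #               "not improved, original retained" | "too few persons, original retained"
    fit_before: FitReport | None
    fit_after: FitReport | None
    adopted_reduced: bool


@dataclass
class PurificationTrace:
    rounds: list[PurificationRound]
    person_round: PersonMisfitRecord | None
    final_calibration: RaschCalibration
    final_responses: ResponseMatrix
    removed_items: list[str]

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {
                    "round": r.round_number,
                    "removed_item_id": r.removed_item_id,
                    "trigger": r.trigger,
                    "trigger_value": r.trigger_value,
                    "fit": r.fit.to_dict(),
                    "assumptions": r.assumptions.to_dict() if r.assumptions else None,
                    "low_mnsq_notes": r.low_mnsq_notes,
                }
                for r in self.rounds
            ],
            "person_round": (
                None
                if self.person_round is None
                else {
                    "removed_person_ids": self.person_round.removed_person_ids,
                    "verdict": self.person_round.verdict,
                    "adopted_reduced": self.person_round.adopted_reduced,
                }
            ),
            "removed_items": self.removed_items,
            "final_converged": bool(self.final_calibration.converged),
        }


def flag_removal_candidates(
    fit: FitReport, rules: PurificationRules | None = None
) -> list[tuple[str, str, float]]:
    """Ordered (item_id, trigger, trigger_value) removal candidates.

    Outfit candidates (mnsq > floor AND zstd > floor) come first, worst
    mean-square first, ties broken by larger |zstd| then item id; items with
    negative PMC follow regardless of their fit.  A negative-PMC item is
    always a polarity candidate, never an outfit candidate: residual fit
    statistics presuppose correct keying, so misfit numbers on a reversed
    item are not interpretable as misfit.
    """
    rules = rules or PurificationRules()
    tab = fit.table
    outfit_mask = (tab["outfit_mnsq"] > rules.outfit_mnsq_removal_floor) & (
        tab["outfit_zstd"] > rules.zstd_removal_floor
    )
    if rules.drop_negative_pmc and "pmc" in tab:
        outfit_mask &= ~(tab["pmc"] < 0)
    sub = tab[outfit_mask].copy()
    sub["abs_z"] = sub["outfit_zstd"].abs()
    sub = sub.sort_values(
        by=["outfit_mnsq", "abs_z"], ascending=[False, False], kind="mergesort"
    )
    # stable lexical tie-break on exactly equal keys
    sub = sub.iloc[
        np.lexsort(
            (sub.index.to_numpy(), -sub["abs_z"].to_numpy(), -sub["outfit_mnsq"].to_numpy())
        )
    ]
    cands = [(iid, "outfit", float(row.outfit_mnsq)) for iid, row in sub.iterrows()]
    if rules.drop_negative_pmc and "pmc" in tab:
        flagged = {c[0] for c in cands}
        neg = tab[(tab["pmc"] < 0) & ~tab.index.isin(flagged)].sort_values("pmc")
        cands += [(iid, "negative_pmc", float(row.pmc)) for iid, row in neg.iterrows()]
    return cands


def purify_items(
    responses: ResponseMatrix,
    rules: PurificationRules | None = None,
    settings: EstimationSettings | None = None,
    keep_items: list[str] | None = None,
) -> PurificationTrace:
    """Calibrate / diagnose / remove-worst loop until every item fits.

    ``keep_items`` is the theory-driven override: listed items are never
    removed regardless of fit.  At most one item is removed per round; the
    final round removes nothing.  Raises :class:`PurificationError` rather
    than purifying below 3 items.
    """
    rules = rules or PurificationRules()
    keep = set(keep_items or [])
    current = responses
    rounds: list[PurificationRound] = []
    removed: list[str] = []
    round_no = 0
    while True:
        round_no += 1
        cal = estimate_jmle(current, settings)
        fit = item_fit(cal, current)
        notes = list(fit.table.index[fit.table["outfit_mnsq"] < rules.low_mnsq_note_floor])
        assumptions = (
            assess_assumptions(cal, current) if rules.recheck_assumptions_each_round else None
        )
        cands = [c for c in flag_removal_candidates(fit, rules) if c[0] not in keep]
        if not cands:
            rounds.append(PurificationRound(round_no, None, None, None, fit, assumptions, notes))
            log.info("round %d: no removal candidates; purification complete", round_no)
            break
        if current.n_items - 1 < MIN_ITEMS:
            raise PurificationError(
                f"removing {cands[0][0]} would leave fewer than {MIN_ITEMS} items"
            )
        iid, trigger, value = cands[0]
        rounds.append(PurificationRound(round_no, iid, trigger, value, fit, assumptions, notes))
        log.info("round %d: removed item %s (trigger=%s, value=%.3f)", round_no, iid, trigger, value)
        removed.append(iid)
        current = current.drop_items([iid])
    final_cal = estimate_jmle(current, settings)
    return PurificationTrace(rounds, None, final_cal, current, removed)


def _misfit_count(fit: FitReport, rules: PurificationRules) -> int:
    m = fit.table["outfit_mnsq"]
    return int(((m < rules.low_mnsq_note_floor) | (m > rules.outfit_mnsq_removal_floor)).sum())


def _mean_abs_zstd(fit: FitReport) -> float:
    return float(fit.table["outfit_zstd"].abs().mean())


def person_misfit_round(
    responses: ResponseMatrix,
    rules: PurificationRules | None = None,
    settings: EstimationSettings | None = None,
) -> tuple[PersonMisfitRecord, ResponseMatrix, RaschCalibration]:
    """One round of person-misfit removal, adopted only if item fit improves."""
    rules = rules or PurificationRules()
    cal = estimate_jmle(responses, settings)
    pfit = person_fit(cal, responses)
    before = item_fit(cal, responses)
    misfits = list(
        pfit.table.index[pfit.table["outfit_mnsq"] > rules.person_outfit_removal_floor]
    )
    if not misfits:
        rec = PersonMisfitRecord([], "no candidates", before, None, False)
        return rec, responses, cal
    if responses.n_persons - len(misfits) < MIN_PERSONS:
        warnings.warn(
            f"removing {len(misfits)} misfitting persons would leave fewer than "
            f"{MIN_PERSONS}; original dataset retained"
        )
        rec = PersonMisfitRecord(misfits, "too few persons, original retained", before, None, False)
        return rec, responses, cal
    reduced = responses.drop_persons(misfits)
    cal_red = estimate_jmle(reduced, settings)
    after = item_fit(cal_red, reduced)
    n_before, n_after = _misfit_count(before, rules), _misfit_count(after, rules)
    improved = n_after < n_before or (
        n_after == n_before and _mean_abs_zstd(after) < _mean_abs_zstd(before)
    )
    if improved:
        log.info(
            "person round: removed %d persons; item misfit count %d -> %d; reduced dataset adopted",
            len(misfits), n_before, n_after,
        )
        rec = PersonMisfitRecord(misfits, "improved, reduced dataset adopted", before, after, True)
        return rec, reduced, cal_red
    log.info("person round: removal did not improve fit; original dataset retained")
    rec = PersonMisfitRecord(misfits, "not improved, original retained", before, after, False)
    return rec, responses, cal
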