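"""Iterative item purification and the one-round person-misfit procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import raschval as rv
from raschval.data import ItemSpec
from raschval.diagnostics import FitReport
from raschval.purify import PurificationError, PurificationRules
from raschval.synthetic import AbilityDist, CohortConfig, TrueItem

INJECT_ABILITY = AbilityDist((0.5, 0.5), (0.0, 0.0), (1.5, 1.5))


def _fit_report(records: dict) -> FitReport:
    tab = pd.DataFrame(records).T
    tab.index.name = "item_id"
    return FitReport("item", tab)


def _bank(n, lo, hi, prefix="G"):
    return tuple(
        TrueItem(ItemSpec(f"{prefix}{i+1:02d}"), b)
        for i, b in enumerate(np.linspace(lo, hi, n))
    )


class TestFlagRemovalCandidates:
    def test_all_items_in_band_yield_no_candidates(self):
        fit = _fit_report(
            {
                "A": dict(outfit_mnsq=1.2, outfit_zstd=1.0, infit_mnsq=1, infit_zstd=0, pmc=0.5),
                "B": dict(outfit_mnsq=0.7, outfit_zstd=-1.5, infit_mnsq=1, infit_zstd=0, pmc=0.4),
            }
        )
        assert rv.flag_removal_candidates(fit) == []

    def test_zstd_gate_blocks_high_mnsq(self):
        fit = _fit_report(
            {
                "A": dict(outfit_mnsq=1.8, outfit_zstd=2.5, infit_mnsq=1, infit_zstd=0, pmc=0.5),
                "B": dict(outfit_mnsq=1.6, outfit_zstd=1.0, infit_mnsq=1, infit_zstd=0, pmc=0.4),
            }
        )
        cands = rv.flag_removal_candidates(fit)
        assert [c[0] for c in cands] == ["A"]
        assert cands[0][1] == "outfit"

    def test_negative_pmc_flagged_despite_perfect_fit(self):
        fit = _fit_report(
            {
                "A": dict(outfit_mnsq=1.0, outfit_zstd=0.0, infit_mnsq=1, infit_zstd=0, pmc=-0.1),
            }
        )
        cands = rv.flag_removal_candidates(fit)
        assert cands == [("A", "negative_pmc", pytest.approx(-0.1))]

    def test_negative_pmc_item_never_an_outfit_candidate(self):
        fit = _fit_report(
            {
                "A": dict(outfit_mnsq=3.0, outfit_zstd=6.0, infit_mnsq=1, infit_zstd=0, pmc=-0.3),
                "B": dict(outfit_mnsq=1.7, outfit_zstd=2.5, infit_mnsq=1, infit_zstd=0, pmc=0.2),
            }
        )
        cands = rv.flag_removal_candidates(fit)
        assert cands[0] == ("B", "outfit", pytest.approx(1.7))
        assert cands[1][0] == "A" and cands[1][1] == "negative_pmc"

    def test_ordering_worst_mnsq_then_zstd_then_id(self):
        fit = _fit_report(
            {
                "C": dict(outfit_mnsq=2.0, outfit_zstd=3.0, infit_mnsq=1, infit_zstd=0, pmc=0.2),
                "B": dict(outfit_mnsq=2.0, outfit_zstd=4.0, infit_mnsq=1, infit_zstd=0, pmc=0.2),
                "A": dict(outfit_mnsq=2.5, outfit_zstd=2.5, infit_mnsq=1, infit_zstd=0, pmc=0.2),
                "E": dict(outfit_mnsq=2.0, outfit_zstd=3.0, infit_mnsq=1, infit_zstd=0, pmc=0.2),
            }
        )
        assert [c[0] for c in rv.flag_removal_candidates(fit)] == ["A", "B", "C", "E"]

    @settings(max_examples=100, derandomize=True)
    @given(
        mnsq=st.floats(0.1, 4.0),
        zstd=st.floats(-6.0, 8.0),
        pmc=st.floats(-1.0, 1.0),
    )
    def test_gate_is_exact_conjunction(self, mnsq, zstd, pmc):
        fit = _fit_report(
            {"X": dict(outfit_mnsq=mnsq, outfit_zstd=zstd, infit_mnsq=1, infit_zstd=0, pmc=pmc)}
        )
        cands = rv.flag_removal_candidates(fit)
        should_outfit = mnsq > 1.5 and zstd > 2.0 and not pmc < 0
        should_pmc = pmc < 0
        assert (("X", "outfit") in [(c[0], c[1]) for c in cands]) == should_outfit
        assert (("X", "negative_pmc") in [(c[0], c[1]) for c in cands]) == should_pmc


class TestPurifyItems:
    def test_model_consistent_data_single_round_no_removals(self):
        removals = []
        for seed in range(1, 11):
            data = rv.generate_cohort(
                CohortConfig(seed=seed + 40, item_bank=_bank(20, -2, 2), ability=INJECT_ABILITY)
            )
            tr = rv.purify_items(data.responses)
            removals.append(len(tr.removed_items))
        assert np.mean(removals) <= 1.0
        assert removals.count(0) >= 8

    def test_six_noise_items_removed_from_twelve(self):
        """Mirrors a 12-item bank purified down to its 6 coherent items."""
        exact = 0
        for seed in range(1, 6):
            noise = tuple(f"G{i:02d}" for i in (2, 4, 6, 8, 10, 12))
            data = rv.generate_cohort(
                CohortConfig(
                    seed=seed,
                    item_bank=_bank(12, -1.5, 1.5),
                    noise_items=noise,
                    noise_rate=0.15,
                    ability=INJECT_ABILITY,
                )
            )
            tr = rv.purify_items(data.responses)
            exact += set(tr.removed_items) == set(noise)
            assert tr.rounds[-1].removed_item_id is None  # final round removes nothing
        assert exact >= 4

    def test_four_noise_and_one_reversed_split_by_trigger(self):
        ok = 0
        for seed in range(1, 6):
            bank = _bank(14, -1.8, 1.8, prefix="H") + (TrueItem(ItemSpec("H15"), -2.4),)
            noise = ("H03", "H06", "H09", "H12")
            data = rv.generate_cohort(
                CohortConfig(
                    seed=seed + 1000,
                    item_bank=bank,
                    noise_items=noise,
                    noise_rate=0.2,
                    reversed_items=("H15",),
                    reversed_slope=-1.0,
                    ability=INJECT_ABILITY,
                )
            )
            tr = rv.purify_items(data.responses)
            trig = {r.removed_item_id: r.trigger for r in tr.rounds if r.removed_item_id}
            ok += {k for k, v in trig.items() if v == "outfit"} == set(noise) and {
                k for k, v in trig.items() if v == "negative_pmc"
            } == {"H15"}
        assert ok >= 4

    def test_trace_is_deterministic_and_audited(self):
        noise = ("G02", "G05")
        cfg = CohortConfig(
            seed=77, item_bank=_bank(10, -1.5, 1.5), noise_items=noise,
            noise_rate=0.15, ability=INJECT_ABILITY,
        )
        tr1 = rv.purify_items(rv.generate_cohort(cfg).responses)
        tr2 = rv.purify_items(rv.generate_cohort(cfg).responses)
        assert tr1.removed_items == tr2.removed_items
        rules = PurificationRules()
        for r1, r2 in zip(tr1.rounds, tr2.rounds):
            assert r1.removed_item_id == r2.removed_item_id
            if r1.trigger == "outfit":
                assert r1.trigger_value > rules.outfit_mnsq_removal_floor
            elif r1.trigger == "negative_pmc":
                assert r1.trigger_value < 0
            pd.testing.assert_frame_equal(r1.fit.table, r2.fit.table)
        assert tr1.rounds[0].assumptions is not None

    def test_noise_removed_before_any_clean_item(self):
        hits = 0
        for seed in range(1, 11):
            noise = ("G02", "G05", "G08")
            data = rv.generate_cohort(
                CohortConfig(
                    seed=seed + 60, item_bank=_bank(12, -1.5, 1.5), noise_items=noise,
                    noise_rate=0.15, ability=INJECT_ABILITY,
                )
            )
            tr = rv.purify_items(data.responses)
            k = len(set(noise))
            first_k = tr.removed_items[:k]
            if set(first_k) <= set(noise) and set(noise) <= set(tr.removed_items):
                hits += 1
        assert hits >= 9

    def test_keep_list_overrides_removal(self):
        noise = ("G02", "G05")
        data = rv.generate_cohort(
            CohortConfig(
                seed=78, item_bank=_bank(10, -1.5, 1.5), noise_items=noise,
                noise_rate=0.15, ability=INJECT_ABILITY,
            )
        )
        tr = rv.purify_items(data.responses, keep_items=["G02"])
        assert "G02" not in tr.removed_items

    def test_item_floor_raises(self):
        data = rv.generate_cohort(
            CohortConfig(
                seed=79, item_bank=_bank(3, -1, 1), noise_items=("G02",),
                noise_rate=0.15, ability=INJECT_ABILITY,
            )
        )
        with pytest.raises(PurificationError):
            rv.purify_items(data.responses)


class TestPersonMisfitRound:
    def test_no_candidates_retains_original(self):
        data = rv.generate_cohort(
            CohortConfig(seed=90, item_bank=_bank(20, -2, 2), ability=INJECT_ABILITY)
        )
        rules = PurificationRules(person_outfit_removal_floor=50.0)
        rec, final, _ = rv.person_misfit_round(data.responses, rules)
        assert rec.verdict == "no candidates"
        assert final is data.responses

    def test_injected_random_responders_improve_fit(self):
        adopted = 0
        for seed in range(1, 6):
            data = rv.generate_cohort(
                CohortConfig(
                    seed=seed, n_persons=500, item_bank=_bank(20, -2, 2, prefix="N"),
                    n_misfit_persons=20,
                    ability=AbilityDist((0.5, 0.5), (0.0, 0.0), (1.0, 1.0)),
                )
            )
            rec, final, _ = rv.person_misfit_round(data.responses)
            if rec.adopted_reduced:
                adopted += 1
                assert final.n_persons < 500
        assert adopted >= 3

    def test_person_floor_retains_original(self):
        data = rv.generate_cohort(
            CohortConfig(
                seed=91, n_persons=34, item_bank=_bank(12, -2, 2),
                n_misfit_persons=8, ability=INJECT_ABILITY,
            )
        )
        rules = PurificationRules(person_outfit_removal_floor=1.2)
        with pytest.warns(UserWarning, match="fewer than"):
            rec, final, _ = rv.person_misfit_round(data.responses, rules)
        assert not rec.adopted_reduced
        assert final.n_persons == data.responses.n_persons

    def test_unimproved_fit_retains_original(self):
        # model-consistent cohort: chance "misfits" exist, removing them does
        # not reduce the (already zero) count of items outside the band and
        # rarely improves mean |zstd|; across seeds at least one retention
        verdicts = []
        for seed in (2, 6, 11, 14):
            data = rv.generate_cohort(
                CohortConfig(
                    seed=seed, n_persons=500, item_bank=_bank(20, -2, 2, prefix="N"),
                    n_misfit_persons=20,
                    ability=AbilityDist((0.5, 0.5), (0.0, 0.0), (1.0, 1.0)),
                )
            )
            rec, final, _ = rv.person_misfit_round(data.responses)
            verdicts.append(rec.verdict)
        assert any(v == "not improved, original retained" for v in verdicts)

    def test_trace_serializes(self):
        data = rv.generate_cohort(
            CohortConfig(seed=92, item_bank=_bank(10, -1.5, 1.5), ability=INJECT_ABILITY)
        )
        tr = rv.purify_items(data.responses)
        d = tr.to_dict()
        assert d["rounds"][-1]["removed_item_id"] is None
        assert isinstance(d["final_converged"], bool)
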