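"""Fit statistics, point-measure correlations, and assumption screens."""

import numpy as np
import pandas as pd
import pytest

import raschval as rv
from raschval.data import ItemSpec, ResponseMatrix
from raschval.synthetic import AbilityDist, CohortConfig, TrueItem


def _two_by_two(scores, theta, b):
    """Tiny response matrix + hand calibration for residual arithmetic."""
    rm = ResponseMatrix(
        ["p1", "p2"], [ItemSpec("i1"), ItemSpec("i2")], np.asarray(scores)
    )
    return rm


class TestStandardizedResiduals:
    def test_hand_values(self, hand_calibration):
        # person at theta=b: x=1 -> z = (1-0.5)/0.5 = 1; x=0 at P=0.75 -> z = -sqrt(3)
        cal = hand_calibration([0.0, -np.log(3)], persons=[0.0, 0.0])
        rm = _two_by_two([[1, 0], [0, 1]], 0.0, 0.0)
        z = rv.standardized_residuals(cal, rm)
        assert z.loc["p1", "i1"] == pytest.approx(1.0)
        assert z.loc["p1", "i2"] == pytest.approx(-np.sqrt(3.0))
        assert z.loc["p2", "i1"] == pytest.approx(-1.0)

    def test_missing_cells_propagate(self, hand_calibration):
        cal = hand_calibration([0.0, 0.0], persons=[0.0, 0.0])
        rm = ResponseMatrix(
            ["p1", "p2"],
            [ItemSpec("i1"), ItemSpec("i2")],
            np.array([[1, 0], [0, 1]]),
            np.array([[False, True], [False, False]]),
        )
        z = rv.standardized_residuals(cal, rm)
        assert np.isnan(z.loc["p1", "i2"])
        assert np.isfinite(z.loc["p2", "i2"])

    def test_shape_mismatch_rejected(self, hand_calibration):
        cal = hand_calibration([0.0, 0.0], persons=[0.0, 0.0])
        rm = ResponseMatrix(
            ["q1", "q2"], [ItemSpec("j1"), ItemSpec("j2")], np.array([[1, 0], [0, 1]])
        )
        with pytest.raises(ValueError):
            rv.standardized_residuals(cal, rm)


class TestItemFit:
    def test_unit_residuals_give_outfit_one(self, hand_calibration):
        """Every |z| = 1 when all persons sit at the item locations."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=(20, 3))
        cal = hand_calibration([0.0, 0.0, 0.0], persons=[0.0] * 20)
        rm = ResponseMatrix(
            [f"p{i+1}" for i in range(20)], [ItemSpec(f"i{j+1}") for j in range(3)], x
        )
        fit = rv.item_fit(cal, rm)
        assert fit.table["outfit_mnsq"].to_numpy() == pytest.approx([1.0] * 3)

    def test_null_simulation_outfit_centres_on_one(self, null_cohort_500x20, null_calibration):
        fit = rv.item_fit(null_calibration, null_cohort_500x20.responses)
        assert 0.9 <= fit.table["outfit_mnsq"].mean() <= 1.1

    def test_injected_noise_item_attains_max_outfit(self):
        hits = 0
        for seed in range(1, 11):
            rng = np.random.default_rng(3000 + seed)
            bank = tuple(
                TrueItem(ItemSpec(f"N{i:02d}"), b)
                for i, b in enumerate(np.linspace(-1.5, 1.5, 20))
            )
            cfg = CohortConfig(
                seed=seed + 400,
                n_persons=500,
                item_bank=bank,
                noise_items=("N07",),
                noise_rate=0.2,
                ability=AbilityDist((0.5, 0.5), (0.0, 0.0), (1.2, 1.2)),
            )
            data = rv.generate_cohort(cfg)
            cal = rv.estimate_jmle(data.responses)
            fit = rv.item_fit(cal, data.responses)
            top = fit.table["outfit_mnsq"].idxmax()
            if top == "N07" and fit.table.loc["N07", "outfit_zstd"] > 2:
                hits += 1
        assert hits >= 9

    def test_fit_invariant_to_person_order(self, hand_calibration):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, size=(30, 4))
        thetas = rng.normal(0, 1, 30)
        cal = hand_calibration([0.0, 0.5, -0.5, 1.0], persons=list(thetas))
        rm = ResponseMatrix(
            [f"p{i+1}" for i in range(30)], [ItemSpec(f"i{j+1}") for j in range(4)], x
        )
        fit = rv.item_fit(cal, rm)
        perm = rng.permutation(30)
        cal2 = hand_calibration([0.0, 0.5, -0.5, 1.0], persons=list(thetas[perm]))
        rm2 = ResponseMatrix(
            [f"p{i+1}" for i in range(30)],
            [ItemSpec(f"i{j+1}") for j in range(4)],
            x[perm],
        )
        fit2 = rv.item_fit(cal2, rm2)
        pd.testing.assert_frame_equal(fit.table, fit2.table)


class TestPersonFit:
    def test_guttman_person_overfits(self, hand_calibration):
        """A deterministic response vector at matching ability has outfit < 1."""
        b = np.linspace(-2, 2, 10)
        cal = hand_calibration(list(b), persons=[0.0, 0.0])
        x = np.vstack([(b < 0).astype(int), (b <= 0.5).astype(int)])
        rm = ResponseMatrix(
            ["p1", "p2"], [ItemSpec(f"i{j+1}") for j in range(10)], x
        )
        fit = rv.person_fit(cal, rm)
        assert fit.table.loc["p1", "outfit_mnsq"] < 1.0

    def test_random_responder_ranks_in_worst_decile(self):
        """With only ~20 responses a single random responder cannot reliably
        beat the null maximum over a whole cohort, but it lands in the worst
        decile of the person outfit distribution essentially always."""
        hits = 0
        for seed in range(1, 11):
            bank = tuple(
                TrueItem(ItemSpec(f"N{i:02d}"), b)
                for i, b in enumerate(np.linspace(-3, 3, 20))
            )
            cfg = CohortConfig(
                seed=seed + 500,
                n_persons=100,
                item_bank=bank,
                n_misfit_persons=1,
                ability=AbilityDist((0.5, 0.5), (0.0, 0.0), (1.2, 1.2)),
            )
            data = rv.generate_cohort(cfg)
            cal = rv.estimate_jmle(data.responses)
            fit = rv.person_fit(cal, data.responses)
            injected = data.truth["misfit_person_ids"][0]
            rank = fit.table["outfit_mnsq"].rank(ascending=False)[injected]
            if rank <= 10:
                hits += 1
        assert hits >= 9

    def test_person_with_single_response_warns(self, hand_calibration):
        cal = hand_calibration([0.0, 0.5, -0.5], persons=[0.0, 0.1, -0.1])
        missing = np.array(
            [[False, False, False], [False, False, False], [True, True, False]]
        )
        rm = ResponseMatrix(
            ["p1", "p2", "p3"],
            [ItemSpec(f"i{j+1}") for j in range(3)],
            np.array([[1, 0, 1], [0, 1, 0], [0, 0, 1]]),
            missing,
        )
        with pytest.warns(UserWarning, match="<2 usable responses"):
            fit = rv.person_fit(cal, rm)
        assert "p3" not in fit.table.index


class TestPointMeasureCorrelation:
    def test_affine_item_scores_give_unit_pmc(self, hand_calibration):
        thetas = np.linspace(-2, 2, 12)
        cal = hand_calibration([0.0, 0.0], persons=list(thetas))
        x = np.column_stack([(thetas > 0).astype(int), (thetas > 0.5).astype(int)])
        rm = ResponseMatrix(
            [f"p{i+1}" for i in range(12)], [ItemSpec("i1"), ItemSpec("i2")], x
        )
        pmc = rv.point_measure_correlation(rm, cal)
        # monotone step functions of theta correlate strongly positively
        assert pmc["i1"] > 0.8

    def test_reverse_keyed_item_negative_pmc(self, default_cohort):
        data = rv.generate_cohort(
            CohortConfig(seed=9, reversed_items=("IHL05",), reversed_slope=-1.0)
        )
        cal = rv.estimate_jmle(data.responses)
        pmc = rv.point_measure_correlation(data.responses, cal)
        assert pmc["IHL05"] < 0

    def test_matches_direct_pearson(self, default_cohort, default_calibration):
        resp = default_cohort.responses
        pmc = rv.point_measure_correlation(resp, default_calibration)
        theta = np.array(
            [
                default_calibration.person_measure[default_calibration.person_ids.index(p)]
                for p in resp.person_ids
            ]
        )
        j = resp.item_ids.index("FHL01")
        use = np.isfinite(theta) & resp.observed()[:, j]
        r = np.corrcoef(resp.scores[use, j], theta[use])[0, 1]
        assert pmc["FHL01"] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_item_flagged(self, hand_calibration):
        cal = hand_calibration([0.0, 0.0], persons=[0.0, 0.5, 1.0, -0.5])
        x = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
        rm = ResponseMatrix(
            ["p1", "p2", "p3", "p4"], [ItemSpec("i1"), ItemSpec("i2")], x
        )
        with pytest.warns(UserWarning, match="zero score variance"):
            pmc = rv.point_measure_correlation(rm, cal)
        assert np.isnan(pmc["i1"])


class TestAssumptionChecks:
    def test_null_residuals_unidimensional(self, null_cohort_500x20, null_calibration):
        z = rv.standardized_residuals(null_calibration, null_cohort_500x20.responses)
        eig, unidim, _ = rv.residual_pca_first_contrast(z)
        assert eig < 2.0 and unidim

    def test_second_dimension_detected(self):
        """8 of 20 items loading on an independent second trait push the
        first residual contrast to two items-worth or more."""
        rng = np.random.default_rng(42)
        n = 500
        theta = rng.normal(0, 1, n)
        theta2 = rng.normal(0, 1, n)
        b = np.linspace(-1.5, 1.5, 20)
        scores = np.zeros((n, 20), dtype=int)
        for j in range(20):
            drive = 0.5 * theta + 1.1 * theta2 if j < 8 else theta
            p = 1 / (1 + np.exp(-(drive - b[j])))
            scores[:, j] = (rng.random(n) < p).astype(int)
        rm = ResponseMatrix(
            [f"p{i}" for i in range(n)], [ItemSpec(f"i{j+1}") for j in range(20)], scores
        )
        cal = rv.estimate_jmle(rm)
        z = rv.standardized_residuals(cal, rm)
        eig, unidim, _ = rv.residual_pca_first_contrast(z)
        assert eig >= 2.0 and not unidim

    def test_orthogonal_residuals_eigenvalue_near_one(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(rng.normal(size=(2000, 3)), columns=["a", "b", "c"])
        eig, unidim, _ = rv.residual_pca_first_contrast(z)
        assert eig == pytest.approx(1.0, abs=0.1)
        assert unidim

    def test_pca_needs_three_items(self):
        z = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            rv.residual_pca_first_contrast(z)

    def test_pca_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(8)
        z = pd.DataFrame(rng.normal(size=(200, 6)))
        eig, _, _ = rv.residual_pca_first_contrast(z)
        direct = np.linalg.eigvalsh(np.corrcoef(z.to_numpy().T)).max()
        assert eig == pytest.approx(direct, abs=1e-8)

    def test_local_independence_duplicate_column(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=300)
        z = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=300)})
        res = rv.local_independence(z)
        assert res["max_abs_residual_correlation"] == pytest.approx(1.0)
        assert not res["locally_independent"]

    def test_local_independence_null(self, null_cohort_500x20, null_calibration):
        z = rv.standardized_residuals(null_calibration, null_cohort_500x20.responses)
        res = rv.local_independence(z)
        assert res["max_abs_residual_correlation"] < 0.50
        assert res["locally_independent"]
        # signed extremes match a direct pairwise computation
        corr = z.corr().to_numpy()
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert res["max_residual_correlation"] == pytest.approx(np.nanmax(off), abs=1e-12)
        assert res["min_residual_correlation"] == pytest.approx(np.nanmin(off), abs=1e-12)

    def test_tcc_monotone_with_limits(self, default_calibration):
        mono, curve = rv.check_tcc_monotonicity(default_calibration)
        assert mono
        assert len(curve) >= 201
        assert curve["expected_total"].iloc[0] < 1.0
        assert curve["expected_total"].iloc[-1] > 29.0

    def test_single_item_tcc_equals_icc(self, hand_calibration):
        cal = hand_calibration([0.4, 20.0])  # second item far away contributes ~0 low end
        cal_single = hand_calibration([0.4])
        mono, curve = rv.check_tcc_monotonicity(cal_single)
        icc = rv.dichotomous_prob(curve["theta"].to_numpy(), 0.4)
        assert curve["expected_total"].to_numpy() == pytest.approx(icc, abs=1e-10)

    def test_assess_assumptions_bundle(self, default_cohort, default_calibration):
        rep = rv.assess_assumptions(default_calibration, default_cohort.responses)
        assert rep.unidimensional and rep.locally_independent and rep.tcc_monotone
        d = rep.to_dict()
        assert set(d) >= {"first_contrast_eigenvalue", "tcc_monotone"}
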