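import numpy as np
import pytest

import raschval as rv
from raschval.data import ItemSpec, ResponseMatrix
from raschval.model import EstimationSettings
from raschval.synthetic import AbilityDist, CohortConfig, TrueItem


@pytest.fixture(scope="session")
def default_cohort():
    """One default study-like cohort (355 x 23 mixed battery), seed 1."""
    return rv.generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_calibration(default_cohort):
    return rv.estimate_jmle(default_cohort.responses)


@pytest.fixture(scope="session")
def null_cohort_500x20():
    """Model-consistent 500 x 20 dichotomous cohort on a U(-2, 2) bank."""
    rng = np.random.default_rng(20)
    bank = tuple(
        TrueItem(ItemSpec(f"N{i+1:02d}"), b) for i, b in enumerate(rng.uniform(-2, 2, 20))
    )
    ability = AbilityDist((0.5, 0.5), (0.0, 0.0), (1.0, 1.0))
    return rv.generate_cohort(
        CohortConfig(seed=20, n_persons=500, item_bank=bank, ability=ability)
    )


@pytest.fixture(scope="session")
def null_calibration(null_cohort_500x20):
    return rv.estimate_jmle(null_cohort_500x20.responses)


def make_calibration(difficulties, thresholds=None, persons=None):
    """Hand-built calibration object for probability-level tests."""
    thresholds = thresholds or {}
    item_ids = [f"i{j+1}" for j in range(len(difficulties))]
    specs = []
    th = {}
    for j, (iid, b) in enumerate(zip(item_ids, difficulties)):
        tau = thresholds.get(j)
        if tau is None:
            specs.append(ItemSpec(iid))
        else:
            specs.append(ItemSpec(iid, "partial_credit", len(tau)))
            th[iid] = np.asarray(tau, dtype=float)
    persons = persons if persons is not None else [0.0, 0.0]
    pids = [f"p{n+1}" for n in range(len(persons))]
    b = np.asarray(difficulties, dtype=float)
    return rv.RaschCalibration(
        item_ids=item_ids,
        item_specs=specs,
        item_difficulty=b,
        item_se=np.full(b.size, 0.1),
        thresholds=th,
        threshold_se={k: np.full(len(v), 0.1) for k, v in th.items()},
        person_ids=pids,
        person_measure=np.asarray(persons, dtype=float),
        person_se=np.full(len(persons), 0.1),
        excluded_persons=[],
        excluded_items=[],
        converged=True,
        n_iterations=1,
        max_residual_change=0.0,
        settings=EstimationSettings(),
    )


@pytest.fixture
def hand_calibration():
    return make_calibration
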