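"""Markov cohort engine: matrix structure, mass conservation, rewards."""

import numpy as np
import pytest

from lynchcea import ParameterSet, arm_outcomes, build_transition_matrix, run_cohort
from lynchcea.markov import (
    AFTER_FIRST,
    DEATH,
    N_STATES,
    WELL,
    Stratum,
    crc_state,
    ec_state,
    second_state,
    stratum_weights,
)
from lynchcea.synthetic import make_degenerate_params


def _with(params, **updates) -> ParameterSet:
    doc = params.model_dump(mode="python")
    doc.update(updates)
    return ParameterSet(**doc)


ALL_STRATA = [
    Stratum("male", True, adherent=True),
    Stratum("male", True, adherent=False),
    Stratum("female", True, adherent=True, surgery=True),
    Stratum("female", True, adherent=True, surgery=False),
    Stratum("female", True, adherent=False),
    Stratum("male", False),
    Stratum("female", False),
]


def test_rows_stochastic_for_all_ages_and_strata(params):
    for stratum in ALL_STRATA:
        for age in range(params.fdr_entry_age, params.max_age):
            P = build_transition_matrix(params, stratum, age)
            assert np.all(P >= -1e-15)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)


def test_no_cancer_well_row_is_pure_survival(params):
    fc = make_degenerate_params("two_state_geometric")
    P = build_transition_matrix(fc.params, Stratum("male", False), 40)
    assert P[WELL, WELL] == pytest.approx(0.95)
    assert P[WELL, DEATH] == pytest.approx(0.05)
    assert P[WELL].sum() == pytest.approx(1.0)


def test_ec_entry_zero_after_prophylactic_surgery(params):
    s = Stratum("female", True, adherent=True, surgery=True)
    P = build_transition_matrix(params, s, 46)
    assert P[WELL, ec_state(1)] == 0.0
    # without surgery the same woman still faces endometrial-cancer risk
    P2 = build_transition_matrix(params, Stratum("female", True, adherent=True), 46)
    assert P2[WELL, ec_state(1)] > 0.0


def test_unsurveilled_male_crc_entry_matches_annual_risk_and_stage_split(params):
    # near-zero background mortality isolates the cancer hazard
    doc = params.model_dump(mode="python")
    doc["background_mortality"] = {"male": {"a": 1e-15, "b": 0.0}, "female": {"a": 1e-15, "b": 0.0}}
    p = ParameterSet(**doc)
    P = build_transition_matrix(p, Stratum("male", False), 40)
    entries = np.array([P[WELL, crc_state(s, 1)] for s in (1, 2, 3, 4)])
    assert entries.sum() == pytest.approx(0.010566792814283188, abs=1e-9)
    np.testing.assert_allclose(entries / entries.sum(), [0.267, 0.533, 0.133, 0.067], atol=1e-12)


def test_crc_entry_zero_outside_risk_window(params):
    P = build_transition_matrix(params, Stratum("male", False), 75)
    assert sum(P[WELL, crc_state(s, 1)] for s in (1, 2, 3, 4)) == 0.0


def test_tunnel_exit_routes_to_second_cancer_or_cure(params):
    P = build_transition_matrix(params, Stratum("male", False), 50)
    row = P[crc_state(2, 5)]
    survive = 1.0 - row[DEATH]
    assert row[second_state(1)] == pytest.approx(survive * params.p_second_cancer)
    assert row[AFTER_FIRST] == pytest.approx(survive * (1 - params.p_second_cancer))
    # second-cancer survivors cannot have another second cancer
    row2 = P[second_state(5)]
    assert row2[second_state(1)] == 0.0


def test_geometric_two_state_closed_form():
    fc = make_degenerate_params("two_state_geometric")
    trace = run_cohort(fc.params, Stratum("male", False))
    assert trace.total_qaly == pytest.approx(fc.expected, abs=fc.tolerance)
    # and the infinite-horizon limit a/(1-a) is approached from below
    a = 0.95 / 1.035
    assert trace.total_qaly == pytest.approx(a / (1 - a), abs=1e-4)


def test_no_discount_equals_undiscounted_life_years(params):
    p = _with(params, discount_rate=0.0)
    trace = run_cohort(p, Stratum("male", False))
    assert trace.total_qaly == pytest.approx(trace.undiscounted_qaly, abs=1e-12)


def test_immortal_cohort_accrues_one_qaly_per_cycle():
    fc = make_degenerate_params("no_cancer")
    trace = run_cohort(fc.params, Stratum("male", False))
    assert trace.total_qaly == pytest.approx(fc.expected, abs=fc.tolerance)


def test_mass_conserved_and_death_monotone(params):
    for stratum in ALL_STRATA:
        trace = run_cohort(params, stratum)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        deaths = trace.occupancy[:, DEATH]
        assert np.all(np.diff(deaths) >= -1e-12)


def test_rerun_is_deterministic(params):
    a = run_cohort(params, Stratum("female", True, adherent=True))
    b = run_cohort(params, Stratum("female", True, adherent=True))
    np.testing.assert_array_equal(a.occupancy, b.occupancy)
    assert a.total_cost == b.total_cost and a.total_qaly == b.total_qaly


def test_discounting_strictly_reduces_qalys(params):
    trace = run_cohort(params, Stratum("male", False))
    assert trace.total_qaly < trace.undiscounted_qaly


def test_weaker_aspirin_weakly_lowers_surveilled_qalys(params):
    qalys = []
    for rr in (0.5, 0.8, 1.0):
        p = _with(params, aspirin_rr_crc=rr)
        qalys.append(arm_outcomes(p, "surveilled").discounted_qaly)
    assert qalys[0] >= qalys[1] >= qalys[2]


def test_surveilled_arm_dominates_on_qalys(params):
    surv = arm_outcomes(params, "surveilled")
    unsurv = arm_outcomes(params, "unsurveilled")
    assert surv.discounted_qaly > unsurv.discounted_qaly


def test_arms_collapse_when_surveillance_has_no_effect():
    fc = make_degenerate_params("collapse_arms")
    surv = arm_outcomes(fc.params, "surveilled")
    unsurv = arm_outcomes(fc.params, "unsurveilled")
    assert abs(surv.discounted_qaly - unsurv.discounted_qaly) <= fc.tolerance


def test_zero_utilities_zero_qalys_costs_unchanged(params):
    doc = params.model_dump(mode="python")
    doc["utilities"] = {
        "well": 0.0,
        "crc_by_stage": {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        "ec": 0.0,
        "second_cancer": 0.0,
        "alive_after_cancer": 0.0,
    }
    p = ParameterSet(**doc)
    trace = run_cohort(p, Stratum("male", False))
    reference = run_cohort(params, Stratum("male", False))
    assert trace.total_qaly == 0.0
    assert trace.total_cost == reference.total_cost


def test_stratum_weights_sum_to_one(params):
    for arm in ("surveilled", "unsurveilled"):
        weights = [w for _, w in stratum_weights(params, arm)]
        assert sum(weights) == pytest.approx(1.0)
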