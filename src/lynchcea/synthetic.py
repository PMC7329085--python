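"""Validation inputs: degenerate parameter sets with closed-form outcomes,
published-style outcome tables for the CEA layer, and an individual-level
microsimulation that serves as an independent oracle for the cohort engine.

The degenerate catalogue collapses the model onto cases whose outcome is
computable without the engine (geometric series, pure counting, perfect
tests), so any disagreement isolates a defect in the cohort algebra rather
than in the inputs.  The microsimulation draws individual annual trajectories
from the *same* transition matrices the cohort engine multiplies, which makes
it a Monte-Carlo cross-check of the cohort algebra specifically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import math

import numpy as np
import pandas as pd

from .markov import Stratum, build_transition_matrix, state_costs, state_utilities
from .parameters import ParameterSet, default_parameters

__all__ = [
    "FixtureCase",
    "DEGENERATE_CASES",
    "make_degenerate_params",
    "microsim_oracle",
    "make_fixture_outcomes",
    "truncated_geometric_qaly",
]


@dataclass
class FixtureCase:
    name: str
    params: ParameterSet
    expected: Any
    tolerance: float
    oracle: str


def truncated_geometric_qaly(q: float, r: float, cycles: int, utility: float = 1.0) -> float:
    """Closed-form discounted QALYs of a well/death model with constant annual
    death probability ``q``: sum over t of u * ((1-q)/(1+r))**t."""
    a = (1.0 - q) / (1.0 + r)
    if a == 1.0:
        return utility * cycles
    return utility * a * (1.0 - a**cycles) / (1.0 - a)


def _overridden(**updates) -> dict:
    doc = default_parameters().model_dump(mode="python")
    doc.update(updates)
    return doc


def _no_cancer_overrides(doc: dict) -> None:
    doc["cum_crc_risk_male"] = 0.0
    doc["cum_crc_risk_female"] = 0.0
    doc["cum_ec_risk_female"] = 0.0
    doc["p_second_cancer"] = 0.0


def _zero_costs(doc: dict) -> None:
    uc = doc["unit_costs"]
    for key in (
        "colonoscopy",
        "gyn_visit_endometrial_sampling",
        "transvaginal_ultrasound",
        "prophylactic_surgery",
        "aspirin_year",
        "ec_management",
        "second_cancer_management",
        "post_cancer_followup",
    ):
        uc[key] = 0.0
    uc["crc_management"] = {s: 0.0 for s in (1, 2, 3, 4)}


DEGENERATE_CASES = (
    "two_state_geometric",
    "no_cancer",
    "perfect_tests",
    "zero_uptake",
    "collapse_arms",
)


def make_degenerate_params(case: str) -> FixtureCase:
    """A parameter set whose expected outcome has a closed form."""
    if case == "two_state_geometric":
        # well/death only: q = 0.05 at every age, utility 1, r = 3.5%
        q = 0.05
        doc = _overridden(max_age=400)
        _no_cancer_overrides(doc)
        _zero_costs(doc)
        doc["background_mortality"] = {
            "male": {"a": -math.log(1.0 - q), "b": 0.0},
            "female": {"a": -math.log(1.0 - q), "b": 0.0},
        }
        doc["utilities"]["well"] = 1.0
        params = ParameterSet(**doc)
        cycles = params.max_age - params.fdr_entry_age
        expected = truncated_geometric_qaly(q, params.discount_rate, cycles)
        return FixtureCase(
            case,
            params,
            expected,
            1e-9,
            "geometric series: sum_t ((1-q)/(1+r))^t, truncated at the horizon",
        )
    if case == "no_cancer":
        # essentially immortal, no disease, undiscounted: QALYs = cycle count
        doc = _overridden(discount_rate=0.0)
        _no_cancer_overrides(doc)
        doc["background_mortality"] = {
            "male": {"a": 1e-15, "b": 0.0},
            "female": {"a": 1e-15, "b": 0.0},
        }
        doc["utilities"]["well"] = 1.0
        params = ParameterSet(**doc)
        expected = float(params.max_age - params.fdr_entry_age)
        return FixtureCase(case, params, expected, 1e-6, "pure cycle counting")
    if case == "perfect_tests":
        doc = _overridden(prop_age_ge70=0.0)
        for test in doc["test_performance"].values():
            test["sensitivity"] = 1.0
            test["specificity"] = 1.0
        params = ParameterSet(**doc)
        expected = params.incident_crc_cases * params.uptake_proband * params.ls_share
        return FixtureCase(
            case, params, expected, 1e-9, "every uptaking LS proband is detected by s1, s2 and s3"
        )
    if case == "zero_uptake":
        params = ParameterSet(**_overridden(uptake_proband=0.0))
        return FixtureCase(
            case, params, 0.0, 0.0, "no proband tested: every strategy equals no screening"
        )
    if case == "collapse_arms":
        doc = _overridden(adherence_colonoscopy=0.0, aspirin_rr_crc=1.0)
        doc["stage_dist_surveilled"] = list(doc["stage_dist_unsurveilled"])
        params = ParameterSet(**doc)
        return FixtureCase(
            case, params, 0.0, 1e-9, "arms share transitions, so QALY difference is 0"
        )
    raise KeyError(f"unknown degenerate case {case!r}; known: {DEGENERATE_CASES}")


def microsim_oracle(
    params: ParameterSet, stratum: Stratum, n_individuals: int, seed: int
) -> tuple[float, float, float, float]:
    """Individual-level Monte-Carlo re-run of one cohort stratum.

    Returns (mean discounted cost, mean discounted QALY, SE cost, SE QALY).
    Transitions are drawn from the same matrices the cohort engine uses.
    """
    if n_individuals < 1000:
        raise ValueError("use at least 1000 individuals for a meaningful oracle")
    entry = params.fdr_entry_age
    T = params.max_age - entry
    u = state_utilities(params)
    r = params.discount_rate
    rng = np.random.default_rng(seed)

    states = np.zeros(n_individuals, dtype=np.int64)
    cost_acc = np.zeros(n_individuals)
    qaly_acc = np.zeros(n_individuals)
    for t in range(1, T + 1):
        P = build_transition_matrix(params, stratum, entry + t - 1)
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0  # guard against float round-off in the draw
        draws = rng.random(n_individuals)
        states = (draws[:, None] > cum[states]).sum(axis=1)
        c = state_costs(params, stratum, entry + t)
        disc = (1.0 + r) ** -t
        cost_acc += c[states] * disc
        qaly_acc += u[states] * disc

    se = lambda x: float(np.std(x, ddof=1) / np.sqrt(n_individuals))
    return float(cost_acc.mean()), float(qaly_acc.mean()), se(cost_acc), se(qaly_acc)


def make_fixture_outcomes() -> dict[str, pd.DataFrame]:
    """Published-style outcome tables used as inputs to the CEA layer.

    ``screening``: per-strategy detected cases and screening / cascade costs.
    ``base`` and ``no_preventive_monitoring``: per-strategy total cost and
    QALY cells, on which ICER arithmetic can be regression-tested exactly.
    """
    screening = pd.DataFrame(
        {
            "strategy": ["no_screening", "s3", "s2", "s1"],
            "ls_cases_detected": [0, 910, 980, 1167],
            "screening_cost_eur": [0.0, 1_753_059.93, 2_714_094.85, 10_388_000.00],
            "fdr_testing_cost_eur": [0.0, 87_257.29, 93_966.50, 111_886.34],
        }
    )
    base = pd.DataFrame(
        {
            "strategy": ["no_screening", "s3", "s2", "s1"],
            "cost_eur": [1_505_199.28, 8_407_988.32, 9_880_720.30, 18_921_334.15],
            "qaly": [3_369.65, 10_703.39, 11_526.37, 13_724.50],
        }
    )
    no_monitoring = pd.DataFrame(
        {
            "strategy": ["no_screening", "s3", "s2", "s1"],
            "cost_eur": [1_441_792.53, 7_350_880.05, 8_742_331.04, 17_565_848.77],
            "qaly": [3_369.65, 10_703.39, 11_526.37, 13_724.50],
        }
    )
    return {"screening": screening, "base": base, "no_preventive_monitoring": no_monitoring}
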