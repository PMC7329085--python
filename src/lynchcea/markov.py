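"""Discrete-time Markov cohort model for FDR carriers of an MMR variant.

Carriers are followed from their entry age to the horizon in 1-year cycles
through the states

    well -> CRC (stage 1-4, tunnel years 1-5)
         -> endometrial cancer (tunnel years 1-5, females)
         -> second cancer (tunnel years 1-5)
         -> alive after cancer (after first / after second cancer)
         -> death (absorbing)

Cancer mortality is stage-specific (CRC), time-since-diagnosis-specific (EC)
and applies only during the 5 tunnel years; survivors of the fifth year are
considered cured and carry background mortality only.  At most one second
cancer can occur, entered from a tunnel exit or from the alive-after-first-
cancer state with a constant annual probability.

Two arms are modelled.  The *surveilled* arm (carriers detected through the
cascade) receives 2-yearly colonoscopy from 25 plus daily aspirin, annual
gynecologic surveillance from 35 and, for the accepting fraction of women,
prophylactic surgery at 45 (which removes endometrial-cancer risk).  The
adherent fraction also benefits from an earlier CRC stage distribution and
the aspirin relative risk; non-adherent members keep the unsurveilled
natural history and accrue no prevention costs.  The *unsurveilled* arm
(undetected carriers) follows standard relative surveillance: colonoscopy
every 5 years from 45.

Within a cycle competing events are applied in the order background death,
then CRC, then EC; rewards accrue on the post-transition occupancy and cycle
t is discounted by (1 + r)^-t.  A half-cycle correction (average of pre- and
post-transition occupancy) is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .parameters import STAGES, ParameterSet

__all__ = [
    "Stratum",
    "CohortTrace",
    "ArmOutcome",
    "N_STATES",
    "STATE_NAMES",
    "WELL",
    "DEATH",
    "crc_state",
    "ec_state",
    "second_state",
    "AFTER_FIRST",
    "AFTER_SECOND",
    "build_transition_matrix",
    "state_costs",
    "state_utilities",
    "run_cohort",
    "arm_outcomes",
    "stratum_weights",
]

# ---- state space ----------------------------------------------------------

WELL = 0


def crc_state(stage: int, year: int) -> int:
    """CRC tunnel state index, stage 1-4, year-since-diagnosis 1-5."""
    return 1 + (stage - 1) * 5 + (year - 1)


def ec_state(year: int) -> int:
    return 21 + (year - 1)


def second_state(year: int) -> int:
    return 26 + (year - 1)


AFTER_FIRST = 31   # alive > 5 years after a first cancer
AFTER_SECOND = 32  # alive > 5 years after a second cancer
DEATH = 33
N_STATES = 34

STATE_NAMES = (
    ["well"]
    + [f"crc_s{s}_y{k}" for s in STAGES for k in range(1, 6)]
    + [f"ec_y{k}" for k in range(1, 6)]
    + [f"second_y{k}" for k in range(1, 6)]
    + ["alive_after_first", "alive_after_second", "death"]
)


@dataclass(frozen=True)
class Stratum:
    """One homogeneous sub-cohort: sex x arm x behaviour."""

    sex: Literal["male", "female"]
    surveilled: bool
    adherent: bool = True   # meaningful only in the surveilled arm
    surgery: bool = False   # accepts prophylactic surgery (surveilled females)

    @property
    def surveillance_active(self) -> bool:
        return self.surveilled and self.adherent


# ---- transition matrix ----------------------------------------------------


def build_transition_matrix(params: ParameterSet, stratum: Stratum, age: float) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix at the given age."""
    if not params.fdr_entry_age <= age <= params.max_age:
        raise ValueError(f"age {age} outside [{params.fdr_entry_age}, {params.max_age}]")
    q = params.background_mortality.annual_q(stratum.sex, age)

    lo, hi = params.crc_risk_window
    p_crc = params.annual_crc_probability(stratum.sex) if lo <= age < hi else 0.0
    if stratum.surveillance_active:
        p_crc *= params.aspirin_rr_crc
    p_ec = 0.0
    if stratum.sex == "female":
        lo_e, hi_e = params.ec_risk_window
        post_surgery = stratum.surgery and age >= params.schedules.prophylactic_surgery_age
        if lo_e <= age < hi_e and not post_surgery:
            p_ec = params.annual_ec_probability()

    stage_dist = params.stage_distribution(surveilled=stratum.surveillance_active)
    p2 = params.p_second_cancer

    P = np.zeros((N_STATES, N_STATES))

    # well: background death, then CRC, then EC, remainder stays well
    P[WELL, DEATH] = q
    crc_mass = (1 - q) * p_crc
    for j, s in enumerate(STAGES):
        P[WELL, crc_state(s, 1)] = crc_mass * stage_dist[j]
    ec_mass = (1 - q) * (1 - p_crc) * p_ec
    P[WELL, ec_state(1)] = ec_mass
    P[WELL, WELL] = 1.0 - q - crc_mass - ec_mass

    def tunnel(row: int, nxt: int | None, annual_death: float, exit_had_first: bool) -> None:
        die = 1.0 - (1.0 - q) * (1.0 - annual_death)
        P[row, DEATH] = die
        if nxt is not None:
            P[row, nxt] = 1.0 - die
        elif exit_had_first:
            P[row, second_state(1)] = (1.0 - die) * p2
            P[row, AFTER_FIRST] = (1.0 - die) * (1.0 - p2)
        else:
            P[row, AFTER_SECOND] = 1.0 - die

    for s in STAGES:
        d = params.stage_survival.crc[s]
        for k in range(1, 5):
            tunnel(crc_state(s, k), crc_state(s, k + 1), d, True)
        tunnel(crc_state(s, 5), None, d, True)
    for k in range(1, 5):
        tunnel(ec_state(k), ec_state(k + 1), params.stage_survival.ec_by_year[k - 1], True)
    tunnel(ec_state(5), None, params.stage_survival.ec_by_year[4], True)
    d2 = params.stage_survival.second_cancer
    for k in range(1, 5):
        tunnel(second_state(k), second_state(k + 1), d2, False)
    tunnel(second_state(5), None, d2, False)

    P[AFTER_FIRST, DEATH] = q
    P[AFTER_FIRST, second_state(1)] = (1.0 - q) * p2
    P[AFTER_FIRST, AFTER_FIRST] = (1.0 - q) * (1.0 - p2)
    P[AFTER_SECOND, DEATH] = q
    P[AFTER_SECOND, AFTER_SECOND] = 1.0 - q
    P[DEATH, DEATH] = 1.0

    rowsum = P.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-9):
        bad = int(np.argmax(np.abs(rowsum - 1.0)))
        raise RuntimeError(f"transition row {STATE_NAMES[bad]} sums to {rowsum[bad]}")
    return P


# ---- rewards --------------------------------------------------------------


def state_costs(params: ParameterSet, stratum: Stratum, age: float) -> np.ndarray:
    """Per-cycle cost (EUR) of occupying each state at the given age.

    Scheduled interventions are costed as expected cost per cycle
    (unit cost / interval) to avoid phase artifacts of the 1-year grid;
    prophylactic surgery is a one-off charge in the cycle reaching the
    surgery age.
    """
    uc = params.unit_costs
    sch = params.schedules
    c = np.zeros(N_STATES)

    well = 0.0
    if stratum.surveillance_active:
        if age >= sch.colonoscopy_start_surveilled:
            well += uc.colonoscopy / sch.colonoscopy_interval_surveilled
            well += uc.aspirin_year
        if stratum.sex == "female":
            post_surgery = stratum.surgery and age >= sch.prophylactic_surgery_age
            if age >= sch.gyn_surveillance_start and not post_surgery:
                well += uc.gyn_visit_endometrial_sampling + uc.transvaginal_ultrasound
            if stratum.surgery and age == sch.prophylactic_surgery_age:
                well += uc.prophylactic_surgery
    elif not stratum.surveilled:
        if age >= sch.colonoscopy_start_unsurveilled:
            well += uc.colonoscopy / sch.colonoscopy_interval_unsurveilled
    # surveilled non-adherent: no prevention costs
    c[WELL] = well

    for s in STAGES:
        c[crc_state(s, 1)] = uc.crc_management[s]
        for k in range(2, 6):
            c[crc_state(s, k)] = uc.post_cancer_followup
    c[ec_state(1)] = uc.ec_management
    c[second_state(1)] = uc.second_cancer_management
    for k in range(2, 6):
        c[ec_state(k)] = uc.post_cancer_followup
        c[second_state(k)] = uc.post_cancer_followup
    c[AFTER_FIRST] = c[AFTER_SECOND] = uc.post_cancer_followup
    return c


def state_utilities(params: ParameterSet) -> np.ndarray:
    u = np.zeros(N_STATES)
    ut = params.utilities
    u[WELL] = ut.well
    for s in STAGES:
        for k in range(1, 6):
            u[crc_state(s, k)] = ut.crc_by_stage[s]
    for k in range(1, 6):
        u[ec_state(k)] = ut.ec
        u[second_state(k)] = ut.second_cancer
    u[AFTER_FIRST] = u[AFTER_SECOND] = ut.alive_after_cancer
    return u


# ---- cohort engine --------------------------------------------------------


@dataclass
class CohortTrace:
    stratum: Stratum
    ages: np.ndarray            # age after each cycle, length T (+ entry age at [0])
    occupancy: np.ndarray       # (T+1, N_STATES); row 0 is the entry distribution
    cycle_cost: np.ndarray      # (T,)
    cycle_cost_disc: np.ndarray
    cycle_qaly: np.ndarray
    cycle_qaly_disc: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cycle_cost_disc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.cycle_qaly_disc.sum())

    @property
    def undiscounted_qaly(self) -> float:
        return float(self.cycle_qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy[1:], columns=STATE_NAMES)
        df.insert(0, "age", self.ages[1:])
        df["cycle_cost_disc"] = self.cycle_cost_disc
        df["cycle_qaly_disc"] = self.cycle_qaly_disc
        return df


def run_cohort(params: ParameterSet, stratum: Stratum) -> CohortTrace:
    """Iterate the cohort from the entry age to the horizon.

    Cycle t uses the transition matrix of the age lived through during the
    cycle (entry_age + t - 1); rewards accrue on the post-transition
    occupancy, valued at the attained age, and are discounted by
    (1 + r)^-t.
    """
    entry = params.fdr_entry_age
    T = params.max_age - entry
    if T < 1:
        raise ValueError("horizon shorter than one cycle")
    u = state_utilities(params)
    r = params.discount_rate

    occ = np.zeros((T + 1, N_STATES))
    occ[0, WELL] = 1.0
    ages = entry + np.arange(T + 1, dtype=float)
    cost = np.zeros(T)
    qaly = np.zeros(T)
    disc = (1.0 + r) ** -np.arange(1, T + 1)

    for t in range(1, T + 1):
        P = build_transition_matrix(params, stratum, entry + t - 1)
        occ[t] = occ[t - 1] @ P
        c = state_costs(params, stratum, entry + t)
        if params.half_cycle_correction:
            basis = 0.5 * (occ[t - 1] + occ[t])
        else:
            basis = occ[t]
        cost[t - 1] = basis @ c
        qaly[t - 1] = basis @ u

    return CohortTrace(
        stratum=stratum,
        ages=ages,
        occupancy=occ,
        cycle_cost=cost,
        cycle_cost_disc=cost * disc,
        cycle_qaly=qaly,
        cycle_qaly_disc=qaly * disc,
    )


# ---- arm aggregation ------------------------------------------------------


@dataclass
class ArmOutcome:
    arm: str
    discounted_cost: float
    discounted_qaly: float


def stratum_weights(params: ParameterSet, arm: str) -> list[tuple[Stratum, float]]:
    """Sub-cohort composition of an arm (weights sum to 1)."""
    f = params.sex_split
    if arm == "unsurveilled":
        return [
            (Stratum("male", False), 1 - f),
            (Stratum("female", False), f),
        ]
    if arm != "surveilled":
        raise ValueError(f"unknown arm {arm!r}")
    adh = params.adherence_colonoscopy
    surg = params.surgery_acceptance
    return [
        (Stratum("male", True, adherent=True), (1 - f) * adh),
        (Stratum("male", True, adherent=False), (1 - f) * (1 - adh)),
        (Stratum("female", True, adherent=True, surgery=True), f * adh * surg),
        (Stratum("female", True, adherent=True, surgery=False), f * adh * (1 - surg)),
        (Stratum("female", True, adherent=False), f * (1 - adh)),
    ]


def arm_outcomes(params: ParameterSet, arm: str) -> ArmOutcome:
    """Discounted lifetime cost and QALYs per average FDR carrier in an arm."""
    cost = 0.0
    qaly = 0.0
    for stratum, w in stratum_weights(params, arm):
        if w == 0.0:
            continue
        trace = run_cohort(params, stratum)
        cost += w * trace.total_cost
        qaly += w * trace.total_qaly
    return ArmOutcome(arm=arm, discounted_cost=cost, discounted_qaly=qaly)
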