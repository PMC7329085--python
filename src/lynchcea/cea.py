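"""Cost-effectiveness layer: strategy totals, ICERs, frontier, NMB and CEAC.

Per-strategy totals combine the one-year screening and cascade costs with the
lifetime discounted costs and QALYs of the carrier relatives they place in
the surveilled (detected) or unsurveilled (undetected) arm.  Incremental
cost-effectiveness ratios are reported both against a fixed reference
(no screening) and sequentially against the previous non-dominated strategy;
the efficiency frontier removes strongly and extendedly dominated options.
The cost-effectiveness acceptability curve (CEAC) is the fraction of PSA
iterations in which each strategy maximises net monetary benefit
NMB = lambda * QALY - cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cascade import CascadeResult
from .diagnostics import ScreeningResult
from .markov import ArmOutcome
from .parameters import ParameterSet

__all__ = [
    "OutcomeSummary",
    "IcerRow",
    "assemble_outcomes",
    "icer",
    "icer_table",
    "efficiency_frontier",
    "nmb",
    "ceac",
]


@dataclass
class OutcomeSummary:
    strategy: str
    total_cost: float
    total_qaly: float


@dataclass
class IcerRow:
    strategy: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str = ""  # "", "dominant", "dominated"


def assemble_outcomes(
    screenings: dict[str, ScreeningResult],
    cascades: dict[str, CascadeResult],
    surveilled: ArmOutcome,
    unsurveilled: ArmOutcome,
    params: ParameterSet,
) -> list[OutcomeSummary]:
    """Per-strategy total discounted cost and QALYs.

    total_cost = screening + cascade + detected carriers x surveilled-arm cost
               + undetected carriers x unsurveilled-arm cost; QALYs analogous
    (screening itself yields no QALYs).
    """
    out = []
    for sid, screening in screenings.items():
        if sid not in cascades:
            raise KeyError(f"missing cascade result for strategy {sid!r}")
        cas = cascades[sid]
        cost = (
            screening.screening_cost
            + cas.cascade_cost
            + cas.carriers_detected * surveilled.discounted_cost
            + cas.carriers_undetected * unsurveilled.discounted_cost
        )
        qaly = (
            cas.carriers_detected * surveilled.discounted_qaly
            + cas.carriers_undetected * unsurveilled.discounted_qaly
        )
        out.append(OutcomeSummary(strategy=sid, total_cost=cost, total_qaly=qaly))
    return out


def icer(a: OutcomeSummary, b: OutcomeSummary) -> IcerRow:
    """ICER of strategy ``a`` relative to comparator ``b``."""
    dc = a.total_cost - b.total_cost
    dq = a.total_qaly - b.total_qaly
    if dq == 0.0:
        label = "dominant" if dc < 0 else ("dominated" if dc > 0 else "")
        return IcerRow(a.strategy, b.strategy, dc, dq, None, label)
    value = dc / dq
    label = ""
    if dq > 0 and dc < 0:
        label = "dominant"
    elif dq < 0 and dc > 0:
        label = "dominated"
    return IcerRow(a.strategy, b.strategy, dc, dq, value, label)


def icer_table(outcomes: list[OutcomeSummary], reference: str = "no_screening") -> pd.DataFrame:
    """Strategies sorted by ascending cost with ICERs vs reference and sequential.

    Full precision is kept in the returned frame; round at presentation time.
    """
    ids = [o.strategy for o in outcomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strategy ids")
    if reference not in ids:
        raise ValueError(f"reference {reference!r} not among outcomes {ids}")
    if len(outcomes) < 2:
        raise ValueError("need at least two outcomes")
    ref = next(o for o in outcomes if o.strategy == reference)
    ordered = sorted(outcomes, key=lambda o: (o.total_cost, o.total_qaly))
    rows = []
    prev = None
    for o in ordered:
        row = {
            "strategy": o.strategy,
            "cost_eur": o.total_cost,
            "qaly": o.total_qaly,
            "icer_vs_reference": np.nan,
            "icer_sequential": np.nan,
            "label": "",
        }
        if o.strategy != reference:
            vs_ref = icer(o, ref)
            row["icer_vs_reference"] = np.nan if vs_ref.icer is None else vs_ref.icer
            row["label"] = vs_ref.label
        if prev is not None:
            seq = icer(o, prev)
            row["icer_sequential"] = np.nan if seq.icer is None else seq.icer
        rows.append(row)
        prev = o
    return pd.DataFrame(rows)


def efficiency_frontier(outcomes: list[OutcomeSummary]) -> pd.DataFrame:
    """Classify strategies as on-frontier / dominated / extendedly dominated.

    Strongly dominated: another option has no higher cost and no fewer QALYs
    (one strictly better).  Extended dominance: an option whose sequential
    ICER exceeds that of the next more effective frontier option is removed
    until frontier ICERs are strictly increasing.
    """
    if not outcomes:
        raise ValueError("no outcomes")
    ordered = sorted(outcomes, key=lambda o: (o.total_cost, -o.total_qaly))
    status = {o.strategy: "frontier" for o in ordered}

    for o in ordered:
        for other in ordered:
            if other.strategy == o.strategy:
                continue
            if (
                other.total_cost <= o.total_cost
                and other.total_qaly >= o.total_qaly
                and (other.total_cost < o.total_cost or other.total_qaly > o.total_qaly)
            ):
                status[o.strategy] = "dominated"
                break

    # extended dominance on the remaining, cost-ordered candidates
    changed = True
    while changed:
        changed = False
        cand = [o for o in ordered if status[o.strategy] == "frontier"]
        for i in range(1, len(cand) - 1):
            lo, mid, hi = cand[i - 1], cand[i], cand[i + 1]
            icer_mid = icer(mid, lo).icer
            icer_hi = icer(hi, mid).icer
            if icer_mid is not None and icer_hi is not None and icer_mid > icer_hi:
                status[mid.strategy] = "extendedly_dominated"
                changed = True
                break

    cand = [o for o in ordered if status[o.strategy] == "frontier"]
    rows = []
    for i, o in enumerate(ordered):
        row = {
            "strategy": o.strategy,
            "cost_eur": o.total_cost,
            "qaly": o.total_qaly,
            "status": status[o.strategy],
            "frontier_icer": np.nan,
        }
        rows.append(row)
    for i in range(1, len(cand)):
        val = icer(cand[i], cand[i - 1]).icer
        for row in rows:
            if row["strategy"] == cand[i].strategy:
                row["frontier_icer"] = np.nan if val is None else val
    return pd.DataFrame(rows)


def nmb(cost: np.ndarray, qaly: np.ndarray, wtp: float) -> np.ndarray:
    """Net monetary benefit at willingness-to-pay ``wtp`` (EUR/QALY)."""
    return wtp * np.asarray(qaly, float) - np.asarray(cost, float)


def ceac(
    costs: np.ndarray,
    qalys: np.ndarray,
    strategies: list[str],
    wtp_grid: np.ndarray,
    mode: str = "joint",
    reference: str = "no_screening",
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    ``costs`` and ``qalys`` are (iterations, strategies) arrays from a PSA.
    ``joint`` mode reports, for each lambda, the fraction of iterations in
    which each strategy has the maximal NMB (ties split evenly); ``pairwise``
    reports the fraction in which each strategy beats the reference.
    """
    wtp_grid = np.asarray(wtp_grid, float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    costs = np.asarray(costs, float)
    qalys = np.asarray(qalys, float)
    n_iter, n_strat = costs.shape
    if n_strat != len(strategies):
        raise ValueError("strategy list does not match array width")

    rows = []
    if mode == "joint":
        for lam in wtp_grid:
            benefit = nmb(costs, qalys, lam)  # (n_iter, n_strat)
            best = benefit.max(axis=1, keepdims=True)
            is_best = np.isclose(benefit, best, rtol=0.0, atol=1e-9)
            shares = is_best / is_best.sum(axis=1, keepdims=True)
            probs = shares.mean(axis=0)
            for sid, p in zip(strategies, probs):
                rows.append({"wtp": float(lam), "strategy": sid, "probability": float(p)})
    elif mode == "pairwise":
        if reference not in strategies:
            raise ValueError(f"reference {reference!r} not among strategies")
        j_ref = strategies.index(reference)
        for lam in wtp_grid:
            benefit = nmb(costs, qalys, lam)
            for j, sid in enumerate(strategies):
                if sid == reference:
                    continue
                diff = benefit[:, j] - benefit[:, j_ref]
                p = float(np.mean((diff > 0) + 0.5 * (diff == 0)))
                rows.append({"wtp": float(lam), "strategy": sid, "probability": p})
    else:
        raise ValueError(f"unknown CEAC mode {mode!r}")
    return pd.DataFrame(rows)


def format_currency(x: float) -> str:
    """Pretty thousands-separated formatting used in the text report."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "-"
    return f"{x:,.2f}"
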