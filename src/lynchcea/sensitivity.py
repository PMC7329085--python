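"""Deterministic (tornado) and probabilistic sensitivity analysis, scenarios.

One-way analysis re-runs the whole pipeline with a single parameter moved to
its low and high value and records the spread of a chosen ICER comparison
(default: the age-targeted strategy against no screening).  The PSA draws
full parameter sets from the method-of-moments distributions and re-runs the
pipeline per draw.  Two scenarios are provided: withdrawing aspirin
prophylaxis (RR back to 1, cost to 0) and excluding the gynecologic
preventive-monitoring cost drivers (costs to 0, effects untouched — a
cost-only scenario that leaves QALYs identical to the base case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet, PsaSpec, SchemaError, _get, _set, sample_psa
from .pipeline import PipelineResult, run_pipeline

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "DEFAULT_TORNADO_PARAMETERS",
    "one_way",
    "tornado",
    "default_ranges",
    "run_psa",
    "scenario",
    "SCENARIOS",
]

logger = logging.getLogger(__name__)

DEFAULT_COMPARISON = ("s3", "no_screening")

# parameters swept by default in the tornado (dotted paths into the config)
DEFAULT_TORNADO_PARAMETERS: tuple[str, ...] = (
    "n_fdr_per_proband",
    "cum_crc_risk_male",
    "cum_crc_risk_female",
    "p_second_cancer",
    "cum_ec_risk_female",
    "uptake_fdr",
    "uptake_proband",
    "adherence_colonoscopy",
    "aspirin_rr_crc",
    "sporadic_mlh1_methylation_share",
    "ls_share",
    "unit_costs.colonoscopy",
    "unit_costs.gyn_visit_endometrial_sampling",
    "test_performance.sequencing.unit_cost",
    "utilities.alive_after_cancer",
)

_UNIT_INTERVAL_PREFIXES = (
    "cum_",
    "uptake_",
    "adherence_",
    "ls_share",
    "p_",
    "prop_",
    "sporadic_",
    "sex_split",
    "surgery_acceptance",
    "utilities",
)


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass
class PSAResult:
    seed: int
    iterations: int
    strategies: list[str]
    costs: np.ndarray  # (iterations_kept, n_strategies)
    qalys: np.ndarray
    excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.costs.shape[0]):
            for j, sid in enumerate(self.strategies):
                rows.append(
                    {
                        "iteration": i,
                        "strategy": sid,
                        "cost_eur": self.costs[i, j],
                        "qaly": self.qalys[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _lookup(doc: dict, path: str) -> float:
    try:
        return float(_get(doc, path))
    except (KeyError, TypeError, IndexError, ValueError):
        raise KeyError(
            f"unknown parameter {path!r}; valid keys are dotted paths into the "
            f"configuration, e.g. {DEFAULT_TORNADO_PARAMETERS[:4]}"
        ) from None


def _with(params: ParameterSet, path: str, value: float) -> ParameterSet:
    doc = params.model_dump(mode="python")
    _lookup(doc, path)
    _set(doc, path, value)
    try:
        return ParameterSet(**doc)
    except Exception as err:  # pydantic ValidationError
        raise SchemaError(f"value {value} invalid for {path}: {err}") from err


def _comparison_icer(result: PipelineResult, comparison: tuple[str, str]) -> float:
    value = result.icer(*comparison)
    return np.nan if value is None else float(value)


def one_way(
    params: ParameterSet,
    parameter: str,
    low: float,
    high: float,
    comparison: tuple[str, str] = DEFAULT_COMPARISON,
) -> TornadoEntry:
    """Re-run the full pipeline at the low and high value of one parameter."""
    base = _lookup(params.model_dump(mode="python"), parameter)
    if not low <= base <= high:
        raise ValueError(f"{parameter}: require low <= base <= high, got {low} <= {base} <= {high}")
    icer_low = _comparison_icer(run_pipeline(_with(params, parameter, low)), comparison)
    icer_high = _comparison_icer(run_pipeline(_with(params, parameter, high)), comparison)
    return TornadoEntry(parameter, low, high, icer_low, icer_high)


def default_ranges(params: ParameterSet, rel: float = 0.2) -> dict[str, tuple[float, float]]:
    """+/- ``rel`` around base values, truncated to valid domains."""
    doc = params.model_dump(mode="python")
    ranges = {}
    for path in DEFAULT_TORNADO_PARAMETERS:
        base = float(_get(doc, path))
        lo, hi = base * (1 - rel), base * (1 + rel)
        if path.startswith(_UNIT_INTERVAL_PREFIXES) or path.endswith(
            ("sensitivity", "specificity")
        ):
            hi = min(hi, 1.0)
        ranges[path] = (lo, hi)
    return ranges


def tornado(
    params: ParameterSet,
    ranges: dict[str, tuple[float, float]] | None = None,
    comparison: tuple[str, str] = DEFAULT_COMPARISON,
) -> pd.DataFrame:
    """One-way entries for every parameter, sorted by descending spread."""
    if ranges is None:
        ranges = default_ranges(params)
    if not ranges:
        raise ValueError("empty tornado ranges")
    entries = [one_way(params, name, lo, hi, comparison) for name, (lo, hi) in ranges.items()]
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "spread": [e.spread for e in entries],
        }
    )


def run_psa(
    params: ParameterSet,
    spec: PsaSpec,
    strategies: tuple[str, ...] = ("no_screening", "s3", "s2", "s1"),
) -> PSAResult:
    """Full pipeline per PSA draw; non-finite iterations are flagged and dropped."""
    draws = sample_psa(params, spec)
    costs = np.empty((len(draws), len(strategies)))
    qalys = np.empty_like(costs)
    keep = np.ones(len(draws), dtype=bool)
    for i, draw in enumerate(draws):
        result = run_pipeline(draw, strategies=strategies)
        for j, sid in enumerate(strategies):
            o = result.outcome(sid)
            costs[i, j] = o.total_cost
            qalys[i, j] = o.total_qaly
        if not (np.isfinite(costs[i]).all() and np.isfinite(qalys[i]).all()):
            keep[i] = False
            logger.warning("PSA iteration %d produced non-finite outcomes; excluded", i)
    excluded = int((~keep).sum())
    return PSAResult(
        seed=spec.seed,
        iterations=spec.iterations,
        strategies=list(strategies),
        costs=costs[keep],
        qalys=qalys[keep],
        excluded=excluded,
    )


def _apply_no_aspirin(params: ParameterSet) -> ParameterSet:
    doc = params.model_dump(mode="python")
    doc["aspirin_rr_crc"] = 1.0
    doc["unit_costs"]["aspirin_year"] = 0.0
    return ParameterSet(**doc)


def _apply_no_gyn_monitoring(params: ParameterSet) -> ParameterSet:
    doc = params.model_dump(mode="python")
    doc["unit_costs"]["gyn_visit_endometrial_sampling"] = 0.0
    doc["unit_costs"]["transvaginal_ultrasound"] = 0.0
    doc["unit_costs"]["prophylactic_surgery"] = 0.0
    return ParameterSet(**doc)


SCENARIOS = {
    "no_aspirin": _apply_no_aspirin,
    "no_gyn_monitoring": _apply_no_gyn_monitoring,
}


def scenario(params: ParameterSet, name: str) -> PipelineResult:
    """Run a named scenario through the full pipeline."""
    try:
        transform = SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}") from None
    return run_pipeline(transform(params))
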