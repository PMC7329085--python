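"""Diagnostic decision trees for identifying Lynch syndrome among CRC probands.

Four options are modelled on the annual cohort of newly diagnosed colorectal
cancer patients:

* ``no_screening`` — comparator, nobody is tested;
* ``s1`` — germline sequencing of all four MMR genes for every consenting
  proband, no prior tumor analysis;
* ``s2`` — tumor IHC for the four MMR proteins; MLH1-absent tumors are
  triaged with methylation-specific MLPA (promoter methylation indicates a
  sporadic tumor); the remaining screen-positives get targeted germline
  sequencing;
* ``s3`` — as ``s2`` for probands diagnosed before age 70; probands aged
  >= 70 are first assessed against the revised Bethesda criteria and only
  fulfilling patients continue to the tumor work-up.

The cohort is propagated by expectation (fractional persons); every
root-to-leaf path of a tree contributes its probability mass to the test
volumes, costs and detection counts.  Reported case counts are rounded down,
matching the deterministic cohort convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .parameters import GENES, ParameterSet

__all__ = [
    "StrategyDefinition",
    "ScreeningResult",
    "STRATEGIES",
    "STRATEGY_ORDER",
    "eligible_cohort",
    "run_strategy",
    "strategy_comparison_table",
]


@dataclass(frozen=True)
class StrategyDefinition:
    """A diagnostic pathway.

    ``paths`` (built lazily from a ParameterSet) enumerate every root-to-leaf
    route as ``(weight, tests, detected)`` separately for the LS-positive and
    LS-negative sub-cohorts; weights within each sub-cohort sum to 1.
    """

    id: str
    description: str
    sequencing_first: bool = False  # s1: sequence everyone, no tumor triage
    tumor_triage: bool = False      # s2/s3: IHC -> MS-MLPA -> sequencing
    bethesda_age_gate: bool = False  # s3: gate the >=70 subcohort on Bethesda


STRATEGIES: dict[str, StrategyDefinition] = {
    "no_screening": StrategyDefinition("no_screening", "no proband testing"),
    "s1": StrategyDefinition("s1", "universal germline MMR sequencing", sequencing_first=True),
    "s2": StrategyDefinition("s2", "IHC + MS-MLPA triage, then sequencing", tumor_triage=True),
    "s3": StrategyDefinition(
        "s3",
        "age-targeted: revised Bethesda gate at >=70, then IHC + MS-MLPA",
        tumor_triage=True,
        bethesda_age_gate=True,
    ),
}
STRATEGY_ORDER = ("no_screening", "s3", "s2", "s1")


@dataclass
class ScreeningResult:
    strategy: str
    tested_probands: float
    tests_performed: dict[str, float] = field(default_factory=dict)
    true_positive_probands: float = 0.0
    false_negative_probands: float = 0.0
    screening_cost: float = 0.0

    @property
    def cost_per_case_detected(self) -> float:
        if self.true_positive_probands == 0:
            return math.nan
        return self.screening_cost / self.true_positive_probands

    @property
    def reported_cases(self) -> int:
        """Detected LS probands rounded down, the convention used in reports."""
        return int(math.floor(self.true_positive_probands + 1e-9))


def eligible_cohort(params: ParameterSet) -> tuple[float, float, float]:
    """Size of the tested proband cohort and its LS split, in expected persons."""
    tested = params.incident_crc_cases * params.uptake_proband
    ls_positive = tested * params.ls_share
    return tested, ls_positive, tested - ls_positive


Path = tuple[float, tuple[str, ...], bool]  # (weight, tests, detected-as-LS)


def _triage_paths_ls(params: ParameterSet) -> list[Path]:
    """IHC -> MS-MLPA -> sequencing pathway for one unit of LS probands."""
    ihc = params.test_performance["ihc"]
    mlpa = params.test_performance["ms_mlpa"]
    seq = params.test_performance["sequencing"]
    paths: list[Path] = []
    for gene in GENES:
        g = params.gene_distribution[gene]
        if g == 0:
            continue
        if gene == "MLH1":
            # hereditary MLH1 loss: promoter unmethylated; MS-MLPA must call it so
            hit = g * ihc.sensitivity
            onward = hit * mlpa.specificity
            paths.append((onward * seq.sensitivity, ("ihc", "ms_mlpa", "sequencing"), True))
            paths.append((onward * (1 - seq.sensitivity), ("ihc", "ms_mlpa", "sequencing"), False))
            paths.append((hit * (1 - mlpa.specificity), ("ihc", "ms_mlpa"), False))
            paths.append((g * (1 - ihc.sensitivity), ("ihc",), False))
        else:
            hit = g * ihc.sensitivity
            paths.append((hit * seq.sensitivity, ("ihc", "sequencing"), True))
            paths.append((hit * (1 - seq.sensitivity), ("ihc", "sequencing"), False))
            paths.append((g * (1 - ihc.sensitivity), ("ihc",), False))
    return paths


def _triage_paths_sporadic(params: ParameterSet) -> list[Path]:
    """Same pathway for one unit of non-LS (sporadic) probands; never detected."""
    ihc = params.test_performance["ihc"]
    mlpa = params.test_performance["ms_mlpa"]
    m = params.sporadic_mlh1_methylation_share
    paths: list[Path] = []
    # sporadic tumors with genuine MLH1 loss by promoter methylation
    hit = m * ihc.sensitivity
    paths.append((hit * mlpa.sensitivity, ("ihc", "ms_mlpa"), False))  # methylation found, stop
    paths.append((hit * (1 - mlpa.sensitivity), ("ihc", "ms_mlpa", "sequencing"), False))
    paths.append((m * (1 - ihc.sensitivity), ("ihc",), False))
    # MMR-proficient sporadics: IHC false positives, pattern per gene distribution
    fp = (1 - m) * (1 - ihc.specificity)
    p_mlh1 = params.gene_distribution["MLH1"]
    fp_mlh1 = fp * p_mlh1
    paths.append((fp_mlh1 * mlpa.specificity, ("ihc", "ms_mlpa", "sequencing"), False))
    paths.append((fp_mlh1 * (1 - mlpa.specificity), ("ihc", "ms_mlpa"), False))
    paths.append((fp * (1 - p_mlh1), ("ihc", "sequencing"), False))
    paths.append(((1 - m) * ihc.specificity, ("ihc",), False))
    return paths


def _prefix(paths: list[Path], scale: float, tests: tuple[str, ...]) -> list[Path]:
    return [(scale * w, tests + t, d) for w, t, d in paths]


def strategy_paths(strategy: StrategyDefinition, params: ParameterSet) -> tuple[list[Path], list[Path]]:
    """Root-to-leaf paths for one unit of LS and one unit of sporadic probands."""
    if strategy.sequencing_first:
        seq = params.test_performance["sequencing"]
        ls = [
            (seq.sensitivity, ("sequencing",), True),
            (1 - seq.sensitivity, ("sequencing",), False),
        ]
        sporadic = [(1.0, ("sequencing",), False)]
        return ls, sporadic
    if not strategy.tumor_triage:
        return [(1.0, (), False)], [(1.0, (), False)]
    ls = _triage_paths_ls(params)
    sporadic = _triage_paths_sporadic(params)
    if strategy.bethesda_age_gate:
        beth = params.test_performance["bethesda"]
        young = 1 - params.prop_age_ge70
        old = params.prop_age_ge70
        ls = _prefix(ls, young, ()) + _prefix(ls, old * beth.sensitivity, ("bethesda",)) + [
            (old * (1 - beth.sensitivity), ("bethesda",), False)
        ]
        sporadic = (
            _prefix(sporadic, young, ())
            + _prefix(sporadic, old * (1 - beth.specificity), ("bethesda",))
            + [(old * beth.specificity, ("bethesda",), False)]
        )
    return ls, sporadic


def run_strategy(strategy: StrategyDefinition | str, params: ParameterSet) -> ScreeningResult:
    """Propagate the expected proband cohort through one diagnostic pathway."""
    if isinstance(strategy, str):
        try:
            strategy = STRATEGIES[strategy]
        except KeyError:
            raise KeyError(f"unknown strategy {strategy!r}; known: {sorted(STRATEGIES)}") from None
    tested, ls_pos, ls_neg = eligible_cohort(params)
    ls_paths, sp_paths = strategy_paths(strategy, params)

    tests: dict[str, float] = {}
    detected = 0.0
    for count, paths in ((ls_pos, ls_paths), (ls_neg, sp_paths)):
        for weight, path_tests, is_detected in paths:
            mass = count * weight
            if mass == 0.0:
                continue
            for t in path_tests:
                tests[t] = tests.get(t, 0.0) + mass
            if is_detected:
                detected += mass

    for t in tests:
        if t not in params.test_performance:
            raise KeyError(f"strategy references test {t!r} absent from test_performance")
    cost = sum(n * params.test_performance[t].unit_cost for t, n in tests.items())
    return ScreeningResult(
        strategy=strategy.id,
        tested_probands=tested if strategy.id != "no_screening" else 0.0,
        tests_performed=tests,
        true_positive_probands=detected,
        false_negative_probands=ls_pos - detected,
        screening_cost=cost,
    )


def strategy_comparison_table(results: list[ScreeningResult]) -> pd.DataFrame:
    """One row per strategy: detections, screening cost, cost per case detected."""
    if not results:
        raise ValueError("at least one ScreeningResult required")
    rows = [
        {
            "strategy": r.strategy,
            "ls_cases_detected": r.reported_cases,
            "screening_cost_eur": r.screening_cost,
            "cost_per_case_detected_eur": r.cost_per_case_detected,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
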