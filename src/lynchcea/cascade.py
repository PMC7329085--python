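"""Cascade predictive testing of first-degree relatives (FDRs).

Each proband with a confirmed pathogenic variant unlocks targeted
single-variant testing for their first-degree relatives.  The predictive test
is assumed perfect (sensitivity = specificity = 100%), so relatives split
cleanly into detected carriers (who enter intensified surveillance),
non-carriers (test cost only, no downstream states) and undetected carriers —
relatives of probands who were missed or declined testing, plus carrier
relatives who declined the predictive test themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

from .diagnostics import ScreeningResult
from .parameters import ParameterSet

__all__ = ["CascadeResult", "run_cascade", "total_fdr_carriers"]


@dataclass
class CascadeResult:
    strategy: str
    probands_detected: float
    fdrs_eligible: float
    fdrs_tested: float
    carriers_detected: float
    carriers_undetected: float
    noncarriers_tested: float
    cascade_cost: float


def total_fdr_carriers(params: ParameterSet) -> float:
    """Expected carriers among FDRs of *all* LS probands in one incidence year.

    Independent of the screening strategy: the pool of carrier relatives is
    fixed by epidemiology; strategies only change how many are found.
    """
    return (
        params.incident_crc_cases
        * params.ls_share
        * params.n_fdr_per_proband
        * params.p_fdr_carrier
    )


def run_cascade(screening: ScreeningResult, params: ParameterSet) -> CascadeResult:
    """Convert detected probands into tested relatives and detected carriers."""
    test = params.test_performance["fdr_predictive"]
    detected_probands = screening.true_positive_probands
    fdrs_eligible = detected_probands * params.n_fdr_per_proband
    fdrs_tested = fdrs_eligible * params.uptake_fdr
    carriers_detected = fdrs_tested * params.p_fdr_carrier * test.sensitivity
    noncarriers_tested = fdrs_tested * (1.0 - params.p_fdr_carrier)
    carriers_undetected = total_fdr_carriers(params) - carriers_detected
    return CascadeResult(
        strategy=screening.strategy,
        probands_detected=detected_probands,
        fdrs_eligible=fdrs_eligible,
        fdrs_tested=fdrs_tested,
        carriers_detected=carriers_detected,
        carriers_undetected=carriers_undetected,
        noncarriers_tested=noncarriers_tested,
        cascade_cost=fdrs_tested * test.unit_cost,
    )
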