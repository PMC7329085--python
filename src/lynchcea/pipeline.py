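"""End-to-end evaluation of one parameter set: trees -> cascade -> Markov -> CEA."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cascade as cascade_mod
from . import cea, diagnostics, markov
from .parameters import ParameterSet

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    params: ParameterSet
    screenings: dict[str, diagnostics.ScreeningResult]
    cascades: dict[str, cascade_mod.CascadeResult]
    arm_surveilled: markov.ArmOutcome
    arm_unsurveilled: markov.ArmOutcome
    outcomes: list[cea.OutcomeSummary] = field(default_factory=list)

    def outcome(self, strategy: str) -> cea.OutcomeSummary:
        for o in self.outcomes:
            if o.strategy == strategy:
                return o
        raise KeyError(strategy)

    def icer(self, strategy: str, comparator: str) -> float | None:
        return cea.icer(self.outcome(strategy), self.outcome(comparator)).icer

    def table1(self) -> pd.DataFrame:
        df = diagnostics.strategy_comparison_table(
            [self.screenings[s] for s in diagnostics.STRATEGY_ORDER]
        )
        df["cascade_cost_eur"] = [
            self.cascades[s].cascade_cost for s in diagnostics.STRATEGY_ORDER
        ]
        return df

    def table2(self, reference: str = "no_screening") -> pd.DataFrame:
        return cea.icer_table(self.outcomes, reference=reference)


def run_pipeline(
    params: ParameterSet, strategies: tuple[str, ...] = diagnostics.STRATEGY_ORDER
) -> PipelineResult:
    """Run every strategy through screening, cascade and the Markov arms."""
    screenings = {s: diagnostics.run_strategy(s, params) for s in strategies}
    cascades = {s: cascade_mod.run_cascade(screenings[s], params) for s in strategies}
    arm_s = markov.arm_outcomes(params, "surveilled")
    arm_u = markov.arm_outcomes(params, "unsurveilled")
    outcomes = cea.assemble_outcomes(screenings, cascades, arm_s, arm_u, params)
    return PipelineResult(
        params=params,
        screenings=screenings,
        cascades=cascades,
        arm_surveilled=arm_s,
        arm_unsurveilled=arm_u,
        outcomes=outcomes,
    )
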