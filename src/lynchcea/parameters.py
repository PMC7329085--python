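"""Parameter space of the Lynch syndrome screening cost-effectiveness model.

Every model input — epidemiology, diagnostic test performance, uptake and
adherence, natural-history risks, stage distributions, unit costs, utility
weights and economic settings — lives in a single validated
:class:`ParameterSet`.  Each parameter carries a provenance tag:

``printed``
    stated in the main text of the source cost-effectiveness study,
``supplementary_placeholder``
    only available in supplementary material we do not assert; shipped as a
    plausible, clearly flagged default that users should override,
``assumption``
    a modelling assumption (ours or the original study's).

Probabilistic-sensitivity-analysis sampling distributions (beta for
probabilities and utilities, gamma for costs, Dirichlet for compositional
vectors) are auto-derived from base-case values by method of moments.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "TestPerformance",
    "GompertzMortality",
    "BackgroundMortality",
    "StageSurvival",
    "Schedules",
    "UnitCosts",
    "Utilities",
    "ParameterSet",
    "PsaSpec",
    "SchemaError",
    "load_parameters",
    "write_parameters",
    "default_parameters",
    "cumulative_to_annual",
    "sample_psa",
]

STAGES = (1, 2, 3, 4)
GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
TESTS = ("ihc", "ms_mlpa", "bethesda", "sequencing", "fdr_predictive")

Proportion = Field(ge=0.0, le=1.0)


class SchemaError(ValueError):
    """A configuration document does not match the parameter schema."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TestPerformance(_Model):
    sensitivity: float = Proportion
    specificity: float = Proportion
    unit_cost: float = Field(ge=0.0)


class GompertzMortality(_Model):
    """Two-parameter exponential-growth hazard mu(x) = a * exp(b * x)."""

    a: float = Field(gt=0.0)
    b: float = Field(ge=0.0)

    def annual_death_probability(self, age: float) -> float:
        return 1.0 - math.exp(-self.a * math.exp(self.b * age))


class BackgroundMortality(_Model):
    male: GompertzMortality
    female: GompertzMortality
    # optional life-table override: sex -> annual death probability indexed by age from 0
    life_table: dict[str, list[float]] | None = None

    def annual_q(self, sex: str, age: float) -> float:
        if self.life_table is not None and sex in self.life_table:
            table = self.life_table[sex]
            idx = min(int(age), len(table) - 1)
            return float(table[idx])
        return getattr(self, sex).annual_death_probability(age)


class StageSurvival(_Model):
    """Annual death probabilities during the five post-diagnosis years.

    CRC mortality is stage-dependent and constant across the five years;
    endometrial-cancer mortality depends on time since diagnosis and not on
    carrier status; a single rate is used for second cancers.
    """

    crc: dict[int, float]
    ec_by_year: list[float]
    second_cancer: float = Proportion

    @field_validator("crc")
    @classmethod
    def _crc_keys(cls, v: dict[int, float]) -> dict[int, float]:
        if set(v) != set(STAGES):
            raise ValueError(f"crc stage-survival must have keys {STAGES}, got {sorted(v)}")
        for s, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"crc stage {s} annual death probability {p} outside [0, 1]")
        return v

    @field_validator("ec_by_year")
    @classmethod
    def _ec_len(cls, v: list[float]) -> list[float]:
        if len(v) != 5:
            raise ValueError("ec_by_year must list 5 annual death probabilities")
        if any(not 0.0 <= p <= 1.0 for p in v):
            raise ValueError("ec_by_year probabilities must lie in [0, 1]")
        return v


class Schedules(_Model):
    """Intervention timing, in years of age."""

    colonoscopy_interval_surveilled: float = Field(default=2.0, gt=0)
    colonoscopy_start_surveilled: int = 25
    gyn_surveillance_start: int = 35
    prophylactic_surgery_age: int = 45
    colonoscopy_interval_unsurveilled: float = Field(default=5.0, gt=0)
    colonoscopy_start_unsurveilled: int = 45


class UnitCosts(_Model):
    """Direct medical unit costs, EUR."""

    colonoscopy: float = Field(ge=0)
    gyn_visit_endometrial_sampling: float = Field(ge=0)
    transvaginal_ultrasound: float = Field(ge=0)
    prophylactic_surgery: float = Field(ge=0)
    aspirin_year: float = Field(ge=0)
    crc_management: dict[int, float]
    ec_management: float = Field(ge=0)
    second_cancer_management: float = Field(ge=0)
    post_cancer_followup: float = Field(ge=0)

    @field_validator("crc_management")
    @classmethod
    def _stages(cls, v: dict[int, float]) -> dict[int, float]:
        if set(v) != set(STAGES):
            raise ValueError(f"crc_management must have stage keys {STAGES}")
        if any(c < 0 for c in v.values()):
            raise ValueError("costs must be non-negative")
        return v


class Utilities(_Model):
    """Health-state utility weights in [0, 1]."""

    well: float = Proportion
    crc_by_stage: dict[int, float]
    ec: float = Proportion
    second_cancer: float = Proportion
    alive_after_cancer: float = Proportion

    @field_validator("crc_by_stage")
    @classmethod
    def _stages(cls, v: dict[int, float]) -> dict[int, float]:
        if set(v) != set(STAGES):
            raise ValueError(f"crc_by_stage must have stage keys {STAGES}")
        if any(not 0.0 <= u <= 1.0 for u in v.values()):
            raise ValueError("utilities must lie in [0, 1]")
        return v


class ParameterSet(_Model):
    """Complete, validated input space of the model."""

    # epidemiology of the proband cohort
    incident_crc_cases: float = Field(gt=0)
    crc_incidence_rate: float = Proportion  # informational
    ls_share: float = Proportion
    prop_age_ge70: float = Proportion
    sex_split: float = Proportion  # proportion female among FDR carriers

    # diagnostic tests
    test_performance: dict[str, TestPerformance]
    gene_distribution: dict[str, float]
    sporadic_mlh1_methylation_share: float = Proportion

    # uptake / family structure
    uptake_proband: float = Proportion
    uptake_fdr: float = Proportion
    n_fdr_per_proband: float = Field(ge=0)
    p_fdr_carrier: float = Proportion
    fdr_entry_age: int = Field(ge=0)

    # prevention behaviour
    adherence_colonoscopy: float = Proportion
    surgery_acceptance: float = Proportion

    # natural history
    cum_crc_risk_male: float = Proportion
    cum_crc_risk_female: float = Proportion
    crc_risk_window: tuple[int, int]
    cum_ec_risk_female: float = Proportion
    ec_risk_window: tuple[int, int]
    stage_dist_surveilled: list[float]
    stage_dist_unsurveilled: list[float]
    stage_survival: StageSurvival
    p_second_cancer: float = Proportion
    aspirin_rr_crc: float = Field(ge=0.0, le=1.5)
    background_mortality: BackgroundMortality

    # costs, utilities, economics
    schedules: Schedules = Schedules()
    unit_costs: UnitCosts
    utilities: Utilities
    discount_rate: float = Field(ge=0.0)
    wtp_threshold: float = Field(ge=0.0)
    max_age: int = Field(gt=0)
    half_cycle_correction: bool = False

    provenance: dict[str, Literal["printed", "supplementary_placeholder", "assumption"]] = Field(
        default_factory=dict
    )

    @field_validator("gene_distribution")
    @classmethod
    def _genes(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(GENES):
            raise ValueError(f"gene_distribution must have keys {GENES}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"gene_distribution sums to {total}, expected 1 within 1e-9")
        return v

    @field_validator("test_performance")
    @classmethod
    def _tests(cls, v: dict[str, TestPerformance]) -> dict[str, TestPerformance]:
        missing = [t for t in TESTS if t not in v]
        if missing:
            raise ValueError(f"test_performance missing tests: {missing}")
        return v

    @field_validator("stage_dist_surveilled", "stage_dist_unsurveilled")
    @classmethod
    def _stage_dist(cls, v: list[float]) -> list[float]:
        if len(v) != 4:
            raise ValueError("stage distribution must have 4 entries (stages 1-4)")
        if any(p < 0 for p in v):
            raise ValueError("stage distribution entries must be non-negative")
        if sum(v) <= 0:
            raise ValueError("stage distribution must have positive mass")
        return v

    @model_validator(mode="after")
    def _windows(self) -> "ParameterSet":
        for name in ("crc_risk_window", "ec_risk_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy start < end, got ({lo}, {hi})")
        if self.max_age <= self.fdr_entry_age:
            raise ValueError("max_age must exceed fdr_entry_age")
        return self

    # --- normalized accessors -------------------------------------------------

    def stage_distribution(self, surveilled: bool) -> np.ndarray:
        """Stage composition, renormalized to sum exactly to 1.

        The surveilled distribution is renormalized because the source values
        (69.4 / 25.0 / 5.6 / 0.04 %) total 100.04 %.
        """
        raw = np.asarray(
            self.stage_dist_surveilled if surveilled else self.stage_dist_unsurveilled, float
        )
        return raw / raw.sum()

    def annual_crc_probability(self, sex: str) -> float:
        cum = self.cum_crc_risk_male if sex == "male" else self.cum_crc_risk_female
        lo, hi = self.crc_risk_window
        return cumulative_to_annual(cum, hi - lo)

    def annual_ec_probability(self) -> float:
        lo, hi = self.ec_risk_window
        return cumulative_to_annual(self.cum_ec_risk_female, hi - lo)


class PsaSpec(_Model):
    """Probabilistic sensitivity analysis specification.

    Hyperparameters are derived by method of moments from the base-case value
    and a coefficient of variation ``cv``: probabilities and utilities get a
    beta with sd = cv * min(m, 1-m); costs a gamma with sd = cv * m;
    compositional vectors a Dirichlet with concentration 1/cv**2 - 1.  With
    ``cv = 0`` every draw equals the base case.
    """

    iterations: int = Field(default=1000, ge=1)
    seed: int = 0
    cv: float = Field(default=0.2, ge=0.0, lt=1.0)


# --------------------------------------------------------------------------
# conversions


def cumulative_to_annual(cum_risk: float, window_years: float) -> float:
    """Convert a cumulative risk over a window to a constant annual probability.

    Solves (1 - p)**window_years = 1 - cum_risk.
    """
    if not 0.0 <= cum_risk <= 1.0:
        raise ValueError(f"cumulative risk {cum_risk} outside [0, 1]")
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    if cum_risk == 1.0:
        return 1.0
    return 1.0 - (1.0 - cum_risk) ** (1.0 / window_years)


# --------------------------------------------------------------------------
# config I/O


def _validate(doc: dict) -> ParameterSet:
    try:
        return ParameterSet(**doc)
    except ValidationError as err:
        lines = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            lines.append(f"{loc}: {e['msg']}")
        raise SchemaError("invalid parameter configuration:\n  " + "\n  ".join(lines)) from err


def load_parameters(config_path: str | Path) -> ParameterSet:
    """Load and validate a complete YAML/JSON parameter configuration."""
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path} does not contain a mapping")
    return _validate(doc)


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialize a ParameterSet to YAML so that load_parameters round-trips."""
    doc = params.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_parameters() -> ParameterSet:
    """The bundled base-case configuration."""
    with resources.files("lynchcea.data").joinpath("default.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    return _validate(doc)


# --------------------------------------------------------------------------
# PSA sampling

# (dotted path, family); compositional entries are sampled jointly
_BETA_PATHS: tuple[str, ...] = (
    "ls_share",
    "prop_age_ge70",
    "sporadic_mlh1_methylation_share",
    "uptake_proband",
    "uptake_fdr",
    "p_fdr_carrier",
    "adherence_colonoscopy",
    "surgery_acceptance",
    "cum_crc_risk_male",
    "cum_crc_risk_female",
    "cum_ec_risk_female",
    "p_second_cancer",
    "aspirin_rr_crc",
    "stage_survival.second_cancer",
    "utilities.well",
    "utilities.ec",
    "utilities.second_cancer",
    "utilities.alive_after_cancer",
)
_GAMMA_PATHS: tuple[str, ...] = (
    "n_fdr_per_proband",
    "unit_costs.colonoscopy",
    "unit_costs.gyn_visit_endometrial_sampling",
    "unit_costs.transvaginal_ultrasound",
    "unit_costs.prophylactic_surgery",
    "unit_costs.aspirin_year",
    "unit_costs.ec_management",
    "unit_costs.second_cancer_management",
    "unit_costs.post_cancer_followup",
)


def _get(doc: dict, path: str):
    node = doc
    for key in path.split("."):
        if isinstance(node, list):
            node = node[int(key)]
        elif key in node:
            node = node[key]
        else:
            node = node[int(key)]
    return node


def _set(doc: dict, path: str, value) -> None:
    """Set a dotted path; numeric keys address list positions or int dict keys."""
    keys = path.split(".")
    node = doc
    for key in keys[:-1]:
        if isinstance(node, list):
            node = node[int(key)]
        elif key in node:
            node = node[key]
        else:
            node = node[int(key)]
    last = keys[-1]
    if isinstance(node, list):
        node[int(last)] = value
    elif last in node:
        node[last] = value
    else:
        node[int(last)] = value


def _beta_draws(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0 or mean in (0.0, 1.0):
        return np.full(n, mean)
    sd = cv * min(mean, 1.0 - mean)
    var = sd * sd
    nu = mean * (1.0 - mean) / var - 1.0  # > 0 because sd < sqrt(m(1-m))
    return rng.beta(mean * nu, (1.0 - mean) * nu, size=n)


def _gamma_draws(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0 or mean == 0.0:
        return np.full(n, mean)
    shape = 1.0 / (cv * cv)
    return rng.gamma(shape, mean / shape, size=n)


def _dirichlet_draws(rng: np.random.Generator, probs: np.ndarray, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.tile(probs, (n, 1))  # keep the base vector bit-identical
    probs = probs / probs.sum()
    alpha0 = max(1.0 / (cv * cv) - 1.0, 1e-6)
    alpha = np.clip(probs * alpha0, 1e-9, None)
    return rng.dirichlet(alpha, size=n)


def sample_psa(params: ParameterSet, spec: PsaSpec) -> list[ParameterSet]:
    """Draw ``spec.iterations`` parameter sets around the base case.

    Identical seed, identical sequence; compositional draws remain valid
    compositions; with ``cv = 0`` every draw equals the base case.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.iterations
    base = params.model_dump(mode="python")

    scalar_draws: dict[str, np.ndarray] = {}
    for path in _BETA_PATHS:
        m = float(_get(base, path))
        if not np.isfinite(m):
            raise ValueError(f"non-finite base value for {path}")
        if m > 1.0:  # aspirin RR above 1: held fixed rather than forced into a beta
            scalar_draws[path] = np.full(n, m)
        else:
            scalar_draws[path] = _beta_draws(rng, m, spec.cv, n)
    for path in _GAMMA_PATHS:
        m = float(_get(base, path))
        scalar_draws[path] = _gamma_draws(rng, m, spec.cv, n)
    for stage in STAGES:
        m = float(base["stage_survival"]["crc"][stage])
        scalar_draws[f"stage_survival.crc.{stage}"] = _beta_draws(rng, m, spec.cv, n)
        mc = float(base["unit_costs"]["crc_management"][stage])
        scalar_draws[f"unit_costs.crc_management.{stage}"] = _gamma_draws(rng, mc, spec.cv, n)
        mu = float(base["utilities"]["crc_by_stage"][stage])
        scalar_draws[f"utilities.crc_by_stage.{stage}"] = _beta_draws(rng, mu, spec.cv, n)
    for k in range(5):
        m = float(base["stage_survival"]["ec_by_year"][k])
        scalar_draws[f"stage_survival.ec_by_year.{k}"] = _beta_draws(rng, m, spec.cv, n)
    for test in TESTS:
        for fld in ("sensitivity", "specificity"):
            m = float(base["test_performance"][test][fld])
            scalar_draws[f"test_performance.{test}.{fld}"] = _beta_draws(rng, m, spec.cv, n)
        mc = float(base["test_performance"][test]["unit_cost"])
        scalar_draws[f"test_performance.{test}.unit_cost"] = _gamma_draws(rng, mc, spec.cv, n)

    gene_probs = np.array([base["gene_distribution"][g] for g in GENES])
    gene_draws = _dirichlet_draws(rng, gene_probs, spec.cv, n)
    stage_s = _dirichlet_draws(rng, np.asarray(base["stage_dist_surveilled"], float), spec.cv, n)
    stage_u = _dirichlet_draws(rng, np.asarray(base["stage_dist_unsurveilled"], float), spec.cv, n)

    out: list[ParameterSet] = []
    for i in range(n):
        doc = params.model_dump(mode="python")
        for path, draws in scalar_draws.items():
            _set(doc, path, float(draws[i]))
        doc["gene_distribution"] = {g: float(gene_draws[i, j]) for j, g in enumerate(GENES)}
        # guard the 1e-9 sum invariant against float round-off
        total = sum(doc["gene_distribution"].values())
        if abs(total - 1.0) > 1e-12:
            doc["gene_distribution"] = {
                g: v / total for g, v in doc["gene_distribution"].items()
            }
        doc["stage_dist_surveilled"] = [float(x) for x in stage_s[i]]
        doc["stage_dist_unsurveilled"] = [float(x) for x in stage_u[i]]
        out.append(ParameterSet(**doc))
    return out
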