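"""End-to-end orchestration: run every analysis and emit machine-readable files.

``run_all`` produces, in the output directory:

* ``table1.csv``  — screening detections, screening cost, cascade cost
* ``table2.csv``  — base-case totals and ICERs
* ``table3.csv``  — the no-preventive-monitoring scenario totals and ICERs
* ``tornado.csv`` — one-way sensitivity entries (unless skipped)
* ``psa.csv``     — per-iteration PSA cost/QALY pairs (unless skipped)
* ``ceac.csv``    — acceptability curves over the willingness-to-pay grid
* ``manifest.json`` — config hash, seed, version, emitted files

Identical configuration and seed give byte-identical CSV output.  Every
parameter flagged ``supplementary_placeholder`` is logged as a warning so
placeholder-driven results are visible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cea import ceac
from .parameters import ParameterSet, PsaSpec, load_parameters
from .pipeline import run_pipeline
from .sensitivity import run_psa, scenario, tornado

__all__ = ["RunManifest", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    timestamp: str
    scenario_flags: list[str]
    skipped: list[str]
    files: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _config_hash(params: ParameterSet) -> str:
    doc = yaml.safe_dump(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def _warn_placeholders(params: ParameterSet) -> list[str]:
    placeholders = [k for k, v in params.provenance.items() if v == "supplementary_placeholder"]
    for name in placeholders:
        logger.warning(
            "parameter %s is a supplementary placeholder default; override it "
            "with study-specific values before relying on absolute results",
            name,
        )
    return placeholders


def run_all(
    config: ParameterSet | str | Path,
    out_dir: str | Path,
    seed: int = 0,
    skip: tuple[str, ...] = (),
    scenarios: tuple[str, ...] = ("no_gyn_monitoring",),
    psa_iterations: int = 1000,
    wtp_grid: np.ndarray | None = None,
) -> RunManifest:
    """Run screening, CEA, scenario, tornado and PSA analyses and write files."""
    params = config if isinstance(config, ParameterSet) else load_parameters(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(skip) - {"psa", "tornado"}
    if unknown:
        raise ValueError(f"unknown skip stages {sorted(unknown)}; allowed: psa, tornado")

    _warn_placeholders(params)
    manifest = RunManifest(
        config_hash=_config_hash(params),
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        scenario_flags=list(scenarios),
        skipped=list(skip),
    )

    def emit(name: str, df) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        manifest.files.append(name)

    logger.info("stage: base case")
    base = run_pipeline(params)
    emit("table1.csv", base.table1())
    emit("table2.csv", base.table2())

    for name in scenarios:
        logger.info("stage: scenario %s", name)
        scen = scenario(params, name)
        emit("table3.csv" if name == "no_gyn_monitoring" else f"scenario_{name}.csv", scen.table2())

    if "tornado" not in skip:
        logger.info("stage: tornado")
        emit("tornado.csv", tornado(params))

    if "psa" not in skip:
        logger.info("stage: PSA (%d iterations)", psa_iterations)
        psa = run_psa(params, PsaSpec(iterations=psa_iterations, seed=seed))
        emit("psa.csv", psa.to_frame())
        if wtp_grid is None:
            wtp_grid = np.arange(0.0, 50_001.0, 2_500.0)
        emit("ceac.csv", ceac(psa.costs, psa.qalys, psa.strategies, wtp_grid))

    manifest.files.append("manifest.json")
    manifest.write(out / "manifest.json")
    return manifest
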