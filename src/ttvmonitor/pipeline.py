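"""End-to-end analysis pipeline: preprocessing, the three result tables and
a run manifest.

Given a validated cohort the pipeline runs, in order, the patient-level
association screen, the repeated-measures correlation tests and the four
random-intercept event models, then writes ``table2_associations.csv``,
``table3_correlations.csv``, ``table4_mixed_logit.csv`` and
``manifest.json``.  Stages are independent: a stage failure is recorded in
the manifest and the remaining stages still run.  Outputs are a pure
function of (cohort, config): the manifest holds no timestamps, so two runs
with the same seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .associations import run_association_table
from .data_io import Cohort, read_cohort, write_results
from .mixed_logit import QuadratureSpec, run_event_models
from .repeated_correlation import run_correlation_table

logger = logging.getLogger("ttvmonitor")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_permutations: int = 10_000
    min_pairs: int = 3
    quadrature_nodes: int = 21
    adaptive_quadrature: bool = False
    mismatch_as: str = "continuous"

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")

    def analysis_params(self) -> dict:
        # out_dir is where the bundle lands, not part of the analysis; keeping
        # it out of the manifest makes bundles comparable across directories.
        params = dataclasses.asdict(self)
        params.pop("out_dir")
        return params

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class ReportBundle:
    out_dir: Path
    tables: dict
    manifest_path: Path
    errors: dict


def _stage(name: str, fn, errors: dict, results: list):
    start = time.perf_counter()
    try:
        out = fn()
        results.extend(out)
        logger.info("stage %s: %d results in %.2fs", name, len(out), time.perf_counter() - start)
    except (ValueError, KeyError) as exc:
        errors[name] = str(exc)
        logger.warning("stage %s failed: %s", name, exc)


def run_pipeline(cohort: Cohort, config: RunConfig) -> ReportBundle:
    """Run every analysis stage on ``cohort`` and write the report bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    quad = QuadratureSpec(n_nodes=config.quadrature_nodes, adaptive=config.adaptive_quadrature)

    errors: dict[str, str] = {}
    results: list = []
    _stage(
        "associations",
        lambda: run_association_table(cohort, mismatch_as=config.mismatch_as),
        errors,
        results,
    )
    _stage(
        "correlations",
        lambda: run_correlation_table(
            cohort,
            n_permutations=config.n_permutations,
            seed=config.seed,
            min_pairs=config.min_pairs,
        ),
        errors,
        results,
    )
    _stage("event_models", lambda: run_event_models(cohort, quad), errors, results)

    tables = write_results(results, out_dir) if results else {}

    manifest = {
        "package": "ttvmonitor",
        "version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "config": config.analysis_params(),
        "config_hash": config.config_hash(),
        "n_patients": cohort.n_patients,
        "n_visits": cohort.n_visits,
        "tables": {k: p.name for k, p in tables.items()},
        "stage_errors": errors,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return ReportBundle(out_dir=out_dir, tables=tables, manifest_path=manifest_path, errors=errors)


def run_pipeline_from_paths(patients_csv, visits_csv, config: RunConfig) -> ReportBundle:
    return run_pipeline(read_cohort(patients_csv, visits_csv), config)
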