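"""End-to-end pipeline: cohort -> assay -> interpretation -> concordance -> accuracy.

A single master seed deterministically derives the per-stage seeds
(master for the cohort, master+1 for the assay, master+2 for
mislabeling), so a run is reproducible from its RunConfig alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .accuracy import DiagnosticAccuracyResults, evaluate
from .assay import (
    AssayParams,
    apply_mislabel,
    fetal_fraction,
    simulate_markers,
    simulate_rhd_matrix,
    write_calls_csv,
)
from .cohort import CohortConfig, generate_cohort, write_cohort_csv
from .concordance import build_records, make_flow, write_comparison_csv
from .interpret import Category, InterpretConfig, interpret_assays, write_reports_csv

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "error_free_config", "validate_tables"]

logger = logging.getLogger("rhdnipt")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    assay: AssayParams = field(default_factory=AssayParams)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)
    conf_level: float = 0.95
    output_dir: str | Path | None = None
    log_level: str = "INFO"
    seed: int = 0

    def stage_seed(self, offset: int) -> int:
        return (self.seed + offset) % (2**31)


def error_free_config(n: int = 2000, seed: int = 0) -> RunConfig:
    """A configuration with every error process off and detection saturated.

    All swap/variant/vanishing probabilities are zero, every replicate
    sees ample template at every gestational age (fixed 10% fetal
    fraction, unit per-copy detection), and follow-up is complete, so
    interpretation must reproduce the genotype exactly.
    """
    cohort = CohortConfig(
        n_pregnancies=n,
        maternal_variant_prob=0.0,
        d_variant_frac=0.0,
        mislabel_prob=0.0,
        vanishing_twin_prob=0.0,
        followup_prob=1.0,
        seed=seed,
    )
    assay = AssayParams(
        detection_prob_per_copy=1.0,
        spurious_call_prob=0.0,
        ff_slope=0.0,
        ff_intercept=float(np.log(0.1)),
        ff_sd=0.0,
    )
    return RunConfig(cohort=cohort, assay=assay, seed=seed)


def run_pipeline(config: RunConfig) -> DiagnosticAccuracyResults:
    """Execute stages 0-4; write all intermediate tables when output_dir is set."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _write(name: str, writer) -> None:
        if out is None:
            return
        writer(out / name)
        manifest[name] = "written"
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            if out:
                manifest[name] = f"failed: {exc}"
                (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage=%s seed=%s dt=%.3fs", name, config.seed, time.perf_counter() - t0)
        return result

    cohort_cfg = dataclasses.replace(config.cohort, seed=config.stage_seed(0))
    cohort = _stage("cohort", generate_cohort, cohort_cfg)
    _write("cohort.csv", lambda p: write_cohort_csv(cohort, p))

    def _assay_stage():
        rng = np.random.default_rng(config.stage_seed(1))
        results = []
        for preg in cohort:
            ff = fetal_fraction(preg.ga_at_sampling, config.assay, rng)
            matrix = simulate_rhd_matrix(preg, ff, config.assay, rng)
            markers = simulate_markers(preg, ff, config.assay, rng)
            from .assay import AssayResult

            results.append(AssayResult(preg.id, matrix, markers, ff))
        mis_rng = np.random.default_rng(config.stage_seed(2))
        return apply_mislabel(results, mis_rng, cohort_cfg.mislabel_prob)

    assays = _stage("assay", _assay_stage)
    _write("calls.csv", lambda p: write_calls_csv(assays, p))

    reports = _stage("interpret", interpret_assays, assays, config.interpret)
    _write("reports.csv", lambda p: write_reports_csv(reports, p))

    records = _stage("concordance", build_records, cohort, reports)
    _write("comparison.csv", lambda p: write_comparison_csv(records, p))
    flow = make_flow(records) if records else None
    if out and flow:
        _write("flow.json", lambda p: Path(p).write_text(json.dumps(flow.to_dict(), indent=2)))

    results = _stage("accuracy", evaluate, records, None, config.conf_level)
    _write("report.json", lambda p: Path(p).write_text(results.to_json()))
    return results


# ---------------------------------------------------------------------------
# table validation
# ---------------------------------------------------------------------------

_CATEGORY_VALUES = {c.value for c in Category}


def validate_tables(
    cohort_csv=None, calls_csv=None, reports_csv=None, comparison_csv=None
) -> list[str]:
    """Schema/range/join checks over pipeline tables.

    Returns a machine-readable list of violation strings (empty = valid).
    """
    violations: list[str] = []
    ids: dict[str, set] = {}

    def _load(path, name):
        try:
            df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
        except Exception as exc:
            violations.append(f"{name}: unreadable ({exc})")
            return None
        if "id" not in df.columns:
            violations.append(f"{name}: missing id column")
            return None
        if df["id"].duplicated().any():
            violations.append(f"{name}: duplicate ids")
        ids[name] = set(df["id"])
        return df

    if cohort_csv is not None:
        df = _load(cohort_csv, "cohort")
        if df is not None:
            bad = df[(df["n_fetuses"] < 1) | (df["n_fetuses"] > 3)]
            for rid in bad["id"]:
                violations.append(f"cohort: id {rid}: n_fetuses out of 1..3")
            bad = df[(df["ga_days"] < 0) | (df["ga_days"] > 6)]
            for rid in bad["id"]:
                violations.append(f"cohort: id {rid}: ga_days out of 0..6")
    if calls_csv is not None:
        df = _load(calls_csv, "calls")
        if df is not None:
            for col in [c for c in df.columns if c.startswith("exon")]:
                vals = pd.to_numeric(df[col], errors="coerce")
                bad = df[~vals.isin([0, 1])]
                for rid in bad["id"]:
                    violations.append(f"calls: id {rid}: {col} not in {{0,1}}")
            for col in ("sry_calls", "rassf1a_calls"):
                if col in df.columns:
                    vals = pd.to_numeric(df[col], errors="coerce")
                    bad = df[(vals < 0) | (vals > 3) | vals.isna()]
                    for rid in bad["id"]:
                        violations.append(f"calls: id {rid}: {col} out of 0..3")
    if reports_csv is not None:
        df = _load(reports_csv, "reports")
        if df is not None:
            bad = df[~df["category"].isin(_CATEGORY_VALUES)]
            for rid, cat in zip(bad["id"], bad["category"]):
                violations.append(f"reports: id {rid}: unknown category {cat!r}")
            vals = pd.to_numeric(df["call_count"], errors="coerce")
            bad = df[(vals < 0) | (vals > 9) | vals.isna()]
            for rid in bad["id"]:
                violations.append(f"reports: id {rid}: call_count out of 0..9")
    if comparison_csv is not None:
        _load(comparison_csv, "comparison")

    # join integrity across whichever tables were given
    if "cohort" in ids:
        for other in ("calls", "reports", "comparison"):
            if other in ids and ids[other] != ids["cohort"]:
                missing = ids["cohort"] ^ ids[other]
                violations.append(
                    f"join: cohort vs {other}: {len(missing)} unmatched ids"
                )
    return violations
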