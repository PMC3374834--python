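"""End-to-end run: ingest → classify → flag → tables → odds ratios.

A run takes either a directory of registry XML or a synthetic-generator
configuration, produces every summary table as CSV plus aligned text, the
odds-ratio reports, and a manifest recording inputs, stage counts along the
restraint cascade, and the emitted files.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import time
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import association, classifier, filters, reporting
from .records import TrialRecord
from .registry_io import read_corpus
from .synthetic import GeneratorConfig, generate_records

__all__ = ["run_all", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _dictionary_hash() -> str:
    data = (
        resources.files("trialmeta.data")
        .joinpath("sponsor_classes.yaml")
        .read_bytes()
    )
    return hashlib.sha256(data).hexdigest()[:16]


def _emit(frame: pd.DataFrame, out_dir: Path, name: str, index: bool = False) -> list[str]:
    csv_path = out_dir / f"{name}.csv"
    txt_path = out_dir / f"{name}.txt"
    frame.to_csv(csv_path, index=index)
    txt_path.write_text(frame.to_string(index=index, na_rep="n/a") + "\n", encoding="utf-8")
    return [csv_path.name, txt_path.name]


def run_all(
    input_path: str | None,
    out_dir: str,
    generator_config: GeneratorConfig | None = None,
    cutoff: _dt.date = filters.DEFAULT_CUTOFF,
    phase_rule: str = "intersection",
    or_level: float = 0.95,
    or_method: str = "t",
) -> dict:
    """Run the whole analysis; returns the manifest (also written as JSON).

    Exactly one of ``input_path`` (a directory of registry XML) and
    ``generator_config`` must be given.
    """
    if (input_path is None) == (generator_config is None):
        raise PipelineError("provide exactly one of input_path and generator_config")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    manifest: dict = {
        "cutoff": cutoff.isoformat(),
        "phase_rule": phase_rule,
        "dictionary_hash": _dictionary_hash(),
        "stages": {},
    }

    t0 = time.perf_counter()
    if generator_config is not None:
        manifest["input"] = {"kind": "synthetic", "seed": generator_config.seed,
                             "n_trials": generator_config.n_trials}
        records: Sequence[TrialRecord] = generate_records(generator_config).records
        n_failures = 0
    else:
        manifest["input"] = {"kind": "directory", "path": str(input_path)}
        try:
            records, report = read_corpus(input_path)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError(f"ingest: {exc}") from exc
        if not records:
            raise PipelineError(f"ingest: no parseable records in {input_path}")
        n_failures = len(report)
    logger.info("ingest: %d records (%.2fs)", len(records), time.perf_counter() - t0)
    manifest["stages"]["ingested"] = len(records)
    manifest["stages"]["parse_failures"] = n_failures

    t0 = time.perf_counter()
    try:
        assignments, class_summary = classifier.classify_corpus(records)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"classify: {exc}") from exc
    logger.info("classify: done (%.2fs)", time.perf_counter() - t0)
    outputs += _emit(class_summary, out, "table_class_sizes")

    flags = filters.compute_corpus_flags(records, cutoff, phase_rule)
    n_completed = sum(1 for f in flags.values() if f.completed_by_cutoff)
    n_restrained = sum(1 for f in flags.values() if f.all_requirements)
    manifest["stages"]["completed_by_cutoff"] = n_completed
    manifest["stages"]["all_requirements"] = n_restrained

    try:
        yearly = reporting.yearly_requirement_table(records, flags)
        yearly_out = yearly.copy()
        yearly_out.columns = ["_".join(c) for c in yearly_out.columns]
        outputs += _emit(yearly_out.reset_index(), out, "table_yearly_requirements")

        restrained_tbl = reporting.class_restrained_table(records, assignments, flags)
        outputs += _emit(restrained_tbl, out, "table_class_restrained")

        outcomes = reporting.outcome_table(records, assignments)
        outputs += _emit(outcomes, out, "table_outcomes")

        interventions = reporting.intervention_table(records, assignments)
        iv_out = interventions.copy()
        iv_out.columns = [
            "_".join(c).rstrip("_") for c in iv_out.columns
        ]
        outputs += _emit(iv_out.reset_index(), out, "table_interventions")

        enrollment = reporting.enrollment_table(records, assignments)
        outputs += _emit(enrollment, out, "table_enrollment")

        activity = reporting.yearly_activity(records)
        outputs += _emit(activity, out, "table_yearly_activity")

        phases = reporting.phase_distribution(records, assignments)
        outputs += _emit(phases, out, "table_phase_distribution")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"report: {exc}") from exc

    def _or_report(restrained: bool) -> tuple[pd.DataFrame, str]:
        # Zero cells happen on small corpora; fall back to the
        # Haldane–Anscombe correction rather than abort the run.
        try:
            frame = association.class_or_report(
                records, assignments, flags, restrained=restrained,
                level=or_level, method=or_method,
            )
            return frame, "none"
        except association.DegenerateTableError:
            try:
                frame = association.class_or_report(
                    records, assignments, flags, restrained=restrained,
                    level=or_level, method=or_method, correction="haldane",
                )
            except association.DegenerateTableError as exc:
                # an empty class margin: no correction can help
                logger.warning("odds-ratio table degenerate, report skipped: %s", exc)
                return None, "skipped"
            logger.warning(
                "zero cell in %s odds-ratio tables; applied Haldane correction",
                "restrained" if restrained else "unrestricted",
            )
            return frame, "haldane"

    try:
        or_unrestricted, correction_u = _or_report(restrained=False)
        if or_unrestricted is not None:
            outputs += _emit(or_unrestricted, out, "or_report_unrestricted")
        manifest["or_correction_unrestricted"] = correction_u
        if n_restrained > 0:
            or_restrained, correction_r = _or_report(restrained=True)
            if or_restrained is not None:
                outputs += _emit(or_restrained, out, "or_report_restrained")
            manifest["or_correction_restrained"] = correction_r
        else:
            logger.warning("empty restrained pool; restrained OR report skipped")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"odds-ratio: {exc}") from exc

    # Cascade sanity: counts are non-increasing along the restraint chain.
    assert n_restrained <= n_completed <= len(records)
    assert int(restrained_tbl["total"].sum()) <= n_restrained

    manifest["outputs"] = sorted(outputs)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
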