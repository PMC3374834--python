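"""Summary tables for registry reporting efficiency.

Every table reduces to the same ingredients: a grouping (completion-year
bucket, sponsor class, or class × intervention type), a denominator of
trials in the group, and a numerator of trials with a deposited
summary-results section (or, for outcome tables, with listed outcome
measures). Percentages are recomputed from the two counts with half-up
rounding, never carried through intermediate floats.
"""

from __future__ import annotations

import logging
import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .filters import RequirementFlags, completion_year, parse_phase, year_bucket
from .records import ASSIGNED_CLASSES, SponsorClass, TrialRecord

__all__ = [
    "percent",
    "format_percent",
    "yearly_requirement_table",
    "class_restrained_table",
    "outcome_table",
    "intervention_table",
    "enrollment_table",
    "yearly_activity",
    "phase_distribution",
    "REQUIREMENT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Requirement columns of the yearly tables, in presentation order.
REQUIREMENT_COLUMNS = (
    "overall",
    "fda_regulated",
    "section_801",
    "phases_2_4",
    "with_publications",
    "interventional",
    "all_requirements",
)

#: Class row order used by the per-class tables.
CLASS_ORDER = (
    SponsorClass.HOS,
    SponsorClass.EDU,
    SponsorClass.COL,
    SponsorClass.COM,
    SponsorClass.GOV,
)


def percent(numerator: int, denominator: int, decimals: int = 2) -> float | None:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``.

    A zero denominator has no defined rate and returns ``None`` (rendered
    "n/a" by :func:`format_percent`).
    """
    if denominator == 0:
        return None
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


def format_percent(value: float | None) -> str:
    """Render a percentage with trailing zeros trimmed; ``None`` as "n/a"."""
    if value is None:
        return "n/a"
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return text or "0"


def _none_for_nan(frame: pd.DataFrame, columns) -> pd.DataFrame:
    # undefined rates are carried as None, not NaN, so they compare cleanly
    for c in columns:
        col = frame[c].astype(object)
        frame[c] = col.where(pd.notna(col), None)
    return frame


def _requirement_applies(flags: RequirementFlags, column: str) -> bool:
    if column == "overall":
        return True
    if column == "phases_2_4":
        return flags.phase_2_to_4
    if column == "with_publications":
        return flags.has_publication
    if column == "all_requirements":
        return flags.all_requirements
    return getattr(flags, column)


def yearly_requirement_table(
    corpus: Iterable[TrialRecord],
    flags: Mapping[str, RequirementFlags],
    columns: Sequence[str] = REQUIREMENT_COLUMNS,
) -> pd.DataFrame:
    """Completed trials per completion-year bucket under each requirement.

    Rows: each completion year after 2000 (descending), a "2000 and before"
    bucket, and a total row. Cells: count with results, count total, and
    their percentage. Only trials completed by the cutoff enter.
    """
    completed = [
        r for r in corpus if flags[r.nct_id].completed_by_cutoff
    ]
    buckets: dict[str, list[TrialRecord]] = {}
    for record in completed:
        year = completion_year(record)
        # completed_by_cutoff guarantees a completion date
        buckets.setdefault(year_bucket(year), []).append(record)

    years = sorted((b for b in buckets if b != "2000 and before"), reverse=True)
    row_labels = years + (["2000 and before"] if "2000 and before" in buckets else [])
    rows = []
    for label in row_labels + ["total"]:
        members = completed if label == "total" else buckets[label]
        row: dict = {"completion_year": label}
        for column in columns:
            eligible = [r for r in members if _requirement_applies(flags[r.nct_id], column)]
            with_results = sum(1 for r in eligible if r.has_results)
            row[(column, "with_results")] = with_results
            row[(column, "total")] = len(eligible)
            row[(column, "percent")] = percent(with_results, len(eligible))
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame = frame.set_index("completion_year")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return _none_for_nan(frame, [c for c in frame.columns if c[1] == "percent"])


def class_restrained_table(
    corpus: Iterable[TrialRecord],
    assignments: Mapping[str, SponsorClass],
    flags: Mapping[str, RequirementFlags],
    class_order: Sequence[SponsorClass] = CLASS_ORDER,
) -> pd.DataFrame:
    """Results deposition per class among trials meeting every requirement."""
    restrained = [r for r in corpus if flags[r.nct_id].all_requirements]
    rows = []
    for cls in class_order:
        members = [r for r in restrained if assignments[r.nct_id] == cls]
        if not members:
            warnings.warn(f"no trials meeting all requirements for class {cls.value}")
            continue
        with_results = sum(1 for r in members if r.has_results)
        rows.append(
            {
                "class": cls.value,
                "with_results": with_results,
                "total": len(members),
                "percent": percent(with_results, len(members)),
            }
        )
    logger.info("restrained pool: %d trials", len(restrained))
    frame = pd.DataFrame(rows, columns=["class", "with_results", "total", "percent"])
    return _none_for_nan(frame, ["percent"]) if len(frame) else frame


def outcome_table(
    corpus: Iterable[TrialRecord],
    assignments: Mapping[str, SponsorClass],
    class_order: Sequence[SponsorClass] = ASSIGNED_CLASSES,
) -> pd.DataFrame:
    """Outcome reporting per class over the full corpus (no restraints).

    Counts trials listing at least one outcome measure (primary or
    secondary) and trials listing more than one, as counts and as
    percentages of the class total.
    """
    by_class: dict[SponsorClass, list[TrialRecord]] = {cls: [] for cls in class_order}
    for record in corpus:
        cls = assignments[record.nct_id]
        if cls in by_class:
            by_class[cls].append(record)
    rows = []
    for cls in class_order:
        members = by_class[cls]
        at_least_one = sum(1 for r in members if r.n_outcomes >= 1)
        more_than_one = sum(1 for r in members if r.n_outcomes > 1)
        rows.append(
            {
                "class": cls.value,
                "class_total": len(members),
                "n_at_least_one": at_least_one,
                "pct_at_least_one": percent(at_least_one, len(members)),
                "n_more_than_one": more_than_one,
                "pct_more_than_one": percent(more_than_one, len(members)),
            }
        )
    return _none_for_nan(pd.DataFrame(rows), ["pct_at_least_one", "pct_more_than_one"])


#: The three most frequent intervention types in the registry.
TOP_INTERVENTION_TYPES = ("Drug", "Procedure", "Device")


def intervention_table(
    corpus: Iterable[TrialRecord],
    assignments: Mapping[str, SponsorClass],
    types: Sequence[str] = TOP_INTERVENTION_TYPES,
    class_order: Sequence[SponsorClass] = ASSIGNED_CLASSES,
    interventional_only: bool = True,
) -> pd.DataFrame:
    """Trial counts and results-reporting efficiency per class × intervention type.

    Efficiency is the percentage of trials with deposited results among
    trials of the given class and intervention type. A trial with several
    intervention types contributes to each of its types, so type columns
    need not sum to the class total. Shares are relative to the class's
    interventional trials (switchable to all trials).
    """
    corpus = list(corpus)
    rows = []
    for cls in class_order:
        members = [r for r in corpus if assignments[r.nct_id] == cls]
        if interventional_only:
            base = [r for r in members if r.study_type == "Interventional"]
        else:
            base = members
        row: dict = {"class": cls.value, "interventional_total": len(base)}
        for itype in types:
            typed = [r for r in base if itype in r.intervention_types]
            with_results = sum(1 for r in typed if r.has_results)
            row[(itype, "trials")] = len(typed)
            row[(itype, "share_pct")] = percent(len(typed), len(base))
            row[(itype, "efficiency_pct")] = percent(with_results, len(typed))
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("class")
    frame.columns = pd.MultiIndex.from_tuples(
        c if isinstance(c, tuple) else (c, "") for c in frame.columns
    )
    return _none_for_nan(
        frame, [c for c in frame.columns if c[1] in ("share_pct", "efficiency_pct")]
    )


#: Statuses admitted to the enrollment table.
ENROLLMENT_STATUSES = ("Completed", "Active, not recruiting")

ENROLLMENT_STRATA = (
    "all",
    "with_outcome",
    "with_results",
    "with_results_interventional",
)


def _in_stratum(record: TrialRecord, stratum: str) -> bool:
    if stratum == "all":
        return True
    if stratum == "with_outcome":
        return record.n_outcomes >= 1
    if stratum == "with_results":
        return record.has_results
    if stratum == "with_results_interventional":
        return record.has_results and record.study_type == "Interventional"
    raise ValueError(f"unknown stratum {stratum!r}")


def enrollment_table(
    corpus: Iterable[TrialRecord],
    assignments: Mapping[str, SponsorClass],
    strata: Sequence[str] = ENROLLMENT_STRATA,
    class_order: Sequence[SponsorClass] = ASSIGNED_CLASSES,
    statuses: Sequence[str] = ENROLLMENT_STATUSES,
) -> pd.DataFrame:
    """Enrollment summaries per class and stratum.

    Base population: trials whose overall status is completed or active/not
    recruiting and that carry an enrollment value (trials without one are
    excluded from every stratum). Sentinel values (0, 99999999) are kept
    as-is — the registry contains them and they dominate the unrestricted
    maxima and averages, which is part of what the table shows.
    """
    base = [
        r
        for r in corpus
        if r.overall_status in statuses and r.enrollment is not None
    ]
    rows = []
    for stratum in strata:
        stratum_members = [r for r in base if _in_stratum(r, stratum)]
        for cls in class_order:
            members = [r for r in stratum_members if assignments[r.nct_id] == cls]
            if not members:
                rows.append(
                    {
                        "stratum": stratum,
                        "class": cls.value,
                        "n_trials": 0,
                        "max_enrollment": None,
                        "average_enrollment": None,
                        "total_participants": 0,
                    }
                )
                continue
            total = sum(r.enrollment for r in members)
            rows.append(
                {
                    "stratum": stratum,
                    "class": cls.value,
                    "n_trials": len(members),
                    "max_enrollment": max(r.enrollment for r in members),
                    "average_enrollment": round(total / len(members), 2),
                    "total_participants": total,
                }
            )
    return pd.DataFrame(rows)


def yearly_activity(corpus: Iterable[TrialRecord]) -> pd.DataFrame:
    """Trials started and completed per calendar year.

    Trials lacking the relevant date are excluded from that count.
    """
    started: dict[int, int] = {}
    completed: dict[int, int] = {}
    for record in corpus:
        if record.start_date is not None:
            started[record.start_date.year] = started.get(record.start_date.year, 0) + 1
        if record.completion_date is not None:
            year = record.completion_date.year
            completed[year] = completed.get(year, 0) + 1
    years = sorted(set(started) | set(completed))
    return pd.DataFrame(
        {
            "year": years,
            "started": [started.get(y, 0) for y in years],
            "completed": [completed.get(y, 0) for y in years],
        }
    )


def phase_distribution(
    corpus: Iterable[TrialRecord],
    assignments: Mapping[str, SponsorClass],
    class_order: Sequence[SponsorClass] = ASSIGNED_CLASSES,
) -> pd.DataFrame:
    """Counts of trials per class and phase 1–4.

    A trial naming several phases contributes to each; trials without an
    explicit phase are excluded.
    """
    counts = {cls: {p: 0 for p in (1, 2, 3, 4)} for cls in class_order}
    for record in corpus:
        cls = assignments[record.nct_id]
        if cls not in counts:
            continue
        phase = parse_phase(record.phase_raw)
        for p in phase.phases:
            counts[cls][p] += 1
    frame = pd.DataFrame(
        {
            "class": [cls.value for cls in class_order],
            **{
                f"phase_{p}": [counts[cls][p] for cls in class_order]
                for p in (1, 2, 3, 4)
            },
        }
    )
    return frame
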