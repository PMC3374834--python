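"""Per-trial results-deposition requirement flags.

Mandatory summary-results deposition applies to a trial when a cascade of
conditions holds: the trial is completed (by its overall status, with a
completion date on or before the snapshot cutoff), it is FDA regulated and
specifically covered by Section 801 of the FDAAA, it carries an explicit
phase between 2 and 4, it has at least one attached peer-reviewed
reference, and its study type is interventional. Each condition is a pure
function of the record; the conjunction defines the "restrained" pool.

Unknown or absent oversight flags count as not satisfied: the registry's
counts of regulated trials are counts of affirmative assignments.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Iterable, Literal

from .records import TrialRecord

__all__ = [
    "DEFAULT_CUTOFF",
    "PhaseSet",
    "RequirementFlags",
    "parse_phase",
    "completion_year",
    "year_bucket",
    "compute_flags",
    "compute_corpus_flags",
]

#: Snapshot cutoff: trials completed on or before this date count as completed.
DEFAULT_CUTOFF = _dt.date(2011, 12, 31)

_EARLY = re.compile(r"early\s+phase\s*\d", re.IGNORECASE)
_PHASE_NUM = re.compile(r"phase\s*([1-4])", re.IGNORECASE)


@dataclass(frozen=True)
class PhaseSet:
    """Phases named by a registry phase string; empty and non-explicit for "N/A"."""

    phases: frozenset[int]
    explicit: bool

    def __post_init__(self) -> None:
        if not self.explicit and self.phases:
            raise ValueError("non-explicit phase set must be empty")


def parse_phase(phase_raw: str | None) -> PhaseSet:
    """Extract the phases named in a registry phase string.

    "Phase 2/Phase 3" names {2, 3}; "N/A", "Early Phase 1" and absent
    strings are not explicit phase assignments.
    """
    if phase_raw is None:
        return PhaseSet(frozenset(), False)
    text = _EARLY.sub(" ", phase_raw)
    phases = frozenset(int(m) for m in _PHASE_NUM.findall(text))
    if not phases:
        return PhaseSet(frozenset(), False)
    return PhaseSet(phases, True)


def completion_year(record: TrialRecord) -> int | None:
    """Completion year of the record, or None when no completion date exists."""
    if record.completion_date is None:
        return None
    return record.completion_date.year


def year_bucket(year: int) -> str:
    """Report-time bucket label: each year after 2000, else "2000 and before"."""
    return "2000 and before" if year <= 2000 else str(year)


@dataclass(frozen=True)
class RequirementFlags:
    """The five deposition requirements plus completion, and their conjunction."""

    completed_by_cutoff: bool
    fda_regulated: bool
    section_801: bool
    phase_2_to_4: bool
    has_publication: bool
    interventional: bool

    @property
    def all_requirements(self) -> bool:
        return (
            self.completed_by_cutoff
            and self.fda_regulated
            and self.section_801
            and self.phase_2_to_4
            and self.has_publication
            and self.interventional
        )


def compute_flags(
    record: TrialRecord,
    cutoff: _dt.date = DEFAULT_CUTOFF,
    phase_rule: Literal["intersection", "min2"] = "intersection",
) -> RequirementFlags:
    """Evaluate the deposition-requirement cascade for one record.

    ``completed_by_cutoff`` requires overall status "Completed" and a
    completion date whose latest possible day is on or before ``cutoff``
    (month-granular dates are resolved conservatively). ``phase_rule``
    "intersection" accepts any trial naming a phase in 2–4 (so
    "Phase 1/Phase 2" qualifies); "min2" additionally requires the lowest
    named phase to be at least 2.
    """
    phase = parse_phase(record.phase_raw)
    if phase_rule == "intersection":
        phase_ok = phase.explicit and bool(phase.phases & {2, 3, 4})
    elif phase_rule == "min2":
        phase_ok = phase.explicit and min(phase.phases) >= 2
    else:
        raise ValueError(f"unknown phase rule {phase_rule!r}")
    return RequirementFlags(
        completed_by_cutoff=(
            record.overall_status == "Completed"
            and record.completion_date is not None
            and record.completion_date.latest() <= cutoff
        ),
        fda_regulated=record.is_fda_regulated is True,
        section_801=record.is_section_801 is True,
        phase_2_to_4=phase_ok,
        has_publication=record.n_references >= 1,
        interventional=record.study_type == "Interventional",
    )


def compute_corpus_flags(
    corpus: Iterable[TrialRecord],
    cutoff: _dt.date = DEFAULT_CUTOFF,
    phase_rule: Literal["intersection", "min2"] = "intersection",
) -> dict[str, RequirementFlags]:
    """Flags for every record, keyed by registry identifier."""
    return {r.nct_id: compute_flags(r, cutoff, phase_rule) for r in corpus}
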