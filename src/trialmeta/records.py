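"""Core data model for registry trial records.

A registry entry is one clinical study: who sponsors it, its status and
dates, design descriptors (phase, study type, interventions), regulatory
flags, and what has been deposited (summary results, outcome measures,
literature references, enrollment). Dates in the public registry carry
month–year granularity, so they are modelled as partial dates.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "PartialDate",
    "SponsorClass",
    "TrialRecord",
    "AGENCY_CLASSES",
]

#: The registry's own four-way sponsor label.
AGENCY_CLASSES = ("Industry", "NIH", "U.S. Fed", "Other")

_MONTHS = {name: i for i, name in enumerate(calendar.month_name) if name}
_MONTHS.update({name: i for i, name in enumerate(calendar.month_abbr) if name})

_DATE_RE = re.compile(
    r"^\s*(?:(?P<month>[A-Za-z]+)\s+)?(?:(?P<day>\d{1,2}),\s+)?(?P<year>\d{4})\s*$"
)
_ISO_RE = re.compile(r"^(?P<year>\d{4})(?:-(?P<month>\d{2})(?:-(?P<day>\d{2}))?)?$")


@dataclass(frozen=True, order=True)
class PartialDate:
    """A date with optional month and day, as found in registry records.

    Ordering is lexicographic on (year, month, day) with absent components
    sorting first; use :meth:`latest` / :meth:`earliest` for calendar
    comparisons that must resolve the missing granularity explicitly.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day given without month")
            if not 1 <= self.day <= calendar.monthrange(self.year, self.month)[1]:
                raise ValueError(f"day out of range: {self.day}")

    @classmethod
    def parse(cls, text: str) -> "PartialDate":
        """Parse registry-style text: ``"June 2008"``, ``"December 31, 2011"``, ``"2008"``."""
        m = _DATE_RE.match(text)
        if m is None:
            raise ValueError(f"unparseable date: {text!r}")
        month = None
        if m.group("month"):
            name = m.group("month").strip().title()
            if name not in _MONTHS:
                raise ValueError(f"unknown month name in {text!r}")
            month = _MONTHS[name]
        day = int(m.group("day")) if m.group("day") else None
        return cls(int(m.group("year")), month, day)

    @classmethod
    def from_iso(cls, text: str) -> "PartialDate":
        """Parse the ISO-like serialisation ``"2011"`` / ``"2011-12"`` / ``"2011-12-05"``."""
        m = _ISO_RE.match(text)
        if m is None:
            raise ValueError(f"unparseable ISO partial date: {text!r}")
        return cls(
            int(m.group("year")),
            int(m.group("month")) if m.group("month") else None,
            int(m.group("day")) if m.group("day") else None,
        )

    def isoformat(self) -> str:
        parts = [f"{self.year:04d}"]
        if self.month is not None:
            parts.append(f"{self.month:02d}")
            if self.day is not None:
                parts.append(f"{self.day:02d}")
        return "-".join(parts)

    def registry_format(self) -> str:
        """Render in the registry's human style, e.g. ``"June 2008"``."""
        if self.month is None:
            return str(self.year)
        name = calendar.month_name[self.month]
        if self.day is None:
            return f"{name} {self.year}"
        return f"{name} {self.day}, {self.year}"

    def latest(self) -> _dt.date:
        """Latest calendar day compatible with this partial date."""
        month = self.month if self.month is not None else 12
        day = self.day if self.day is not None else calendar.monthrange(self.year, month)[1]
        return _dt.date(self.year, month, day)

    def earliest(self) -> _dt.date:
        """Earliest calendar day compatible with this partial date."""
        return _dt.date(self.year, self.month or 1, self.day or 1)


class SponsorClass(str, enum.Enum):
    """Five-way institutional classification of a trial's lead sponsor.

    edu — research/educational institutions; com — for-profit health-care
    companies; gov — national and government organisations; hos — hospitals
    and clinics; col — collaborations (associations, networks, consortia).
    Records no rule or fallback can place are ``unclassified``.
    """

    EDU = "edu"
    COM = "com"
    GOV = "gov"
    HOS = "hos"
    COL = "col"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes that carry their own row in per-class tables.
ASSIGNED_CLASSES = (
    SponsorClass.EDU,
    SponsorClass.COM,
    SponsorClass.GOV,
    SponsorClass.HOS,
    SponsorClass.COL,
)


@dataclass
class TrialRecord:
    """One registry entry.

    Optional registry elements map to ``None`` (absent), never to invented
    defaults. ``has_results`` is structural: a deposited summary-results
    section exists in the record, with no judgement of its completeness.
    """

    nct_id: str
    lead_sponsor_name: str = ""
    agency_class: str = "Other"
    overall_status: str = "Unknown"
    start_date: PartialDate | None = None
    completion_date: PartialDate | None = None
    phase_raw: str | None = None
    study_type: str | None = None
    intervention_types: frozenset[str] = field(default_factory=frozenset)
    primary_purpose: str | None = None
    is_fda_regulated: bool | None = None
    is_section_801: bool | None = None
    has_results: bool = False
    n_primary_outcomes: int = 0
    n_secondary_outcomes: int = 0
    n_references: int = 0
    enrollment: int | None = None
    enrollment_type: str | None = None
    number_of_arms: int | None = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"NCT\d{8}", self.nct_id):
            raise ValueError(f"invalid registry identifier: {self.nct_id!r}")
        for name in ("n_primary_outcomes", "n_secondary_outcomes", "n_references"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("enrollment", "number_of_arms"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative when present")
        if not isinstance(self.intervention_types, frozenset):
            self.intervention_types = frozenset(self.intervention_types)

    @property
    def n_outcomes(self) -> int:
        return self.n_primary_outcomes + self.n_secondary_outcomes
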