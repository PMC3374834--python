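"""Read and write trial records in the public-registry XML dialect.

The dialect is one ``clinical_study`` document per trial, with the lead
sponsor under ``sponsors/lead_sponsor``, oversight flags as Yes/No text,
repeated ``primary_outcome`` / ``secondary_outcome`` / ``reference`` /
``intervention`` children, and — when summary results have been deposited —
a ``clinical_results`` section. Absent optional elements stay absent on the
parsed record. A CSV serialisation (RFC 4180, UTF-8) round-trips a corpus
losslessly for tabular work.
"""

from __future__ import annotations

import csv
import io
import os
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

from .records import PartialDate, TrialRecord

__all__ = [
    "RegistryParseError",
    "DuplicateRecordError",
    "ParseFailureReport",
    "read_registry_xml",
    "write_registry_xml",
    "read_corpus",
    "write_tabular",
    "read_tabular",
]


class RegistryParseError(ValueError):
    """Raised for malformed XML or a record missing its identifier."""


class DuplicateRecordError(ValueError):
    """Raised when two corpus files carry the same registry identifier."""


@dataclass
class ParseFailureReport:
    """Files that could not be turned into records, by identifier or path."""

    failures: list[tuple[str, str]] = field(default_factory=list)

    def add(self, identifier: str, reason: str) -> None:
        self.failures.append((identifier, reason))

    def __len__(self) -> int:
        return len(self.failures)


def _text(root: etree._Element, path: str) -> str | None:
    node = root.find(path)
    if node is None or node.text is None:
        return None
    stripped = node.text.strip()
    return stripped or None


def _yes_no(text: str | None) -> bool | None:
    if text is None:
        return None
    return text.strip().lower() == "yes"


def read_registry_xml(source) -> TrialRecord:
    """Parse one ``clinical_study`` XML document into a :class:`TrialRecord`.

    ``source`` may be a path, a file-like object, bytes, or an XML string.
    Malformed XML raises :class:`RegistryParseError` naming the position;
    a document without an ``nct_id`` is rejected with identifier "unknown".
    """
    try:
        if isinstance(source, (str, os.PathLike)) and not str(source).lstrip().startswith("<"):
            tree = etree.parse(str(source))
            root = tree.getroot()
        elif isinstance(source, bytes):
            root = etree.fromstring(source)
        elif isinstance(source, str):
            root = etree.fromstring(source.encode("utf-8"))
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise RegistryParseError(f"malformed XML: {exc}") from exc

    if root.tag != "clinical_study":
        raise RegistryParseError(f"unrecognized root element {root.tag!r}")

    nct_id = _text(root, "id_info/nct_id")
    if nct_id is None:
        raise RegistryParseError("record rejected: missing nct_id (identifier unknown)")

    start = _text(root, "start_date")
    completion = _text(root, "completion_date")
    enrollment_node = root.find("enrollment")
    enrollment = None
    enrollment_type = None
    if enrollment_node is not None and enrollment_node.text is not None:
        enrollment = int(enrollment_node.text.strip())
        enrollment_type = enrollment_node.get("type")

    arms = _text(root, "number_of_arms")
    interventions = frozenset(
        node.text.strip()
        for node in root.findall("intervention/intervention_type")
        if node.text and node.text.strip()
    )

    return TrialRecord(
        nct_id=nct_id,
        lead_sponsor_name=_text(root, "sponsors/lead_sponsor/agency") or "",
        agency_class=_text(root, "sponsors/lead_sponsor/agency_class") or "Other",
        overall_status=_text(root, "overall_status") or "Unknown",
        start_date=PartialDate.parse(start) if start else None,
        completion_date=PartialDate.parse(completion) if completion else None,
        phase_raw=_text(root, "phase"),
        study_type=_text(root, "study_type"),
        intervention_types=interventions,
        primary_purpose=_text(root, "study_design_info/primary_purpose"),
        is_fda_regulated=_yes_no(_text(root, "oversight_info/is_fda_regulated")),
        is_section_801=_yes_no(_text(root, "oversight_info/is_section_801")),
        has_results=root.find("clinical_results") is not None,
        n_primary_outcomes=len(root.findall("primary_outcome")),
        n_secondary_outcomes=len(root.findall("secondary_outcome")),
        n_references=len(root.findall("reference")),
        enrollment=enrollment,
        enrollment_type=enrollment_type,
        number_of_arms=int(arms) if arms is not None else None,
    )


def write_registry_xml(record: TrialRecord) -> str:
    """Serialise a record back to the registry XML dialect (UTF-8 string)."""
    root = etree.Element("clinical_study")

    def sub(parent, tag, text=None, **attrib):
        node = etree.SubElement(parent, tag, **attrib)
        if text is not None:
            node.text = str(text)
        return node

    id_info = sub(root, "id_info")
    sub(id_info, "nct_id", record.nct_id)
    sponsors = sub(root, "sponsors")
    lead = sub(sponsors, "lead_sponsor")
    sub(lead, "agency", record.lead_sponsor_name)
    sub(lead, "agency_class", record.agency_class)
    sub(root, "overall_status", record.overall_status)
    if record.start_date is not None:
        sub(root, "start_date", record.start_date.registry_format())
    if record.completion_date is not None:
        sub(root, "completion_date", record.completion_date.registry_format())
    if record.phase_raw is not None:
        sub(root, "phase", record.phase_raw)
    if record.study_type is not None:
        sub(root, "study_type", record.study_type)
    if record.primary_purpose is not None:
        design = sub(root, "study_design_info")
        sub(design, "primary_purpose", record.primary_purpose)
    for itype in sorted(record.intervention_types):
        sub(sub(root, "intervention"), "intervention_type", itype)
    if record.is_fda_regulated is not None or record.is_section_801 is not None:
        oversight = sub(root, "oversight_info")
        if record.is_fda_regulated is not None:
            sub(oversight, "is_fda_regulated", "Yes" if record.is_fda_regulated else "No")
        if record.is_section_801 is not None:
            sub(oversight, "is_section_801", "Yes" if record.is_section_801 else "No")
    for i in range(record.n_primary_outcomes):
        sub(sub(root, "primary_outcome"), "measure", f"Primary outcome {i + 1}")
    for i in range(record.n_secondary_outcomes):
        sub(sub(root, "secondary_outcome"), "measure", f"Secondary outcome {i + 1}")
    for i in range(record.n_references):
        sub(sub(root, "reference"), "citation", f"Reference {i + 1}")
    if record.enrollment is not None:
        attrib = {"type": record.enrollment_type} if record.enrollment_type else {}
        sub(root, "enrollment", record.enrollment, **attrib)
    if record.number_of_arms is not None:
        sub(root, "number_of_arms", record.number_of_arms)
    if record.has_results:
        results = sub(root, "clinical_results")
        sub(results, "participant_flow")
    return etree.tostring(root, encoding="unicode", pretty_print=True)


def read_corpus(directory: str | os.PathLike) -> tuple[list[TrialRecord], ParseFailureReport]:
    """Read every ``*.xml`` file in ``directory`` as one trial each.

    Returns records sorted by registry identifier together with a report of
    files that failed to parse. Duplicate identifiers across files raise
    :class:`DuplicateRecordError`; an empty directory warns and returns an
    empty corpus.
    """
    directory = Path(directory)
    report = ParseFailureReport()
    records: dict[str, TrialRecord] = {}
    paths = sorted(directory.glob("*.xml"))
    if not paths:
        warnings.warn(f"no XML files found in {directory}", stacklevel=2)
    for path in paths:
        try:
            record = read_registry_xml(path)
        except (RegistryParseError, ValueError) as exc:
            report.add(path.name, str(exc))
            continue
        if record.nct_id in records:
            raise DuplicateRecordError(f"duplicate registry identifier {record.nct_id}")
        records[record.nct_id] = record
    return [records[k] for k in sorted(records)], report


_SET_SEP = ";"

_CSV_FIELDS = [f.name for f in fields(TrialRecord)]


def _serialize_field(value) -> str:
    if value is None:
        return ""
    if isinstance(value, PartialDate):
        return value.isoformat()
    if isinstance(value, frozenset):
        return _SET_SEP.join(sorted(value))
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_tabular(corpus: Iterable[TrialRecord], path: str | os.PathLike) -> None:
    """Write a corpus as UTF-8 CSV (RFC 4180), one row per trial.

    Partial dates serialise ISO-like ("2011-12", "2011"); the file
    round-trips through :func:`read_tabular`.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for record in corpus:
            writer.writerow(
                [_serialize_field(getattr(record, name)) for name in _CSV_FIELDS]
            )


def _deserialize(name: str, text: str):
    if text == "":
        return None
    if name in ("start_date", "completion_date"):
        return PartialDate.from_iso(text)
    if name == "intervention_types":
        return frozenset(text.split(_SET_SEP))
    if name in ("is_fda_regulated", "is_section_801", "has_results"):
        return text == "true"
    if name in (
        "n_primary_outcomes",
        "n_secondary_outcomes",
        "n_references",
        "enrollment",
        "number_of_arms",
    ):
        return int(text)
    return text


def read_tabular(path: str | os.PathLike) -> list[TrialRecord]:
    """Read back a corpus written by :func:`write_tabular`."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            kwargs = {}
            for name in _CSV_FIELDS:
                value = _deserialize(name, row[name])
                if value is None and name in ("intervention_types",):
                    value = frozenset()
                if value is None and name in (
                    "n_primary_outcomes",
                    "n_secondary_outcomes",
                    "n_references",
                ):
                    value = 0
                if value is None and name == "has_results":
                    value = False
                if value is None and name in ("lead_sponsor_name",):
                    value = ""
                if value is None and name in ("agency_class",):
                    value = "Other"
                if value is None and name in ("overall_status",):
                    value = "Unknown"
                kwargs[name] = value
            records.append(TrialRecord(**kwargs))
    return records
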