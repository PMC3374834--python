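"""Prioritised keyword classification of trial lead sponsors.

Registry deposits come from many countries, so sponsor names appear in many
languages ("Hôpitaux de Paris", "Università di Bologna", "Klinikum rechts
der Isar"). Classification is rule-based: per-class keyword dictionaries
with a total priority order, matched at word boundaries against a
normalised name. Facility terms outrank generic institutional terms, so
"University Hospital Basel" is a hospital, not a university. Names matching
no keyword fall back to the registry's own four-way agency class
(Industry → com, NIH / U.S. Fed → gov, Other → unclassified).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .records import SponsorClass, TrialRecord

__all__ = [
    "normalize_name",
    "ClassDictionary",
    "FallbackMap",
    "classify_sponsor",
    "classify_corpus",
    "default_dictionary",
    "default_fallback",
]

_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Normalise a sponsor name for matching.

    Unicode compatibility normalisation (NFKC), case folding, and whitespace
    collapse; diacritics are preserved so multilingual keywords match
    exactly. Idempotent.
    """
    text = unicodedata.normalize("NFKC", raw).casefold()
    text = unicodedata.normalize("NFKC", text)
    return _WS.sub(" ", text).strip()


def _strip_diacritics(text: str) -> str:
    decomposed = unicodedata.normalize("NFD", text)
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


def _keyword_pattern(keyword: str) -> re.Pattern:
    # Word-boundary match; a trailing "." is optional at end of name so the
    # suffix convention "Pfizer Inc" matches the keyword "inc.".
    if keyword.endswith("."):
        core = re.escape(keyword[:-1])
        return re.compile(rf"(?<!\w){core}(?:\.|$)")
    return re.compile(rf"(?<!\w){re.escape(keyword)}(?!\w)")


@dataclass
class ClassDictionary:
    """Per-class keyword lists with a total priority order (highest first)."""

    entries: Mapping[SponsorClass, list[str]]
    priority: list[SponsorClass]
    fold_diacritics: bool = False
    _patterns: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, SponsorClass] = {}
        for cls, keywords in self.entries.items():
            for kw in keywords:
                norm = normalize_name(kw)
                if norm in seen and seen[norm] != cls:
                    raise ValueError(f"keyword {kw!r} assigned to two classes")
                seen[norm] = cls
        if set(self.priority) != set(self.entries):
            raise ValueError("priority order must cover exactly the dictionary classes")
        for cls in self.priority:
            normed = [normalize_name(kw) for kw in self.entries[cls]]
            if self.fold_diacritics:
                normed = [_strip_diacritics(kw) for kw in normed]
            # Longest keyword first, then lexicographic: deterministic ties.
            normed.sort(key=lambda kw: (-len(kw), kw))
            self._patterns[cls] = [(kw, _keyword_pattern(kw)) for kw in normed]

    @classmethod
    def from_yaml(cls, path_or_stream, fold_diacritics: bool = False) -> "ClassDictionary":
        if hasattr(path_or_stream, "read"):
            spec = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream, encoding="utf-8") as fh:
                spec = yaml.safe_load(fh)
        entries = {
            SponsorClass(name): list(keywords)
            for name, keywords in spec["classes"].items()
        }
        priority = [SponsorClass(name) for name in spec["priority"]]
        return cls(entries=entries, priority=priority, fold_diacritics=fold_diacritics)

    def match(self, name: str) -> tuple[SponsorClass, str] | None:
        """Best (class, keyword) match for an already-normalised name, or None."""
        if self.fold_diacritics:
            name = _strip_diacritics(name)
        for cls in self.priority:
            for keyword, pattern in self._patterns[cls]:
                if pattern.search(name):
                    return cls, keyword
        return None

    def keywords(self, cls: SponsorClass) -> list[str]:
        return list(self.entries[cls])


@dataclass
class FallbackMap:
    """Agency-class fallback for names no keyword matches."""

    mapping: Mapping[str, SponsorClass]

    def __post_init__(self) -> None:
        missing = {"Industry", "NIH", "U.S. Fed", "Other"} - set(self.mapping)
        if missing:
            raise ValueError(f"fallback map must be total; missing {sorted(missing)}")

    def __call__(self, agency_class: str) -> SponsorClass:
        return self.mapping.get(agency_class, SponsorClass.UNCLASSIFIED)


def _load_default_spec() -> dict:
    with resources.files("trialmeta.data").joinpath("sponsor_classes.yaml").open(
        encoding="utf-8"
    ) as fh:
        return yaml.safe_load(fh)


def default_dictionary(fold_diacritics: bool = False) -> ClassDictionary:
    """The shipped multilingual keyword dictionary."""
    spec = _load_default_spec()
    return ClassDictionary(
        entries={SponsorClass(k): list(v) for k, v in spec["classes"].items()},
        priority=[SponsorClass(k) for k in spec["priority"]],
        fold_diacritics=fold_diacritics,
    )


def default_fallback() -> FallbackMap:
    spec = _load_default_spec()
    return FallbackMap({k: SponsorClass(v) for k, v in spec["fallback"].items()})


def classify_sponsor(
    name: str,
    agency_class: str = "Other",
    dictionary: ClassDictionary | None = None,
    fallback: FallbackMap | None = None,
) -> SponsorClass:
    """Classify one sponsor name; total (always returns a class)."""
    dictionary = dictionary if dictionary is not None else default_dictionary()
    fallback = fallback if fallback is not None else default_fallback()
    match = dictionary.match(normalize_name(name))
    if match is not None:
        return match[0]
    return fallback(agency_class)


def classify_corpus(
    corpus: Iterable[TrialRecord],
    dictionary: ClassDictionary | None = None,
    fallback: FallbackMap | None = None,
) -> tuple[dict[str, SponsorClass], "pd.DataFrame"]:
    """Classify every trial's lead sponsor.

    Returns a total mapping ``nct_id -> SponsorClass`` and a summary frame
    with absolute count and percentage of the corpus per class.
    """
    import pandas as pd

    dictionary = dictionary if dictionary is not None else default_dictionary()
    fallback = fallback if fallback is not None else default_fallback()
    assignments: dict[str, SponsorClass] = {}
    for record in corpus:
        assignments[record.nct_id] = classify_sponsor(
            record.lead_sponsor_name, record.agency_class, dictionary, fallback
        )
    total = len(assignments)
    counts = {cls: 0 for cls in SponsorClass}
    for cls in assignments.values():
        counts[cls] += 1
    summary = pd.DataFrame(
        {
            "class": [cls.value for cls in SponsorClass],
            "count": [counts[cls] for cls in SponsorClass],
            "percent": [
                round(100.0 * counts[cls] / total, 2) if total else 0.0
                for cls in SponsorClass
            ],
        }
    )
    return assignments, summary
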