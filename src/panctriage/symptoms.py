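"""Free-text symptom mapping.

Reason-for-encounter strings are split into segments and matched against a
configurable lexicon of case-insensitive regular expressions.  Each lexicon
entry carries *include* patterns (any match asserts the symptom) and
*exclude* patterns (any match within the same segment vetoes it).  The
lexicon is configuration, not code: the default shipped with the package is
a documented, replaceable YAML file.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

#: Canonical codes for the 23 signs and symptoms used by the triage tools,
#: in stable report order.  Abbreviations follow common clinical usage:
#: ``cibh`` change in bowel habits, ``uwl`` unexpected weight loss,
#: ``vte`` venous thromboembolism, ``ep_radiating`` epigastric pain
#: radiating to the back, ``gi_bleed`` gastrointestinal bleed.
CANONICAL_SYMPTOMS: tuple[str, ...] = (
    "jaundice",
    "abdominal_pain",
    "ep_radiating",
    "back_pain",
    "abdominal_distension",
    "cibh",
    "constipation",
    "diarrhoea",
    "steatorrhoea",
    "nausea",
    "vomiting",
    "indigestion",
    "dysphagia",
    "appetite_loss",
    "uwl",
    "fatigue",
    "pruritus",
    "new_onset_diabetes",
    "pancreatitis",
    "gi_bleed",
    "vte",
    "depression_anxiety",
    "dark_urine_pale_stools",
)

_CANONICAL_SET = frozenset(CANONICAL_SYMPTOMS)

#: Default segment delimiters for multi-reason encounter text.
DEFAULT_DELIMITERS: str = ";,|\n"

VALID_SOURCES = ("text", "pathology", "prescription", "pathology_or_prescription")


def canonical_symptoms() -> list[str]:
    """Return the 23 canonical symptom codes in stable order."""
    return list(CANONICAL_SYMPTOMS)


@dataclass(frozen=True, order=True)
class SymptomEvent:
    """One dated symptom assertion for one patient.

    ``source`` records which linked table produced the event; ``provenance``
    is the matched text span (text events) or the triggering rule name
    (derived phenotypes).
    """

    patient_id: str
    event_date: _dt.date
    symptom_code: str
    source: str = "text"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.symptom_code not in _CANONICAL_SET:
            raise ValueError(f"non-canonical symptom code: {self.symptom_code!r}")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"invalid event source: {self.source!r}")


class LexiconError(ValueError):
    """Raised for an invalid symptom lexicon."""


@dataclass
class _Entry:
    code: str
    include: list[re.Pattern]
    exclude: list[re.Pattern] = field(default_factory=list)


class SymptomLexicon:
    """Compiled include/exclude regex lexicon keyed by canonical symptom code."""

    def __init__(self, entries: Mapping[str, Mapping[str, Sequence[str]]]):
        self._entries: dict[str, _Entry] = {}
        for code, spec in entries.items():
            if code not in _CANONICAL_SET:
                raise LexiconError(f"unknown symptom code in lexicon: {code!r}")
            if code in self._entries:
                raise LexiconError(f"duplicate lexicon entry: {code!r}")
            include = list(spec.get("include", []))
            exclude = list(spec.get("exclude", []))
            if not include or any(p == "" for p in include):
                raise LexiconError(f"entry {code!r} needs non-empty include patterns")
            try:
                inc = [re.compile(p, re.IGNORECASE) for p in include]
                exc = [re.compile(p, re.IGNORECASE) for p in exclude]
            except re.error as err:
                raise LexiconError(f"bad pattern for {code!r}: {err}") from err
            self._entries[code] = _Entry(code, inc, exc)

    @property
    def codes(self) -> list[str]:
        return [c for c in CANONICAL_SYMPTOMS if c in self._entries]

    def entry(self, code: str) -> _Entry:
        return self._entries[code]

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_list(cls, items: Sequence[Mapping]) -> "SymptomLexicon":
        """Build from a list of ``{code, include: [...], exclude: [...]}`` dicts."""
        entries: dict[str, dict] = {}
        for item in items:
            code = item["code"]
            if code in entries:
                raise LexiconError(f"duplicate lexicon entry: {code!r}")
            entries[code] = {
                "include": item.get("include", []),
                "exclude": item.get("exclude", []),
            }
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "SymptomLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_list(data)


def default_lexicon() -> SymptomLexicon:
    """The replaceable default lexicon shipped with the package."""
    text = resources.files("panctriage.data").joinpath("lexicon.yaml").read_text("utf-8")
    return SymptomLexicon.from_list(yaml.safe_load(text))


def split_reasons(reason_text: str, delimiters: str = DEFAULT_DELIMITERS) -> list[str]:
    """Split a multi-reason encounter string into whitespace-trimmed segments.

    Empty segments are dropped.  Joining the segments with delimiters and
    whitespace removed reconstructs the input.
    """
    if reason_text is None:
        raise ValueError("reason_text must not be None")
    pattern = "[" + re.escape(delimiters) + "]"
    return [seg.strip() for seg in re.split(pattern, reason_text) if seg.strip()]


def match_symptoms(segment: str, lexicon: SymptomLexicon) -> set[str]:
    """Codes whose include patterns match ``segment`` and exclude patterns do not.

    Matching is case-insensitive; exclusion is scoped to the segment.
    """
    matched: set[str] = set()
    for code in lexicon.codes:
        entry = lexicon.entry(code)
        if any(p.search(segment) for p in entry.include) and not any(
            p.search(segment) for p in entry.exclude
        ):
            matched.add(code)
    return matched


def _match_with_spans(segment: str, lexicon: SymptomLexicon) -> dict[str, str]:
    out: dict[str, str] = {}
    for code in lexicon.codes:
        entry = lexicon.entry(code)
        if any(p.search(segment) for p in entry.exclude):
            continue
        for p in entry.include:
            m = p.search(segment)
            if m:
                out.setdefault(code, m.group(0))
                break
    return out


def extract_symptom_events(
    encounters, lexicon: SymptomLexicon, delimiters: str = DEFAULT_DELIMITERS
) -> list[SymptomEvent]:
    """Map an encounters table to deduplicated, sorted text symptom events.

    ``encounters`` is a DataFrame (or iterable of mappings) with columns
    ``patient_id``, ``encounter_date`` and ``reason_text``.  One event is
    emitted per (encounter, matched code) pair; a code matched by several
    patterns or segments of the same encounter yields a single event.
    """
    rows: Iterable
    if hasattr(encounters, "itertuples"):
        rows = encounters.itertuples(index=False)
    else:
        from collections import namedtuple

        Row = namedtuple("Row", ["patient_id", "encounter_date", "reason_text"])
        rows = (Row(r["patient_id"], r["encounter_date"], r["reason_text"]) for r in encounters)

    seen: dict[tuple[str, _dt.date, str], str] = {}
    for row in rows:
        date = _as_date(row.encounter_date)
        for segment in split_reasons(str(row.reason_text), delimiters):
            for code, span in _match_with_spans(segment, lexicon).items():
                seen.setdefault((str(row.patient_id), date, code), span)
    events = [
        SymptomEvent(pid, date, code, source="text", provenance=span)
        for (pid, date, code), span in seen.items()
    ]
    events.sort(key=lambda e: (e.patient_id, e.event_date, e.symptom_code))
    return events


def _as_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value)[:10])
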