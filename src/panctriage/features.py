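"""Derived clinical phenotypes: new-onset diabetes and biochemical jaundice.

New-onset diabetes can be established through any of three routes —
(A) a single HbA1c at or above the diagnostic threshold, (B) two "raised"
HbA1c results more than three months apart (event at the second result), or
(C) a first prescription of a diabetes medication — with the earliest
triggering date taken as onset.  Patients with qualifying evidence before
the study start are not "new onset" and yield no event.

Biochemical jaundice is any total-bilirubin result strictly above the
configured upper limit of normal.
"""

from __future__ import annotations

import datetime as _dt
from collections import defaultdict
from importlib import resources
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from panctriage.symptoms import SymptomEvent, _as_date

# NGSP/IFCC master equation: NGSP% = 0.09148 * IFCC(mmol/mol) + 2.152
_IFCC_SLOPE = 0.09148
_IFCC_OFFSET = 2.152

_SOURCE_RANK = {"text": 0, "pathology": 1, "prescription": 2, "pathology_or_prescription": 3}


def _default_medication_lexicon() -> list[dict]:
    text = (
        resources.files("panctriage.data")
        .joinpath("diabetes_medications.yaml")
        .read_text("utf-8")
    )
    return yaml.safe_load(text)


class FeatureConfig(BaseModel):
    """Thresholds and lexica for the derived phenotypes."""

    hba1c_threshold_pct: float = 6.5
    hba1c_threshold_mmolmol: float = 48.0
    hba1c_raised_pct: Optional[float] = None  # route-B "raised" level; default = threshold
    paired_result_min_gap_days: int = 92
    bilirubin_upper_limit_umol: float = 21.0
    diabetes_medication_lexicon: list[dict] = Field(default_factory=_default_medication_lexicon)
    diabetes_washout_days: Optional[int] = None  # None = entire prior record

    @field_validator("hba1c_threshold_pct", "hba1c_threshold_mmolmol", "bilirubin_upper_limit_umol")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("threshold must be positive")
        return v

    @field_validator("paired_result_min_gap_days")
    @classmethod
    def _gap(cls, v: int) -> int:
        if v < 1:
            raise ValueError("paired_result_min_gap_days must be >= 1")
        return v

    @model_validator(mode="after")
    def _lexicon_nonempty(self) -> "FeatureConfig":
        if not self.diabetes_medication_lexicon:
            raise ValueError("diabetes_medication_lexicon must be non-empty")
        return self

    @property
    def raised_pct(self) -> float:
        return self.hba1c_raised_pct if self.hba1c_raised_pct is not None else self.hba1c_threshold_pct

    def medication_terms(self) -> list[str]:
        terms: list[str] = []
        for entry in self.diabetes_medication_lexicon:
            terms.append(str(entry["generic"]).lower())
            terms.extend(str(b).lower() for b in entry.get("brands", []))
        return terms


def normalise_hba1c(value: float, units: str) -> float:
    """Convert an HbA1c result to NGSP percent units.

    mmol/mol values are converted with the NGSP/IFCC master equation;
    percent values pass through unchanged.
    """
    if value <= 0:
        raise ValueError(f"HbA1c value must be positive, got {value}")
    if units == "%":
        return float(value)
    if units == "mmol/mol":
        return _IFCC_SLOPE * float(value) + _IFCC_OFFSET
    raise ValueError(f"unknown HbA1c units: {units!r}")


def _iter_rows(table, fields: Sequence[str]):
    if table is None:
        return
    if hasattr(table, "itertuples"):
        for row in table.itertuples(index=False):
            yield tuple(getattr(row, f) for f in fields)
    else:
        for row in table:
            yield tuple(row[f] for f in fields)


def detect_new_onset_diabetes(
    pathology,
    prescriptions,
    config: FeatureConfig,
    study_start: Optional[_dt.date] = None,
) -> list[SymptomEvent]:
    """Detect new-onset diabetes, at most one event per patient.

    The event date is the earliest date at which any route triggers.  When
    ``study_start`` is given, any diabetes evidence (a raised HbA1c or a
    diabetes prescription) dated before it disqualifies the patient —
    optionally limited to a ``diabetes_washout_days`` lookback.
    """
    elevated: dict[str, list[_dt.date]] = defaultdict(list)
    raised: dict[str, list[_dt.date]] = defaultdict(list)
    meds: dict[str, list[_dt.date]] = defaultdict(list)
    routes: dict[str, dict[_dt.date, str]] = defaultdict(dict)

    for pid, date, analyte, value, units in _iter_rows(
        pathology, ("patient_id", "result_date", "analyte", "value", "units")
    ):
        if analyte != "hba1c":
            continue
        pct = normalise_hba1c(float(value), str(units))
        date = _as_date(date)
        pid = str(pid)
        if pct >= config.hba1c_threshold_pct:
            elevated[pid].append(date)
        if pct >= config.raised_pct:
            raised[pid].append(date)

    terms = config.medication_terms()
    for pid, date, name in _iter_rows(
        prescriptions, ("patient_id", "script_date", "medication_name")
    ):
        lowered = str(name).lower()
        if any(t in lowered for t in terms):
            meds[str(pid)].append(_as_date(date))

    # evidence older than the washout lookback is stale: ignored entirely
    cutoff: Optional[_dt.date] = None
    if study_start is not None and config.diabetes_washout_days is not None:
        cutoff = study_start - _dt.timedelta(days=config.diabetes_washout_days)

    events: list[SymptomEvent] = []
    for pid in sorted(set(elevated) | set(raised) | set(meds)):
        ele, rai, med = elevated[pid], raised[pid], meds[pid]
        if cutoff is not None:
            ele = [d for d in ele if d >= cutoff]
            rai = [d for d in rai if d >= cutoff]
            med = [d for d in med if d >= cutoff]
        candidates: list[tuple[_dt.date, str]] = []
        for d in ele:
            candidates.append((d, "hba1c_elevated"))
        pair_date = _earliest_pair_trigger(rai, config.paired_result_min_gap_days)
        if pair_date is not None:
            candidates.append((pair_date, "hba1c_paired_raised"))
        for d in med:
            candidates.append((d, "diabetes_medication"))
        if not candidates:
            continue
        if study_start is not None and any(d < study_start for d in rai + med + ele):
            continue
        onset, route = min(candidates)
        events.append(
            SymptomEvent(pid, onset, "new_onset_diabetes", source="pathology_or_prescription", provenance=route)
        )
    events.sort(key=lambda e: (e.patient_id, e.event_date, e.symptom_code))
    return events


def _earliest_pair_trigger(dates: list[_dt.date], min_gap_days: int) -> Optional[_dt.date]:
    """Earliest second result that is >= min_gap_days after an earlier raised result."""
    ds = sorted(dates)
    for i, second in enumerate(ds):
        if any((second - first).days >= min_gap_days for first in ds[:i]):
            return second
    return None


def detect_biochemical_jaundice(pathology, config: FeatureConfig) -> list[SymptomEvent]:
    """One jaundice event per bilirubin result strictly above the upper limit."""
    events: list[SymptomEvent] = []
    for pid, date, analyte, value, units in _iter_rows(
        pathology, ("patient_id", "result_date", "analyte", "value", "units")
    ):
        if analyte != "bilirubin_total":
            continue
        if float(value) > config.bilirubin_upper_limit_umol:
            events.append(
                SymptomEvent(
                    str(pid),
                    _as_date(date),
                    "jaundice",
                    source="pathology",
                    provenance=f"bilirubin {float(value):g} umol/L",
                )
            )
    events.sort(key=lambda e: (e.patient_id, e.event_date, e.symptom_code))
    return events


def merge_events(*streams: Sequence[SymptomEvent]) -> list[SymptomEvent]:
    """Merge event streams, deduplicating on (patient, date, code).

    When the same symptom is asserted on the same date by several sources
    (e.g. text jaundice and raised bilirubin), the text-sourced event wins.
    """
    best: dict[tuple[str, _dt.date, str], SymptomEvent] = {}
    for stream in streams:
        for ev in stream:
            key = (ev.patient_id, ev.event_date, ev.symptom_code)
            cur = best.get(key)
            if cur is None or _SOURCE_RANK[ev.source] < _SOURCE_RANK[cur.source]:
                best[key] = ev
    merged = list(best.values())
    merged.sort(key=lambda e: (e.patient_id, e.event_date, e.symptom_code))
    return merged
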