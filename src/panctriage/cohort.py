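"""Cohort construction: eligibility, study entry, accumulation window,
stopping rules, index date and follow-up outcome.

For each tool, a patient enters at their first event whose symptom code the
tool uses.  Events are then scanned chronologically (same-day events as one
batch) for up to ``accumulation_window_days``; at each batch the tool is
re-evaluated on the accumulated event-code set.  Scanning stops at the
earliest of: the tool flagging, a cancer diagnosis, or the window end.  The
index date is the flag date if flagged, otherwise the last qualifying event
seen before stopping; the outcome is a registry diagnosis within
``followup_window_days`` after the index date (a diagnosis on the index
date itself counts).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from pydantic import BaseModel, model_validator

from panctriage.features import (
    FeatureConfig,
    detect_biochemical_jaundice,
    detect_new_onset_diabetes,
    merge_events,
)
from panctriage.symptoms import (
    SymptomEvent,
    SymptomLexicon,
    _as_date,
    extract_symptom_events,
)
from panctriage.tools import RiskModel, RuleSet, qcancer_flag, qcancer_risk, rule_flag


class CohortConfig(BaseModel):
    study_start: _dt.date = _dt.date(2007, 7, 1)
    study_end: _dt.date = _dt.date(2021, 6, 30)
    registry_end: _dt.date = _dt.date(2022, 6, 30)
    age_min: int = 40
    age_max: int = 100
    accumulation_window_days: int = 365
    followup_window_days: int = 365
    precovid_end: Optional[_dt.date] = _dt.date(2019, 12, 31)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if not (self.study_start < self.study_end <= self.registry_end):
            raise ValueError("require study_start < study_end <= registry_end")
        if self.accumulation_window_days <= 0 or self.followup_window_days <= 0:
            raise ValueError("windows must be positive")
        return self


@dataclass
class EventTimeline:
    """Per-patient date-ordered symptom events plus demographics and outcome."""

    patient_id: str
    sex: str
    birth_date: _dt.date
    events: list[SymptomEvent] = field(default_factory=list)
    bmi: Optional[float] = None
    seifa_percentile: Optional[int] = None
    cancer_diagnosis: Optional[tuple[_dt.date, str]] = None

    def age_at(self, date: _dt.date) -> float:
        """Completed years at ``date``."""
        years = date.year - self.birth_date.year
        if (date.month, date.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        return float(years)

    @property
    def first_event_date(self) -> Optional[_dt.date]:
        return self.events[0].event_date if self.events else None


@dataclass
class ToolEvaluation:
    patient_id: str
    tool: str
    eligible: bool
    entry_date: Optional[_dt.date] = None
    flagged: bool = False
    flag_date: Optional[_dt.date] = None
    index_date: Optional[_dt.date] = None
    outcome_cancer_12m: bool = False
    censoring_note: str = ""


def build_timelines(
    tables: dict,
    lexicon: SymptomLexicon,
    feature_config: FeatureConfig,
    cohort_config: CohortConfig,
) -> tuple[list[EventTimeline], dict]:
    """Assemble per-patient timelines from the linked tables.

    Returns the timelines plus a flow-count dict describing the exclusion
    cascade (encounters considered / dropped, patients without relevant
    symptoms, age exclusions, prior-diagnosis exclusions, final cohort).
    """
    flow: dict[str, int] = {}
    patients = tables["patients"]
    encounters = tables["encounters"]
    pathology = tables.get("pathology")
    prescriptions = tables.get("prescriptions")
    registry = tables.get("registry")

    known = {str(p) for p in patients["patient_id"]}
    flow["patients_total"] = len(known)

    enc = encounters.copy()
    flow["encounters_total"] = len(enc)
    mask = enc["encounter_date"].notna() & enc["reason_text"].notna()
    mask &= enc["reason_text"].astype(str).str.strip() != ""
    enc = enc[mask]
    flow["encounters_dropped_missing"] = flow["encounters_total"] - len(enc)
    orphan = ~enc["patient_id"].astype(str).isin(known)
    if orphan.any():
        flow["encounter_orphans_skipped"] = int(orphan.sum())
        enc = enc[~orphan]

    text_events = extract_symptom_events(enc, lexicon)
    diabetes_events = detect_new_onset_diabetes(
        pathology, prescriptions, feature_config, study_start=cohort_config.study_start
    )
    jaundice_events = detect_biochemical_jaundice(pathology, feature_config)
    merged = merge_events(text_events, diabetes_events, jaundice_events)
    merged = [
        e
        for e in merged
        if cohort_config.study_start <= e.event_date <= cohort_config.registry_end
        and e.patient_id in known
    ]
    flow["symptom_events"] = len(merged)

    by_patient: dict[str, list[SymptomEvent]] = {}
    for ev in merged:
        by_patient.setdefault(ev.patient_id, []).append(ev)

    diagnosis: dict[str, tuple[_dt.date, str]] = {}
    if registry is not None:
        for row in registry.itertuples(index=False):
            code = str(row.icd10_code)
            if not code.startswith("C25"):
                continue
            pid = str(row.patient_id)
            d = _as_date(row.diagnosis_date)
            if pid not in diagnosis or d < diagnosis[pid][0]:
                diagnosis[pid] = (d, code)

    demo: dict[str, tuple] = {}
    for row in patients.itertuples(index=False):
        bmi = getattr(row, "bmi", None)
        seifa = getattr(row, "seifa_percentile", None)
        bmi = None if bmi is None or bmi != bmi else float(bmi)
        seifa = None if seifa is None or seifa != seifa else int(seifa)
        demo[str(row.patient_id)] = (str(row.sex), _as_date(row.birth_date), bmi, seifa)

    timelines: list[EventTimeline] = []
    n_no_symptoms = n_age = n_prior_dx = n_entry_window = 0
    for pid in sorted(demo):
        sex, birth, bmi, seifa = demo[pid]
        events = by_patient.get(pid, [])
        if not events:
            n_no_symptoms += 1
            continue
        tl = EventTimeline(
            patient_id=pid,
            sex=sex,
            birth_date=birth,
            events=events,
            bmi=bmi,
            seifa_percentile=seifa,
            cancer_diagnosis=diagnosis.get(pid),
        )
        first = tl.first_event_date
        if first > cohort_config.study_end:
            n_entry_window += 1
            continue
        age = tl.age_at(first)
        if age < cohort_config.age_min or age > cohort_config.age_max:
            n_age += 1
            continue
        if tl.cancer_diagnosis is not None and tl.cancer_diagnosis[0] < first:
            n_prior_dx += 1
            continue
        timelines.append(tl)

    flow["patients_no_relevant_symptoms"] = n_no_symptoms
    flow["patients_entry_after_study_end"] = n_entry_window
    flow["patients_excluded_age"] = n_age
    flow["patients_excluded_prior_diagnosis"] = n_prior_dx
    flow["cohort_size"] = len(timelines)
    flow["cohort_cancers"] = sum(1 for t in timelines if t.cancer_diagnosis is not None)
    return timelines, flow


def evaluate_tool(
    timeline: EventTimeline,
    tool: Union[RuleSet, RiskModel],
    config: CohortConfig,
) -> ToolEvaluation:
    """Run one tool over one timeline; see module docstring for semantics."""
    tool_codes = tool.symptom_codes
    name = tool.tool_name
    entry_event = next((e for e in timeline.events if e.symptom_code in tool_codes), None)
    if entry_event is None:
        return ToolEvaluation(timeline.patient_id, name, eligible=False,
                              censoring_note="no qualifying symptom for tool")
    entry = entry_event.event_date

    is_risk_model = isinstance(tool, RiskModel)
    if is_risk_model:
        if timeline.sex not in tool.sexes:
            return ToolEvaluation(timeline.patient_id, name, eligible=False,
                                  entry_date=entry, censoring_note="sex not supported by model")
        age_entry = timeline.age_at(entry)
        if age_entry < tool.age_min or age_entry > tool.age_max:
            return ToolEvaluation(timeline.patient_id, name, eligible=False,
                                  entry_date=entry, censoring_note="age outside model range")

    window_end = entry + _dt.timedelta(days=config.accumulation_window_days)
    dx_date = timeline.cancer_diagnosis[0] if timeline.cancer_diagnosis else None

    # group events into same-day batches within [entry, window_end]
    batches: dict[_dt.date, set[str]] = {}
    for ev in timeline.events:
        if entry <= ev.event_date <= window_end:
            batches.setdefault(ev.event_date, set()).add(ev.symptom_code)

    accumulated: set[str] = set()
    flagged = False
    flag_date: Optional[_dt.date] = None
    last_qualifying: Optional[_dt.date] = None
    note = "window end"
    for d in sorted(batches):
        if dx_date is not None and d > dx_date:
            note = "stopped at diagnosis"
            break
        accumulated |= batches[d]
        if batches[d] & tool_codes:
            last_qualifying = d
        age = timeline.age_at(d)
        if is_risk_model:
            risk = qcancer_risk(
                {
                    "age": age,
                    "sex": timeline.sex,
                    "symptoms": accumulated,
                    "bmi": timeline.bmi,
                    "deprivation": timeline.seifa_percentile,
                },
                tool,
            )
            hit = qcancer_flag(risk, tool)
        else:
            hit, _ = rule_flag(accumulated, age, timeline.sex, tool)
        if hit:
            flagged = True
            flag_date = d
            note = "flagged"
            break

    index_date = flag_date if flagged else last_qualifying
    outcome = False
    if index_date is not None and dx_date is not None:
        delta = (dx_date - index_date).days
        outcome = 0 <= delta <= config.followup_window_days
    return ToolEvaluation(
        patient_id=timeline.patient_id,
        tool=name,
        eligible=True,
        entry_date=entry,
        flagged=flagged,
        flag_date=flag_date,
        index_date=index_date,
        outcome_cancer_12m=outcome,
        censoring_note=note,
    )


def apply_precovid_filter(
    timelines: Sequence[EventTimeline], config: CohortConfig
) -> list[EventTimeline]:
    """Sensitivity-analysis subset: keep patients entering on or before
    ``precovid_end``.  Identity when ``precovid_end`` is None."""
    if config.precovid_end is None:
        return list(timelines)
    return [t for t in timelines if t.first_event_date is not None
            and t.first_event_date <= config.precovid_end]
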