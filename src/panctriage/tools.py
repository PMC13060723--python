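"""Triage-tool engines.

Two engine families cover all three tools:

* a declarative combination-rule engine (eRAT, QPaC): a ``RuleSet`` of
  clauses, each a set of symptoms that must co-occur within the
  accumulation window, optionally age/sex restricted;
* a coefficient-driven sex-specific logistic score with a probability
  threshold (QCancer): a ``RiskModel`` loaded from a coefficient file,
  with standard defaults substituted for missing BMI/deprivation.

The behavioural differences between eRAT and QPaC live entirely in their
ruleset files; the engine is shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import yaml

from panctriage.symptoms import CANONICAL_SYMPTOMS

_CANONICAL_SET = frozenset(CANONICAL_SYMPTOMS)


class ToolConfigError(ValueError):
    """Raised for an invalid ruleset or risk-model configuration."""


@dataclass(frozen=True)
class Clause:
    """One high-risk combination: all symptoms required, age/sex optional."""

    required_symptoms: frozenset[str]
    min_age: Optional[float] = None
    max_age: Optional[float] = None
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.required_symptoms:
            raise ToolConfigError("clause must require at least one symptom")
        unknown = self.required_symptoms - _CANONICAL_SET
        if unknown:
            raise ToolConfigError(f"unknown symptom code(s) in clause: {sorted(unknown)}")

    def matches(self, codes: frozenset[str] | set[str], age: float, sex: str) -> bool:
        if not self.required_symptoms <= set(codes):
            return False
        if self.min_age is not None and age < self.min_age:
            return False
        if self.max_age is not None and age > self.max_age:
            return False
        if self.sex is not None and sex != self.sex:
            return False
        return True


@dataclass
class RuleSet:
    tool_name: str
    clauses: list[Clause]
    provenance_note: str = ""

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ToolConfigError("ruleset must contain at least one clause")

    @property
    def symptom_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clauses:
            out |= c.required_symptoms
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "tool_name": self.tool_name,
            "provenance_note": self.provenance_note,
            "clauses": [
                {
                    "required_symptoms": sorted(c.required_symptoms),
                    **({"min_age": c.min_age} if c.min_age is not None else {}),
                    **({"max_age": c.max_age} if c.max_age is not None else {}),
                    **({"sex": c.sex} if c.sex is not None else {}),
                }
                for c in self.clauses
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RuleSet":
        clauses = [
            Clause(
                required_symptoms=frozenset(c["required_symptoms"]),
                min_age=c.get("min_age"),
                max_age=c.get("max_age"),
                sex=c.get("sex"),
            )
            for c in data.get("clauses", [])
        ]
        return cls(
            tool_name=data["tool_name"],
            clauses=clauses,
            provenance_note=data.get("provenance_note", ""),
        )


def load_ruleset(path) -> RuleSet:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return RuleSet.from_dict(data)


def save_ruleset(ruleset: RuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(ruleset.to_dict(), fh, sort_keys=False)


def rule_flag(
    event_codes_in_window: set[str] | frozenset[str],
    age: float,
    sex: str,
    ruleset: RuleSet,
) -> tuple[bool, Optional[int]]:
    """Evaluate a combination ruleset against the windowed event-code set.

    Returns ``(flagged, index of first matching clause or None)``.  The flag
    status does not depend on clause order; the returned index is provenance
    only.
    """
    for i, clause in enumerate(ruleset.clauses):
        if clause.matches(event_codes_in_window, age, sex):
            return True, i
    return False, None


@dataclass
class _SexParams:
    intercept: float
    age_per_decade: float = 0.0
    age_ref: float = 60.0
    bmi_per_unit: float = 0.0
    deprivation_per_decile: float = 0.0
    symptoms: dict[str, float] = field(default_factory=dict)


@dataclass
class RiskModel:
    """Sex-specific logistic risk score with a probability threshold."""

    model_name: str
    sexes: dict[str, _SexParams]
    threshold: float = 0.02
    age_min: float = 25
    age_max: float = 89
    default_bmi: float = 25.0
    default_deprivation: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ToolConfigError("threshold must be in (0, 1)")
        for sex in ("male", "female"):
            if sex not in self.sexes:
                raise ToolConfigError(f"risk model must define sex {sex!r}")
        for sex, params in self.sexes.items():
            unknown = set(params.symptoms) - _CANONICAL_SET
            if unknown:
                raise ToolConfigError(f"unknown symptom code(s) for {sex}: {sorted(unknown)}")
            values = [params.intercept, params.age_per_decade, params.bmi_per_unit,
                      params.deprivation_per_decile, *params.symptoms.values()]
            if not all(math.isfinite(v) for v in values):
                raise ToolConfigError(f"non-finite coefficient for sex {sex!r}")

    @property
    def tool_name(self) -> str:
        return self.model_name

    @property
    def symptom_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for params in self.sexes.values():
            out |= set(params.symptoms)
        return frozenset(out)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RiskModel":
        sexes = {
            sex: _SexParams(
                intercept=float(p["intercept"]),
                age_per_decade=float(p.get("age_per_decade", 0.0)),
                age_ref=float(p.get("age_ref", 60.0)),
                bmi_per_unit=float(p.get("bmi_per_unit", 0.0)),
                deprivation_per_decile=float(p.get("deprivation_per_decile", 0.0)),
                symptoms={k: float(v) for k, v in p.get("symptoms", {}).items()},
            )
            for sex, p in data["sexes"].items()
        }
        return cls(
            model_name=data.get("model_name", "risk_model"),
            sexes=sexes,
            threshold=float(data.get("threshold", 0.02)),
            age_min=float(data.get("age_min", 25)),
            age_max=float(data.get("age_max", 89)),
            default_bmi=float(data.get("default_bmi", 25.0)),
            default_deprivation=float(data.get("default_deprivation", 50.0)),
        )


def load_riskmodel(path) -> RiskModel:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return RiskModel.from_dict(data)


def qcancer_risk(covariates: Mapping, model: RiskModel) -> Optional[float]:
    """Predicted probability for one patient, or None if ineligible.

    ``covariates``: age, sex, symptoms (set/iterable of codes), and optional
    bmi / deprivation (missing values replaced by the model defaults).
    Patients of unknown sex or outside the model's age range are ineligible
    and yield ``None`` rather than an exception.
    """
    sex = covariates.get("sex")
    if sex not in model.sexes:
        return None
    age = float(covariates["age"])
    if age < model.age_min or age > model.age_max:
        return None
    params = model.sexes[sex]
    bmi = covariates.get("bmi")
    bmi = model.default_bmi if bmi is None else float(bmi)
    deprivation = covariates.get("deprivation")
    deprivation = model.default_deprivation if deprivation is None else float(deprivation)
    codes = set(covariates.get("symptoms", ()))

    lp = params.intercept
    lp += params.age_per_decade * (age - params.age_ref) / 10.0
    lp += params.bmi_per_unit * (bmi - model.default_bmi)
    lp += params.deprivation_per_decile * (deprivation - model.default_deprivation) / 10.0
    lp += sum(coef for code, coef in params.symptoms.items() if code in codes)
    return 1.0 / (1.0 + math.exp(-lp))


def qcancer_flag(risk: Optional[float], model: RiskModel) -> bool:
    """Strict threshold: flag iff risk > threshold."""
    if risk is None:
        return False
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk must be a probability, got {risk}")
    return risk > model.threshold


def _data_path(name: str):
    return resources.files("panctriage.data").joinpath(name)


def default_erat_ruleset() -> RuleSet:
    return RuleSet.from_dict(yaml.safe_load(_data_path("erat_rules.yaml").read_text("utf-8")))


def default_qpac_ruleset() -> RuleSet:
    return RuleSet.from_dict(yaml.safe_load(_data_path("qpac_rules.yaml").read_text("utf-8")))


def default_qcancer_model() -> RiskModel:
    return RiskModel.from_dict(
        yaml.safe_load(_data_path("qcancer_coefficients.yaml").read_text("utf-8"))
    )
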