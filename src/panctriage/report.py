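"""End-to-end orchestration and machine-readable result surfaces.

``run_pipeline`` sequences generation (or loading), symptom extraction,
phenotype derivation, cohort construction, tool evaluation and statistics,
and writes a seven-file bundle:

* ``cohort_flow.json`` — exclusion-cascade counts,
* ``table1.csv`` — cohort characteristics by cancer status,
* ``prevalence.csv`` — per-symptom presence by cancer status + pre-diagnosis,
* ``per_symptom_ppv.csv`` — single-symptom PPVs,
* ``tool_confusion.csv`` / ``tool_stats.csv`` — per-tool 2x2 counts and
  the seven accuracy statistics (percentages rounded to 2 dp in CSV),
* ``provenance.json`` — config hash, seed, versions, full-precision stats.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from panctriage.cohort import (
    CohortConfig,
    EventTimeline,
    ToolEvaluation,
    build_timelines,
    evaluate_tool,
)
from panctriage.features import FeatureConfig
from panctriage.stats import (
    accuracy,
    confusion_from_evaluations,
    compare_proportions,
    likelihood_ratios,
    npv,
    per_symptom_ppv,
    ppv,
    sensitivity,
    specificity,
)
from panctriage.symptoms import CANONICAL_SYMPTOMS, SymptomLexicon, default_lexicon
from panctriage.synthetic import SimConfig, generate_cohort_data
from panctriage.tables import read_tables, write_tables
from panctriage.tools import (
    default_erat_ruleset,
    default_qcancer_model,
    default_qpac_ruleset,
    load_riskmodel,
    load_ruleset,
)

BUNDLE_FILES = (
    "cohort_flow.json",
    "table1.csv",
    "prevalence.csv",
    "per_symptom_ppv.csv",
    "tool_confusion.csv",
    "tool_stats.csv",
    "provenance.json",
)


class RunConfig(BaseModel):
    """Top-level pipeline configuration (YAML-loadable)."""

    input_dir: Optional[str] = None
    sim: Optional[SimConfig] = None
    lexicon_path: Optional[str] = None
    feature: FeatureConfig = Field(default_factory=FeatureConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    erat_ruleset_path: Optional[str] = None
    qpac_ruleset_path: Optional[str] = None
    qcancer_coefficients_path: Optional[str] = None
    output_dir: str = "panctriage_out"
    seed: int = 0
    precovid_only: bool = False

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.input_dir is None) == (self.sim is None):
            raise ValueError("provide exactly one of input_dir or sim")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Printed-proportion arithmetic: 100*num/den rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def _median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(list(values), dtype=float)
    return (
        float(np.median(arr)),
        float(np.percentile(arr, 25)),
        float(np.percentile(arr, 75)),
    )


def summarise_cohort(
    timelines: Sequence[EventTimeline], config: Optional[CohortConfig] = None
) -> dict:
    """Cohort characteristics by cancer status, plus pre-diagnosis symptom
    incidence among cancer patients.

    ``prediagnosis_symptomatic`` counts cancer patients with at least one
    event in the follow-back window before diagnosis; the per-symptom
    breakdown is relative to those symptomatic patients.
    """
    if not timelines:
        raise ValueError("no timelines to summarise")
    config = config or CohortConfig()
    window = config.followup_window_days
    cancer = [t for t in timelines if t.cancer_diagnosis is not None]
    non_cancer = [t for t in timelines if t.cancer_diagnosis is None]

    out: dict = {"n_total": len(timelines), "n_cancer": len(cancer), "n_non_cancer": len(non_cancer)}
    for label, group in (("cancer", cancer), ("non_cancer", non_cancer)):
        if not group:
            out[label] = {"note": "empty stratum"}
            continue
        ages = [t.age_at(t.first_event_date) for t in group]
        counts = [len(t.events) for t in group]
        med, q1, q3 = _median_iqr(ages)
        cmed, cq1, cq3 = _median_iqr(counts)
        out[label] = {
            "n": len(group),
            "sex": {s: sum(1 for t in group if t.sex == s) for s in ("male", "female", "unknown")},
            "age_at_presentation": {"median": med, "q1": q1, "q3": q3},
            "n_presentations": {"median": cmed, "q1": cq1, "q3": cq3},
        }

    if cancer:
        predx = [
            t for t in cancer
            if any(0 <= (t.cancer_diagnosis[0] - e.event_date).days <= window for e in t.events)
        ]
        out["prediagnosis_symptomatic"] = {
            "n": len(predx),
            "of": len(cancer),
            "pct": percentage(len(predx), len(cancer), 1),
        }
        breakdown: dict[str, dict] = {}
        for code in CANONICAL_SYMPTOMS:
            n_code = sum(
                1 for t in predx
                if any(
                    e.symptom_code == code
                    and 0 <= (t.cancer_diagnosis[0] - e.event_date).days <= window
                    for e in t.events
                )
            )
            if n_code:
                breakdown[code] = {"n": n_code, "pct": percentage(n_code, len(predx), 1)}
        out["prediagnosis_symptoms"] = breakdown
    else:
        out["prediagnosis_symptomatic"] = {"note": "empty cancer stratum"}
    return out


def prevalence_table(
    timelines: Sequence[EventTimeline], config: Optional[CohortConfig] = None
) -> pd.DataFrame:
    """Per-symptom presence proportions by cancer status with chi-square
    comparison (the Fig-3A-style surface)."""
    cancer = [t for t in timelines if t.cancer_diagnosis is not None]
    non_cancer = [t for t in timelines if t.cancer_diagnosis is None]
    rows = []
    for code in CANONICAL_SYMPTOMS:
        has_c = [any(e.symptom_code == code for e in t.events) for t in cancer]
        has_n = [any(e.symptom_code == code for e in t.events) for t in non_cancer]
        test = compare_proportions(has_c, has_n) if cancer and non_cancer else None
        rows.append(
            {
                "symptom": code,
                "n_cancer": int(sum(has_c)),
                "prop_cancer": round(sum(has_c) / len(cancer), 4) if cancer else "",
                "n_non_cancer": int(sum(has_n)),
                "prop_non_cancer": round(sum(has_n) / len(non_cancer), 4) if non_cancer else "",
                "chi2": round(test[0], 4) if test else "",
                "p_value": round(test[1], 6) if test else "",
            }
        )
    return pd.DataFrame(rows)


def _stat_rows(tool: str, cm, level: float = 0.95) -> tuple[list[dict], dict]:
    named = {
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "ppv": ppv(cm),
        "npv": npv(cm),
        "accuracy": accuracy(cm),
    }
    lr_plus, lr_minus = likelihood_ratios(cm, level)
    rows: list[dict] = []
    full: dict = {}
    for name, stat in named.items():
        if stat is None:
            rows.append({"tool": tool, "statistic": name, "estimate": "", "ci_low": "",
                         "ci_high": "", "method": "undefined"})
            full[name] = None
        else:
            pct = stat.scaled(100.0)
            rows.append({"tool": tool, "statistic": name,
                         "estimate": round(pct.estimate, 2), "ci_low": round(pct.ci_low, 2),
                         "ci_high": round(pct.ci_high, 2), "method": stat.method})
            full[name] = {"estimate": stat.estimate, "ci_low": stat.ci_low,
                          "ci_high": stat.ci_high, "method": stat.method}
    for name, stat in (("lr_plus", lr_plus), ("lr_minus", lr_minus)):
        if stat is None:
            rows.append({"tool": tool, "statistic": name, "estimate": "", "ci_low": "",
                         "ci_high": "", "method": "undefined"})
            full[name] = None
        else:
            rows.append({"tool": tool, "statistic": name,
                         "estimate": round(stat.estimate, 2), "ci_low": round(stat.ci_low, 2),
                         "ci_high": round(stat.ci_high, 2), "method": stat.method})
            full[name] = {"estimate": stat.estimate, "ci_low": stat.ci_low,
                          "ci_high": stat.ci_high, "method": stat.method}
    return rows, full


def _table1_df(summary: dict) -> pd.DataFrame:
    rows = []
    for stratum in ("cancer", "non_cancer"):
        block = summary.get(stratum, {})
        if "note" in block:
            rows.append({"stratum": stratum, "measure": "note", "value": block["note"]})
            continue
        rows.append({"stratum": stratum, "measure": "n", "value": block["n"]})
        for s, n in block["sex"].items():
            rows.append({"stratum": stratum, "measure": f"sex_{s}", "value": n})
        a = block["age_at_presentation"]
        rows.append({"stratum": stratum, "measure": "age_median_q1_q3",
                     "value": f"{a['median']:g} ({a['q1']:g}, {a['q3']:g})"})
        c = block["n_presentations"]
        rows.append({"stratum": stratum, "measure": "presentations_median_q1_q3",
                     "value": f"{c['median']:g} ({c['q1']:g}, {c['q3']:g})"})
    ps = summary.get("prediagnosis_symptomatic", {})
    if "pct" in ps:
        rows.append({"stratum": "cancer", "measure": "prediagnosis_symptomatic",
                     "value": f"{ps['n']}/{ps['of']} ({ps['pct']}%)"})
    return pd.DataFrame(rows, columns=["stratum", "measure", "value"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and write the report bundle; returns the bundle
    as in-memory objects (plus the output paths)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim = config.sim.model_copy(update={"seed": config.seed})
        tables = generate_cohort_data(sim)
        config_digest = hashlib.sha256(
            sim.model_dump_json().encode("utf-8")
        ).hexdigest()
    else:
        tables = read_tables(config.input_dir)
        config_digest = hashlib.sha256(str(config.input_dir).encode("utf-8")).hexdigest()

    lexicon = (
        SymptomLexicon.from_yaml(config.lexicon_path)
        if config.lexicon_path
        else default_lexicon()
    )
    timelines, flow = build_timelines(tables, lexicon, config.feature, config.cohort)
    if config.precovid_only:
        from panctriage.cohort import apply_precovid_filter

        timelines = apply_precovid_filter(timelines, config.cohort)
        flow["cohort_size_precovid"] = len(timelines)

    summary = summarise_cohort(timelines, config.cohort) if timelines else {}
    prevalence = prevalence_table(timelines, config.cohort)

    ppv_rows = []
    for code in CANONICAL_SYMPTOMS:
        stat = per_symptom_ppv(timelines, code, config.cohort)
        if stat is None:
            ppv_rows.append({"symptom": code, "ppv_pct": "", "ci_low": "", "ci_high": "",
                             "method": "undefined"})
        else:
            pct = stat.scaled(100.0)
            ppv_rows.append({"symptom": code, "ppv_pct": round(pct.estimate, 2),
                             "ci_low": round(pct.ci_low, 2), "ci_high": round(pct.ci_high, 2),
                             "method": stat.method})

    tools = {
        "eRAT": load_ruleset(config.erat_ruleset_path) if config.erat_ruleset_path
        else default_erat_ruleset(),
        "QPaC": load_ruleset(config.qpac_ruleset_path) if config.qpac_ruleset_path
        else default_qpac_ruleset(),
        "QCancer": load_riskmodel(config.qcancer_coefficients_path)
        if config.qcancer_coefficients_path else default_qcancer_model(),
    }
    confusion_rows = []
    stat_rows: list[dict] = []
    stats_full: dict = {}
    evaluations: dict[str, list[ToolEvaluation]] = {}
    for label, tool in tools.items():
        evs = [evaluate_tool(t, tool, config.cohort) for t in timelines]
        evaluations[label] = evs
        eligible = [e for e in evs if e.eligible]
        if not eligible:
            confusion_rows.append({"tool": label, "tp": 0, "fp": 0, "fn": 0, "tn": 0,
                                   "n_eligible": 0})
            continue
        cm = confusion_from_evaluations(eligible)
        confusion_rows.append({"tool": label, "tp": cm.tp, "fp": cm.fp, "fn": cm.fn,
                               "tn": cm.tn, "n_eligible": cm.total})
        rows, full = _stat_rows(label, cm)
        stat_rows.extend(rows)
        stats_full[label] = full

    flow_path = out_dir / "cohort_flow.json"
    flow_path.write_text(json.dumps(flow, indent=2, sort_keys=True) + "\n", "utf-8")
    _table1_df(summary).to_csv(out_dir / "table1.csv", index=False, lineterminator="\n")
    prevalence.to_csv(out_dir / "prevalence.csv", index=False, lineterminator="\n")
    pd.DataFrame(ppv_rows).to_csv(out_dir / "per_symptom_ppv.csv", index=False, lineterminator="\n")
    pd.DataFrame(confusion_rows).to_csv(out_dir / "tool_confusion.csv", index=False,
                                        lineterminator="\n")
    pd.DataFrame(stat_rows, columns=["tool", "statistic", "estimate", "ci_low", "ci_high",
                                     "method"]).to_csv(
        out_dir / "tool_stats.csv", index=False, lineterminator="\n")

    import panctriage

    provenance = {
        "config_sha256": config_digest,
        "seed": config.seed,
        "package_version": panctriage.__version__,
        "generated": "deterministic given seed; timestamp omitted on purpose",
        "stats_full_precision": stats_full,
        "summary": summary,
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n", "utf-8"
    )

    return {
        "output_dir": out_dir,
        "files": [out_dir / f for f in BUNDLE_FILES],
        "flow": flow,
        "summary": summary,
        "evaluations": evaluations,
        "stats": stats_full,
    }


def evaluations_to_df(evaluations: Sequence[ToolEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "tool": e.tool,
                "eligible": e.eligible,
                "entry_date": e.entry_date.isoformat() if e.entry_date else "",
                "flagged": e.flagged,
                "flag_date": e.flag_date.isoformat() if e.flag_date else "",
                "index_date": e.index_date.isoformat() if e.index_date else "",
                "outcome_cancer_12m": e.outcome_cancer_12m,
                "censoring_note": e.censoring_note,
            }
            for e in evaluations
        ],
        columns=["patient_id", "tool", "eligible", "entry_date", "flagged", "flag_date",
                 "index_date", "outcome_cancer_12m", "censoring_note"],
    )


def evaluations_from_df(df: pd.DataFrame) -> list[ToolEvaluation]:
    def _date(v):
        v = str(v)
        return _dt.date.fromisoformat(v) if v else None

    def _bool(v):
        return str(v).strip().lower() in ("true", "1")

    return [
        ToolEvaluation(
            patient_id=str(r.patient_id),
            tool=str(r.tool),
            eligible=_bool(r.eligible),
            entry_date=_date(r.entry_date),
            flagged=_bool(r.flagged),
            flag_date=_date(r.flag_date),
            index_date=_date(r.index_date),
            outcome_cancer_12m=_bool(r.outcome_cancer_12m),
            censoring_note=str(r.censoring_note),
        )
        for r in df.itertuples(index=False)
    ]
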