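"""Synthetic linked primary-care + cancer-registry data generator.

Emits five referentially consistent tables — patients, encounters (with
free-text reason-for-encounter), pathology, prescriptions, registry — whose
marginal structure matches what the analysis assumes: per-symptom lifetime
presence probabilities conditional on future cancer status, symptomatic
presentations concentrated in the year before a cancer diagnosis, jaundice
expressible as text and/or raised bilirubin, diabetes expressible via
single elevated HbA1c, paired raised HbA1c results, or a diabetes
prescription, and HbA1c reported in a 50/50 mixture of percent and
mmol/mol units.

Only marginal proportions are modelled: symptom presence is independent
per symptom given cancer status (the sources report no joint
distribution).  Output is deterministic given the seed, down to the
emitted CSV bytes.
"""

from __future__ import annotations

import datetime as _dt
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from panctriage.symptoms import CANONICAL_SYMPTOMS

# lifetime P(>=1 presentation | cancer), P(>=1 presentation | no cancer)
_DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    "jaundice": (0.203, 0.025),
    "new_onset_diabetes": (0.293, 0.206),
    "pancreatitis": (0.033, 0.007),
    "uwl": (0.077, 0.036),
    "back_pain": (0.255, 0.366),
    "fatigue": (0.096, 0.150),
    "indigestion": (0.243, 0.285),
    "abdominal_pain": (0.300, 0.250),
    "cibh": (0.180, 0.120),
    "appetite_loss": (0.060, 0.030),
    "steatorrhoea": (0.020, 0.004),
    "constipation": (0.120, 0.110),
    "diarrhoea": (0.110, 0.100),
    "nausea": (0.100, 0.090),
    "vomiting": (0.080, 0.070),
    "dysphagia": (0.030, 0.025),
    "abdominal_distension": (0.050, 0.030),
    "ep_radiating": (0.015, 0.003),
    "pruritus": (0.050, 0.045),
    "gi_bleed": (0.040, 0.030),
    "vte": (0.030, 0.015),
    "depression_anxiety": (0.150, 0.160),
    "dark_urine_pale_stools": (0.040, 0.006),
}

# given a cancer patient has the symptom at all, probability the (first)
# presentation falls in the 12 months pre-diagnosis
_DEFAULT_PREDX_PLACEMENT: dict[str, float] = {
    "jaundice": 0.90,
    "abdominal_pain": 0.60,
    "cibh": 0.60,
    "new_onset_diabetes": 0.45,
}

_DEFAULT_VARIANTS: dict[str, list[str]] = {
    "jaundice": ["jaundice", "appears jaundiced", "yellow sclera ?jaundice", "icterus noted"],
    "abdominal_pain": ["abdo pain", "abdominal pain 2/52", "stomach ache", "epigastric pain"],
    "ep_radiating": ["epigastric pain radiating to back", "ep radiating", "epigastric pain radiating into the back"],
    "back_pain": ["back pain", "lower back pain", "backache worsening"],
    "abdominal_distension": ["abdominal distension", "bloating", "distended abdomen"],
    "cibh": ["change in bowel habit", "altered bowel habit", "CIBH 3/12"],
    "constipation": ["constipation", "constipated 1/52", "hard stools"],
    "diarrhoea": ["diarrhoea", "loose stools", "watery stool x3 days"],
    "steatorrhoea": ["steatorrhoea", "fatty stools", "pale greasy stool"],
    "nausea": ["nausea", "feeling sick", "nauseous since monday"],
    "vomiting": ["vomiting", "vomited overnight", "emesis"],
    "indigestion": ["indigestion", "dyspepsia", "heartburn after meals"],
    "dysphagia": ["dysphagia", "difficulty swallowing", "food sticking"],
    "appetite_loss": ["loss of appetite", "poor appetite", "anorexia - reduced intake"],
    "uwl": ["weight loss", "unintentional wt loss 5kg", "losing weight without trying"],
    "fatigue": ["fatigue", "tiredness all the time", "lethargy"],
    "pruritus": ["pruritus", "generalised itch", "itchy skin no rash"],
    "pancreatitis": ["pancreatitis", "acute pancreatitis follow up", "inflamed pancreas"],
    "gi_bleed": ["GI bleed", "melaena", "rectal bleeding"],
    "vte": ["DVT", "venous thromboembolism", "pulmonary embolism review"],
    "depression_anxiety": ["depression", "anxiety worsening", "low mood"],
    "dark_urine_pale_stools": ["dark urine", "pale stools", "dark urine and pale stools"],
}

#: Filler / decoy reason strings.  None may match the default lexicon.
_NOISE_TEXTS = [
    "routine script renewal",
    "blood pressure check",
    "immunisation",
    "medical certificate",
    "family history pancreatic cancer",
    "family history of diabetes",
    "diabetes annual review",
    "weight loss program referral",
    "URTI",
    "skin check",
    "repeat prescription",
    "care plan review",
]

_DIABETES_MEDS = [
    "metformin 500mg", "Diabex XR 500", "gliclazide 60mg MR", "Diamicron MR",
    "sitagliptin 100mg", "Januvia", "empagliflozin 10mg", "Jardiance",
    "semaglutide 1mg", "Ozempic 1mg",
]
_DECOY_MEDS = ["atorvastatin 20mg", "perindopril 5mg", "esomeprazole 20mg", "cefalexin 500mg"]

_DECOY_ICD10 = ["C50.9", "C61", "C18.7", "D12.6", "K85.9"]


class SimConfig(BaseModel):
    """Parameters of the synthetic linked-EMR generator."""

    n_patients: int = Field(default=20000, gt=0)
    cancer_prevalence: float = Field(default=0.05, ge=0.0, le=1.0)
    study_start: _dt.date = _dt.date(2007, 7, 1)
    study_end: _dt.date = _dt.date(2021, 6, 30)
    # age at first encounter ~ Normal(median, iqr/1.349), clipped
    age_distribution: dict = Field(
        default_factory=lambda: {
            "cancer": {"median": 74.0, "iqr": [65.0, 82.0]},
            "non_cancer": {"median": 60.0, "iqr": [50.0, 72.0]},
            "clip": [40.0, 95.0],
        }
    )
    symptom_prevalence: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    prediagnosis_symptom_prob: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_PREDX_PLACEMENT)
    )
    default_prediagnosis_prob: float = 0.35
    # symptomatic encounters per patient ~ 1 + NegBinom(n, p): median 4, IQR 2-9
    consult_rate: dict = Field(default_factory=lambda: {"n": 1.1, "mean": 5.5})
    lexical_variants: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_VARIANTS.items()}
    )
    # mixture over expression routes
    jaundice_route_mix: dict = Field(
        default_factory=lambda: {"text": 0.5, "pathology": 0.25, "both": 0.25}
    )
    diabetes_route_mix: dict = Field(
        default_factory=lambda: {"hba1c_single": 0.4, "hba1c_pair": 0.3, "medication": 0.3}
    )
    lab_params: dict = Field(
        default_factory=lambda: {
            "bilirubin_high": {"mean": 45.0, "sd": 12.0, "min": 22.0},
            "bilirubin_normal": {"mean": 10.0, "sd": 4.0, "min": 1.0, "max": 20.0},
            "hba1c_high": {"mean": 7.6, "sd": 0.7, "min": 6.6},
            "hba1c_normal": {"mean": 5.4, "sd": 0.4, "min": 4.0, "max": 6.0},
            "background_rate": 0.25,
        }
    )
    hba1c_mmolmol_fraction: float = 0.5
    missing_bmi_seifa_rate: float = 0.3
    unknown_sex_rate: float = 0.003
    decoy_registry_rate: float = 0.01
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        for name, probs in self.symptom_prevalence.items():
            if name not in CANONICAL_SYMPTOMS:
                raise ValueError(f"symptom_prevalence: unknown symptom {name!r}")
            if not all(0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"symptom_prevalence[{name!r}] outside [0,1]")
            if name != "new_onset_diabetes" and not self.lexical_variants.get(name):
                raise ValueError(f"lexical_variants[{name!r}] must be non-empty")
        for name, p in self.prediagnosis_symptom_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prediagnosis_symptom_prob[{name!r}] outside [0,1]")
        for field_name in ("cancer_prevalence", "hba1c_mmolmol_fraction",
                           "missing_bmi_seifa_rate", "unknown_sex_rate", "decoy_registry_rate"):
            v = getattr(self, field_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{field_name} outside [0,1]")
        return self


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float,
                    lo: Optional[float] = None, hi: Optional[float] = None) -> float:
    x = rng.normal(mean, sd)
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return x


def _rand_date(rng: np.random.Generator, start: _dt.date, end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, max(span, 0) + 1)))


def generate_cohort_data(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Generate the five linked tables.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    start, end = config.study_start, config.study_end
    span_days = (end - start).days

    nb_n = float(config.consult_rate["n"])
    nb_mean = float(config.consult_rate["mean"])
    nb_p = nb_n / (nb_n + nb_mean)

    patients_rows: list[dict] = []
    encounter_rows: list[dict] = []
    pathology_rows: list[dict] = []
    prescription_rows: list[dict] = []
    registry_rows: list[dict] = []

    lab = config.lab_params
    age_cfg = config.age_distribution
    clip_lo, clip_hi = age_cfg.get("clip", [40.0, 95.0])

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        cancer = bool(rng.random() < config.cancer_prevalence)

        u = rng.random()
        if u < config.unknown_sex_rate:
            sex = "unknown"
        else:
            sex = "male" if rng.random() < 0.5 else "female"

        stratum = age_cfg["cancer"] if cancer else age_cfg["non_cancer"]
        iqr_lo, iqr_hi = stratum["iqr"]
        age = _clipped_normal(rng, float(stratum["median"]),
                              (iqr_hi - iqr_lo) / 1.349, clip_lo, clip_hi)

        # active period; cancer patients get a diagnosis with >365 d of lead room
        t0 = start + _dt.timedelta(days=int(rng.integers(0, max(span_days - 730, 1))))
        dx_date: Optional[_dt.date] = None
        if cancer:
            room = (end - t0).days
            dx_offset = int(rng.integers(380, max(room, 381) + 1))
            dx_date = t0 + _dt.timedelta(days=dx_offset)
            t1 = dx_date
        else:
            t1 = t0 + _dt.timedelta(days=int(rng.integers(365, max((end - t0).days, 366) + 1)))
            t1 = min(t1, end)

        birth = t0 - _dt.timedelta(days=int(age * 365.25) + int(rng.integers(0, 365)))

        bmi = None
        seifa = None
        if rng.random() >= config.missing_bmi_seifa_rate:
            bmi = round(_clipped_normal(rng, 27.0, 5.0, 16.0, 55.0), 1)
        if rng.random() >= config.missing_bmi_seifa_rate:
            seifa = int(rng.integers(1, 101))

        patients_rows.append(
            {"patient_id": pid, "sex": sex, "birth_date": birth.isoformat(),
             "bmi": bmi, "seifa_percentile": seifa}
        )

        # --- symptom presence and event dates -------------------------------
        symptomatic_dates: list[_dt.date] = []
        for code in CANONICAL_SYMPTOMS:
            p_cancer, p_nocancer = config.symptom_prevalence.get(code, (0.0, 0.0))
            p = p_cancer if cancer else p_nocancer
            if rng.random() >= p:
                continue
            if cancer:
                q = config.prediagnosis_symptom_prob.get(code, config.default_prediagnosis_prob)
                if rng.random() < q:
                    date = dx_date - _dt.timedelta(days=int(rng.integers(0, 366)))
                else:
                    date = _rand_date(rng, t0, dx_date - _dt.timedelta(days=366))
            else:
                date = _rand_date(rng, t0, t1)
            symptomatic_dates.append(date)

            if code == "jaundice":
                route = _pick(rng, config.jaundice_route_mix)
                if route in ("text", "both"):
                    encounter_rows.append(_encounter(rng, pid, date, code, config))
                if route in ("pathology", "both"):
                    hp = lab["bilirubin_high"]
                    pathology_rows.append(
                        {"patient_id": pid, "result_date": date.isoformat(),
                         "analyte": "bilirubin_total",
                         "value": round(_clipped_normal(rng, hp["mean"], hp["sd"], hp["min"]), 1),
                         "units": "µmol/L"}
                    )
            elif code == "new_onset_diabetes":
                route = _pick(rng, config.diabetes_route_mix)
                if route == "medication":
                    prescription_rows.append(
                        {"patient_id": pid, "script_date": date.isoformat(),
                         "medication_name": _DIABETES_MEDS[int(rng.integers(0, len(_DIABETES_MEDS)))]}
                    )
                else:
                    n_results = 1 if route == "hba1c_single" else 2
                    hp = lab["hba1c_high"]
                    for k in range(n_results):
                        rdate = max(date - _dt.timedelta(days=120 * (n_results - 1 - k)), t0)
                        pct = round(_clipped_normal(rng, hp["mean"], hp["sd"], hp["min"]), 1)
                        pathology_rows.append(_hba1c_row(rng, pid, rdate, pct, config))
            else:
                encounter_rows.append(_encounter(rng, pid, date, code, config))

        # --- filler encounters and background labs/scripts ------------------
        n_total = 1 + int(rng.negative_binomial(nb_n, nb_p))
        n_filler = max(n_total - len(symptomatic_dates), 1)
        for _ in range(n_filler):
            date = _rand_date(rng, t0, t1)
            text = _NOISE_TEXTS[int(rng.integers(0, len(_NOISE_TEXTS)))]
            encounter_rows.append(
                {"patient_id": pid, "encounter_date": date.isoformat(), "reason_text": text}
            )
        if rng.random() < lab["background_rate"]:
            date = _rand_date(rng, t0, t1)
            np_ = lab["bilirubin_normal"]
            pathology_rows.append(
                {"patient_id": pid, "result_date": date.isoformat(),
                 "analyte": "bilirubin_total",
                 "value": round(_clipped_normal(rng, np_["mean"], np_["sd"], np_["min"], np_["max"]), 1),
                 "units": "µmol/L"}
            )
        if rng.random() < lab["background_rate"]:
            date = _rand_date(rng, t0, t1)
            np_ = lab["hba1c_normal"]
            pct = round(_clipped_normal(rng, np_["mean"], np_["sd"], np_["min"], np_["max"]), 1)
            pathology_rows.append(_hba1c_row(rng, pid, date, pct, config))
        if rng.random() < 0.3:
            date = _rand_date(rng, t0, t1)
            prescription_rows.append(
                {"patient_id": pid, "script_date": date.isoformat(),
                 "medication_name": _DECOY_MEDS[int(rng.integers(0, len(_DECOY_MEDS)))]}
            )

        # --- registry --------------------------------------------------------
        if cancer:
            registry_rows.append(
                {"patient_id": pid, "diagnosis_date": dx_date.isoformat(), "icd10_code": "C25.9"}
            )
        if rng.random() < config.decoy_registry_rate:
            date = _rand_date(rng, t0, t1)
            registry_rows.append(
                {"patient_id": pid, "diagnosis_date": date.isoformat(),
                 "icd10_code": _DECOY_ICD10[int(rng.integers(0, len(_DECOY_ICD10)))]}
            )

    tables = {
        "patients": pd.DataFrame(
            patients_rows, columns=["patient_id", "sex", "birth_date", "bmi", "seifa_percentile"]
        ),
        "encounters": pd.DataFrame(
            encounter_rows, columns=["patient_id", "encounter_date", "reason_text"]
        ),
        "pathology": pd.DataFrame(
            pathology_rows, columns=["patient_id", "result_date", "analyte", "value", "units"]
        ),
        "prescriptions": pd.DataFrame(
            prescription_rows, columns=["patient_id", "script_date", "medication_name"]
        ),
        "registry": pd.DataFrame(
            registry_rows, columns=["patient_id", "diagnosis_date", "icd10_code"]
        ),
    }
    for name in ("encounters", "pathology", "prescriptions", "registry"):
        tables[name] = tables[name].sort_values(
            list(tables[name].columns), kind="mergesort"
        ).reset_index(drop=True)
    return tables


def _pick(rng: np.random.Generator, mix: dict) -> str:
    keys = list(mix)
    weights = np.array([float(mix[k]) for k in keys])
    weights = weights / weights.sum()
    u = rng.random()
    acc = 0.0
    for k, w in zip(keys, weights):
        acc += w
        if u < acc:
            return k
    return keys[-1]


def _encounter(rng: np.random.Generator, pid: str, date: _dt.date, code: str,
               config: SimConfig) -> dict:
    variants = config.lexical_variants[code]
    text = variants[int(rng.integers(0, len(variants)))]
    if rng.random() < 0.25:  # multi-reason field
        noise = _NOISE_TEXTS[int(rng.integers(0, len(_NOISE_TEXTS)))]
        text = text + "; " + noise
    return {"patient_id": pid, "encounter_date": date.isoformat(), "reason_text": text}


def _hba1c_row(rng: np.random.Generator, pid: str, date: _dt.date, pct: float,
               config: SimConfig) -> dict:
    if rng.random() < config.hba1c_mmolmol_fraction:
        value = round((pct - 2.152) / 0.09148, 0)
        units = "mmol/mol"
    else:
        value = pct
        units = "%"
    return {"patient_id": pid, "result_date": date.isoformat(),
            "analyte": "hba1c", "value": value, "units": units}
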