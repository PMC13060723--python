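import datetime as dt

import numpy as np
import pandas as pd
import pytest

from panctriage.cohort import (
    CohortConfig,
    apply_precovid_filter,
    build_timelines,
    evaluate_tool,
)
from panctriage.symptoms import CANONICAL_SYMPTOMS
from panctriage.tools import Clause, RuleSet, default_qcancer_model
from tests.conftest import encounters_df, make_timeline, pathology_df, prescriptions_df
from tests.oracles import brute_force_evaluate, random_timeline

JAUNDICE_RULE = RuleSet("t", [Clause(frozenset({"jaundice"}))])
PAIR_RULE = RuleSet("t", [Clause(frozenset({"abdominal_pain", "uwl"}))])


def _tables(patients, encounters=(), pathology=(), prescriptions=(), registry=()):
    return {
        "patients": pd.DataFrame(
            patients, columns=["patient_id", "sex", "birth_date", "bmi", "seifa_percentile"]
        ),
        "encounters": encounters_df(list(encounters)),
        "pathology": pathology_df(list(pathology)),
        "prescriptions": prescriptions_df(list(prescriptions)),
        "registry": pd.DataFrame(
            list(registry), columns=["patient_id", "diagnosis_date", "icd10_code"]
        ),
    }


class TestBuildTimelines:
    def test_prior_diagnosis_excluded(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [("P1", "female", "1950-01-01", None, None)],
            encounters=[("P1", "2015-05-01", "jaundice")],
            registry=[("P1", "2015-04-01", "C25.9")],
        )
        tls, flow = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert tls == []
        assert flow["patients_excluded_prior_diagnosis"] == 1

    def test_same_day_diagnosis_not_excluded(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [("P1", "female", "1950-01-01", None, None)],
            encounters=[("P1", "2015-05-01", "jaundice")],
            registry=[("P1", "2015-05-01", "C25.9")],
        )
        tls, _ = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert len(tls) == 1

    def test_no_relevant_symptoms_not_in_output(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [("P1", "female", "1950-01-01", None, None)],
            encounters=[("P1", "2015-05-01", "routine script renewal")],
        )
        tls, flow = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert tls == []
        assert flow["patients_no_relevant_symptoms"] == 1

    def test_age_39_excluded_and_101_excluded(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [
                ("P1", "female", "1976-01-01", None, None),  # 39 at presentation
                ("P2", "male", "1914-01-01", None, None),  # 101 at presentation
                ("P3", "male", "1955-01-01", None, None),  # 60: kept
            ],
            encounters=[
                ("P1", "2015-05-01", "jaundice"),
                ("P2", "2015-05-01", "jaundice"),
                ("P3", "2015-05-01", "jaundice"),
            ],
        )
        tls, flow = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert [t.patient_id for t in tls] == ["P3"]
        assert flow["patients_excluded_age"] == 2

    def test_missing_reason_encounters_dropped(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [("P1", "female", "1950-01-01", None, None)],
            encounters=[("P1", "2015-05-01", ""), ("P1", "2015-06-01", "jaundice")],
        )
        tls, flow = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert flow["encounters_dropped_missing"] == 1
        assert len(tls) == 1

    def test_orphan_rows_skipped_not_fatal(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [("P1", "female", "1950-01-01", None, None)],
            encounters=[
                ("P1", "2015-05-01", "jaundice"),
                ("GHOST", "2015-05-01", "jaundice"),
            ],
        )
        tls, flow = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert flow["encounter_orphans_skipped"] == 1
        assert [t.patient_id for t in tls] == ["P1"]

    def test_merges_three_sources(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [("P1", "female", "1950-01-01", None, None)],
            encounters=[("P1", "2015-05-01", "back pain")],
            pathology=[("P1", "2015-06-01", "bilirubin_total", 40.0, "µmol/L")],
            prescriptions=[("P1", "2015-07-01", "metformin 500mg")],
        )
        (tl,), _ = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert {e.symptom_code for e in tl.events} == {
            "back_pain",
            "jaundice",
            "new_onset_diabetes",
        }

    def test_flow_counts_weakly_decreasing(self, lexicon, feature_config, cohort_config):
        tables = _tables(
            [("P1", "female", "1950-01-01", None, None),
             ("P2", "male", "1980-06-01", None, None)],
            encounters=[("P1", "2015-05-01", "jaundice"), ("P2", "2015-05-01", "URTI")],
        )
        _, flow = build_timelines(tables, lexicon, feature_config, cohort_config)
        assert flow["cohort_size"] <= flow["patients_total"]
        assert flow["cohort_cancers"] <= flow["cohort_size"]


class TestEvaluateTool:
    def test_single_event_flags_at_entry(self, cohort_config):
        tl = make_timeline(events=[(dt.date(2015, 5, 1), "jaundice")])
        ev = evaluate_tool(tl, JAUNDICE_RULE, cohort_config)
        assert ev.flagged and ev.flag_date == ev.entry_date == ev.index_date

    def test_events_400_days_apart_never_flag(self, cohort_config):
        tl = make_timeline(
            events=[
                (dt.date(2015, 1, 1), "abdominal_pain"),
                (dt.date(2016, 2, 5), "uwl"),  # 400 days later
            ]
        )
        ev = evaluate_tool(tl, PAIR_RULE, cohort_config)
        assert not ev.flagged
        # outside the window: the only in-window qualifying event is entry
        assert ev.index_date == dt.date(2015, 1, 1)
        assert brute_force_evaluate(tl, PAIR_RULE, cohort_config)[1] is False

    def test_stops_at_diagnosis_before_flag(self, cohort_config):
        entry = dt.date(2015, 1, 1)
        tl = make_timeline(
            events=[(entry, "abdominal_pain"), (entry + dt.timedelta(days=20), "uwl")],
            diagnosis=entry + dt.timedelta(days=10),
        )
        ev = evaluate_tool(tl, PAIR_RULE, cohort_config)
        assert not ev.flagged
        assert ev.censoring_note == "stopped at diagnosis"
        assert brute_force_evaluate(tl, PAIR_RULE, cohort_config)[1] is False

    def test_same_day_combination_flags(self, cohort_config):
        d = dt.date(2015, 1, 1)
        tl = make_timeline(events=[(d, "abdominal_pain"), (d, "uwl")])
        ev = evaluate_tool(tl, PAIR_RULE, cohort_config)
        assert ev.flagged and ev.flag_date == d

    def test_outcome_window_inclusive_at_index(self, cohort_config):
        d = dt.date(2015, 1, 1)
        tl = make_timeline(events=[(d, "jaundice")], diagnosis=d)
        ev = evaluate_tool(tl, JAUNDICE_RULE, cohort_config)
        assert ev.outcome_cancer_12m is True

    def test_outcome_window_closes_at_365(self, cohort_config):
        d = dt.date(2015, 1, 1)
        tl_in = make_timeline(events=[(d, "jaundice")], diagnosis=d + dt.timedelta(days=365))
        tl_out = make_timeline(events=[(d, "jaundice")], diagnosis=d + dt.timedelta(days=366))
        assert evaluate_tool(tl_in, JAUNDICE_RULE, cohort_config).outcome_cancer_12m
        assert not evaluate_tool(tl_out, JAUNDICE_RULE, cohort_config).outcome_cancer_12m

    def test_no_qualifying_symptom_ineligible(self, cohort_config):
        tl = make_timeline(events=[(dt.date(2015, 1, 1), "back_pain")])
        ev = evaluate_tool(tl, JAUNDICE_RULE, cohort_config)
        assert not ev.eligible

    def test_riskmodel_age_restriction(self, cohort_config):
        model = default_qcancer_model()
        tl = make_timeline(
            birth=dt.date(1920, 1, 1),  # 95 at presentation: outside 25-89
            events=[(dt.date(2015, 1, 1), "uwl")],
        )
        ev = evaluate_tool(tl, model, cohort_config)
        assert not ev.eligible

    def test_riskmodel_unknown_sex_ineligible(self, cohort_config):
        model = default_qcancer_model()
        tl = make_timeline(sex="unknown", events=[(dt.date(2015, 1, 1), "uwl")])
        assert not evaluate_tool(tl, model, cohort_config).eligible

    def test_unknown_sex_eligible_for_rule_tools(self, cohort_config):
        tl = make_timeline(sex="unknown", events=[(dt.date(2015, 1, 1), "jaundice")])
        assert evaluate_tool(tl, JAUNDICE_RULE, cohort_config).eligible

    def test_no_events_after_stop_used(self, cohort_config):
        entry = dt.date(2015, 1, 1)
        tl = make_timeline(
            events=[(entry, "abdominal_pain"), (entry + dt.timedelta(days=100), "uwl")],
            diagnosis=entry + dt.timedelta(days=50),
        )
        ev = evaluate_tool(tl, PAIR_RULE, cohort_config)
        # uwl arrives after the diagnosis stop: index stays at entry
        assert ev.index_date == entry and not ev.flagged

    def test_translation_equivariance(self, cohort_config):
        entry = dt.date(2012, 3, 1)
        events = [(entry, "abdominal_pain"), (entry + dt.timedelta(days=90), "uwl")]
        dx = entry + dt.timedelta(days=200)
        base = make_timeline(events=events, diagnosis=dx, birth=dt.date(1950, 6, 15))
        k = 37
        shifted = make_timeline(
            events=[(d + dt.timedelta(days=k), c) for d, c in events],
            diagnosis=dx + dt.timedelta(days=k),
            birth=dt.date(1950, 6, 15) + dt.timedelta(days=k),
        )
        e0 = evaluate_tool(base, PAIR_RULE, cohort_config)
        e1 = evaluate_tool(shifted, PAIR_RULE, cohort_config)
        delta = dt.timedelta(days=k)
        assert e1.entry_date == e0.entry_date + delta
        assert e1.flag_date == e0.flag_date + delta
        assert e1.index_date == e0.index_date + delta
        assert e1.flagged == e0.flagged

    @pytest.mark.parametrize("tool_kind", ["rule", "risk"])
    def test_matches_brute_force_on_random_timelines(self, cohort_config, tool_kind):
        rng = np.random.default_rng(7)
        codes = ["jaundice", "abdominal_pain", "uwl", "back_pain", "cibh", "new_onset_diabetes"]
        tool = (
            RuleSet(
                "t",
                [
                    Clause(frozenset({"jaundice"})),
                    Clause(frozenset({"abdominal_pain", "uwl"}), min_age=60),
                    Clause(frozenset({"cibh", "new_onset_diabetes"})),
                ],
            )
            if tool_kind == "rule"
            else default_qcancer_model()
        )
        for _ in range(200):
            tl = random_timeline(rng, codes)
            expected = brute_force_evaluate(tl, tool, cohort_config)
            got = evaluate_tool(tl, tool, cohort_config)
            if not got.eligible:
                continue
            assert (got.entry_date, got.flagged, got.flag_date, got.index_date) == expected


class TestPrecovidFilter:
    def test_straddling_entries(self, cohort_config):
        early = make_timeline(patient_id="A", events=[(dt.date(2018, 1, 1), "jaundice")])
        late = make_timeline(patient_id="B", events=[(dt.date(2020, 6, 1), "jaundice")])
        out = apply_precovid_filter([early, late], cohort_config)
        assert [t.patient_id for t in out] == ["A"]

    def test_empty_input(self, cohort_config):
        assert apply_precovid_filter([], cohort_config) == []

    def test_all_pre2019_identity(self, cohort_config):
        tls = [make_timeline(patient_id=str(i), events=[(dt.date(2015, 1, i + 1), "jaundice")])
               for i in range(3)]
        assert apply_precovid_filter(tls, cohort_config) == tls

    def test_disabled_filter_is_identity(self):
        cfg = CohortConfig(precovid_end=None)
        late = make_timeline(events=[(dt.date(2020, 6, 1), "jaundice")])
        assert apply_precovid_filter([late], cfg) == [late]


class TestCohortConfigValidation:
    def test_bad_date_order_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(study_start=dt.date(2022, 1, 1), study_end=dt.date(2021, 1, 1))

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(accumulation_window_days=0)

    def test_defaults_mirror_study_window(self, cohort_config):
        assert cohort_config.study_start == dt.date(2007, 7, 1)
        assert cohort_config.study_end == dt.date(2021, 6, 30)
        assert cohort_config.age_min == 40 and cohort_config.age_max == 100
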