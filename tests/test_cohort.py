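import numpy as np
import pandas as pd
import pytest

from corticorl import cohort
from corticorl.synthetic_ehr import admissions_frame

from conftest import make_admissions, make_events


class TestSofaDaily:
    def test_isolated_thrombocytopenia(self):
        adm = make_admissions([("a", 50, 30)])
        ev = make_events([("a", "platelets", 2.0, 90.0, "lab")])
        days = cohort.compute_sofa_daily(ev, adm)
        assert days[0].subscores["coagulation"] == 2
        assert days[0].total == 2

    def test_hypotension_without_vasopressors(self):
        adm = make_admissions([("a", 50, 30)])
        ev = make_events([("a", "mean_arterial_pressure", 2.0, 65.0, "vital")])
        days = cohort.compute_sofa_daily(ev, adm)
        assert days[0].subscores["cardiovascular"] == 1
        assert days[0].total == 1

    def test_all_variables_absent_scores_zero(self):
        adm = make_admissions([("a", 50, 30)])
        days = cohort.compute_sofa_daily(make_events([]), adm)
        assert [d.total for d in days] == [0, 0]

    def test_worst_value_in_window_drives_score(self):
        adm = make_admissions([("a", 50, 30)])
        ev = make_events([("a", "platelets", 1.0, 200.0, "lab"),
                          ("a", "platelets", 5.0, 40.0, "lab")])
        days = cohort.compute_sofa_daily(ev, adm)
        assert days[0].subscores["coagulation"] == 3   # worst value, <50

    def test_vasopressor_dose_grid(self):
        adm = make_admissions([("a", 50, 30)])
        ev = make_events([("a", "norepinephrine", 2.0, 0.05, "drug_rate")])
        low = cohort.compute_sofa_daily(ev, adm)[0]
        ev2 = make_events([("a", "norepinephrine", 2.0, 0.3, "drug_rate")])
        high = cohort.compute_sofa_daily(ev2, adm)[0]
        assert low.subscores["cardiovascular"] == 3
        assert high.subscores["cardiovascular"] == 4

    def test_totals_equal_sum_of_subscores(self, cohort_data):
        admissions, events, _ = cohort_data
        adf = admissions_frame(admissions)
        days = cohort.compute_sofa_daily(events.head(5000), adf.head(20))
        for d in days:
            assert d.total == sum(d.subscores.values())
            assert all(0 <= v <= 4 for v in d.subscores.values())


class TestSuspectedInfection:
    def test_culture_then_antibiotic_pair(self):
        ev = make_events([("a", "blood_culture", 24.0, 1.0, "culture"),
                          ("a", "antibiotic", 48.0, 1000.0, "drug_bolus")])
        sus = cohort.detect_suspected_infection(ev)
        assert list(sus) == ["a"]
        assert sus["a"][0] == pd.Timestamp("2020-01-01") + pd.Timedelta(hours=24)

    def test_antibiotic_without_culture_is_no_suspicion(self):
        ev = make_events([("a", "antibiotic", 5.0, 1000.0, "drug_bolus")])
        assert cohort.detect_suspected_infection(ev) == {}

    def test_antibiotic_outside_window(self):
        ev = make_events([("a", "blood_culture", 0.0, 1.0, "culture"),
                          ("a", "antibiotic", 240.0, 1000.0, "drug_bolus")])
        assert cohort.detect_suspected_infection(ev) == {}

    def test_suspicion_time_is_earlier_of_pair(self):
        ev = make_events([("a", "antibiotic", 10.0, 1000.0, "drug_bolus"),
                          ("a", "blood_culture", 20.0, 1.0, "culture")])
        sus = cohort.detect_suspected_infection(ev)
        assert sus["a"][0] == pd.Timestamp("2020-01-01") + pd.Timedelta(hours=10)


def _sofa(adm_id, totals):
    return [cohort.SofaDaily(adm_id, i, {"respiration": t, "coagulation": 0,
                                         "liver": 0, "cardiovascular": 0,
                                         "cns": 0, "renal": 0}, t)
            for i, t in enumerate(totals)]


class TestIdentifySepsis:
    def test_minor_excluded_despite_high_sofa(self):
        adm = make_admissions([("a", 17, 72)])
        eps = cohort.identify_sepsis(_sofa("a", [4, 4, 4]),
                                     {"a": [pd.Timestamp("2020-01-01")]}, adm)
        assert not eps[0].included
        assert eps[0].exclusion_reason == "age_lt_18"

    def test_short_stay_excluded(self):
        adm = make_admissions([("a", 60, 20)])
        eps = cohort.identify_sepsis(_sofa("a", [4]),
                                     {"a": [pd.Timestamp("2020-01-01")]}, adm)
        assert eps[0].exclusion_reason == "los_lt_24h"

    def test_sofa_rise_sets_onset_day(self):
        adm = make_admissions([("a", 60, 80)])
        eps = cohort.identify_sepsis(_sofa("a", [1, 1, 3]),
                                     {"a": [pd.Timestamp("2020-01-01")]}, adm)
        assert eps[0].included and eps[0].onset_day == 2

    def test_admission_day_sofa_two_is_onset_zero(self):
        adm = make_admissions([("a", 60, 80)])
        eps = cohort.identify_sepsis(_sofa("a", [2, 1, 1]),
                                     {"a": [pd.Timestamp("2020-01-01")]}, adm)
        assert eps[0].included and eps[0].onset_day == 0

    def test_no_suspicion_excluded(self):
        adm = make_admissions([("a", 60, 80)])
        eps = cohort.identify_sepsis(_sofa("a", [4, 4, 4]), {}, adm)
        assert eps[0].exclusion_reason == "no_sepsis"

    def test_rise_measured_from_running_minimum(self):
        # 3 -> 1 -> 2: never rises 2 above the running minimum after day 0
        adm = make_admissions([("a", 60, 80)])
        eps = cohort.identify_sepsis(_sofa("a", [1, 0, 1]),
                                     {"a": [pd.Timestamp("2020-01-01")]}, adm)
        assert not eps[0].included
        eps2 = cohort.identify_sepsis(_sofa("a", [1, 0, 2]),
                                      {"a": [pd.Timestamp("2020-01-01")]}, adm)
        assert eps2[0].included and eps2[0].onset_day == 2

    def test_unknown_admission_in_sofa_raises(self):
        adm = make_admissions([("a", 60, 80)])
        with pytest.raises(ValueError):
            cohort.identify_sepsis(_sofa("zz", [3]), {}, adm)

    def test_self_consistency_against_generator_ground_truth(self, cohort_data):
        admissions, events, gt = cohort_data
        adf = admissions_frame(admissions)
        sofa = cohort.compute_sofa_daily(events, adf)
        sus = cohort.detect_suspected_infection(events)
        eps = cohort.identify_sepsis(sofa, sus, adf)
        truth = gt.groupby("admission_id")["eligible_sepsis"].first()
        pred = {e.admission_id: e.included for e in eps}
        tp = sum(truth[a] and pred[a] for a in truth.index)
        fn = sum(truth[a] and not pred[a] for a in truth.index)
        tn = sum((not truth[a]) and (not pred[a]) for a in truth.index)
        fp = sum((not truth[a]) and pred[a] for a in truth.index)
        assert tp / (tp + fn) >= 0.95, "sensitivity below 0.95"
        assert tn / (tn + fp) >= 0.95, "specificity below 0.95"


class TestSepticShock:
    def _episode(self):
        return cohort.SepsisEpisode("a", 0, True, "none")

    def test_requires_both_vasopressor_and_lactate(self):
        ev = make_events([("a", "norepinephrine", 2.0, 0.1, "drug_rate"),
                          ("a", "lactate", 3.0, 1.8, "lab")])
        assert cohort.flag_septic_shock(self._episode(), ev) is False

    def test_vasopressor_and_high_lactate(self):
        ev = make_events([("a", "norepinephrine", 2.0, 0.1, "drug_rate"),
                          ("a", "lactate", 3.0, 2.5, "lab")])
        assert cohort.flag_septic_shock(self._episode(), ev) is True

    def test_lactate_alone_insufficient(self):
        ev = make_events([("a", "lactate", 3.0, 5.0, "lab")])
        assert cohort.flag_septic_shock(self._episode(), ev) is False

    def test_adding_vasopressor_event_is_monotone(self):
        base = [("a", "lactate", 3.0, 2.5, "lab"),
                ("a", "norepinephrine", 2.0, 0.1, "drug_rate")]
        assert cohort.flag_septic_shock(self._episode(), make_events(base))
        extended = base + [("a", "dopamine", 5.0, 3.0, "drug_rate")]
        assert cohort.flag_septic_shock(self._episode(), make_events(extended))
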