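import numpy as np
import pandas as pd
import pytest

from corticorl import features
from corticorl.cohort import SepsisEpisode

from conftest import make_admissions, make_events


def episode(adm_id, onset=0, last=1):
    return SepsisEpisode(adm_id, onset, True, "none", last_day=last)


class TestBinAndAggregate:
    def test_measurement_aggregates(self):
        adm = make_admissions([("a", 60, 48)])
        ev = make_events([("a", "heart_rate", 2.0, 60.0, "vital"),
                          ("a", "heart_rate", 5.0, 80.0, "vital")])
        raw = features.bin_and_aggregate(ev, [episode("a")], adm)
        row = raw.loc[("a", 0)]
        assert row["heart_rate__mean"] == 70
        assert row["heart_rate__max"] == 80
        assert row["heart_rate__min"] == 60
        assert row["heart_rate__sd"] == 10          # population convention

    def test_single_observation_sd_is_zero(self):
        adm = make_admissions([("a", 60, 48)])
        ev = make_events([("a", "heart_rate", 2.0, 72.0, "vital")])
        raw = features.bin_and_aggregate(ev, [episode("a")], adm)
        assert raw.loc[("a", 0), "heart_rate__sd"] == 0

    def test_drug_doses_sum(self):
        adm = make_admissions([("a", 60, 48)])
        ev = make_events([("a", "antibiotic", 2.0, 50.0, "drug_bolus"),
                          ("a", "antibiotic", 8.0, 50.0, "drug_bolus")])
        raw = features.bin_and_aggregate(ev, [episode("a")], adm)
        assert raw.loc[("a", 0), "antibiotic__sum"] == 100

    def test_unobserved_day_is_missing(self):
        adm = make_admissions([("a", 60, 48)])
        ev = make_events([("a", "lactate", 30.0, 2.0, "lab")])  # day 1 only
        raw = features.bin_and_aggregate(ev, [episode("a")], adm)
        assert np.isnan(raw.loc[("a", 0), "lactate__mean"])
        assert raw.loc[("a", 1), "lactate__mean"] == 2.0

    def test_days_since_onset_indexing(self):
        adm = make_admissions([("a", 60, 72)])
        ev = make_events([("a", "lactate", 50.0, 3.0, "lab")])  # absolute day 2
        raw = features.bin_and_aggregate(ev, [episode("a", onset=1, last=2)], adm)
        assert list(raw.index) == [("a", 0), ("a", 1)]
        assert raw.loc[("a", 1), "lactate__mean"] == 3.0


class TestCoverageFilter:
    def _raw(self, observed_days, total_days=100):
        idx = pd.MultiIndex.from_tuples([("a", d) for d in range(total_days)],
                                        names=["admission_id", "day_index"])
        cols = features.column_names(features.DEFAULT_REGISTRY)
        raw = pd.DataFrame(np.nan, index=idx, columns=cols)
        raw.loc[:, "heart_rate__mean"] = 1.0      # fully covered reference
        for d in range(observed_days):
            raw.loc[("a", d), "lactate__mean"] = 2.0
        return raw

    def test_one_percent_coverage_dropped(self):
        reduced, dropped = features.filter_coverage(self._raw(1), ["a"])
        assert "lactate" in dropped
        assert "lactate__mean" not in reduced.columns

    def test_three_percent_coverage_kept(self):
        reduced, dropped = features.filter_coverage(self._raw(3), ["a"])
        assert "lactate" not in dropped

    def test_threshold_zero_keeps_any_observed(self):
        reduced, dropped = features.filter_coverage(self._raw(1), ["a"],
                                                    threshold=0.0)
        assert "lactate" not in dropped

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 2.0])
    def test_invalid_threshold(self, bad):
        with pytest.raises(ValueError):
            features.filter_coverage(self._raw(1), ["a"], threshold=bad)


def _table(values, column="lactate__mean", ids=None):
    ids = ids or ["a"] * len(values)
    idx = pd.MultiIndex.from_tuples(
        [(i, d) for d, i in enumerate(ids)], names=["admission_id", "day_index"])
    return pd.DataFrame({column: values}, index=idx)


class TestImpute:
    def test_forward_fill_within_admission(self):
        out, _, _ = features.impute(_table([5.0, np.nan, np.nan, 7.0]))
        assert out["lactate__mean"].tolist() == [5.0, 5.0, 5.0, 7.0]

    def test_drug_missing_becomes_zero(self):
        out, _, _ = features.impute(_table([np.nan, 100.0, np.nan],
                                           column="antibiotic__sum"))
        assert out["antibiotic__sum"].tolist() == [0.0, 100.0, 0.0]

    def test_fully_observed_fraction_zero(self):
        out, _, frac = features.impute(_table([1.0, 2.0]))
        assert frac == 0.0

    def test_no_fill_across_admissions(self):
        t = _table([5.0, np.nan], ids=["a", "b"])
        out, _, _ = features.impute(t, train_ids=["a"])
        # admission b's leading gap takes the training median, not a's value
        assert out.loc[("b", 1), "lactate__mean"] == 5.0  # median of train obs
        t2 = _table([5.0, 9.0, np.nan], ids=["a", "a", "b"])
        out2, _, _ = features.impute(t2, train_ids=["a"])
        assert out2.loc[("b", 2), "lactate__mean"] == 7.0  # median, not ffill

    def test_idempotent(self):
        t = _table([np.nan, 3.0, np.nan, 8.0])
        once, _, _ = features.impute(t)
        twice, _, frac = features.impute(once)
        pd.testing.assert_frame_equal(once, twice)
        assert frac == 0.0


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        t = _table([2.0, 6.0, 4.0])
        out, bounds = features.normalize(t)
        assert out["lactate__mean"].tolist() == [-1.0, 1.0, 0.0]

    def test_out_of_range_clipped(self):
        t = _table([2.0, 6.0], ids=["a", "a"])
        _, bounds = features.normalize(t)
        test_rows = _table([10.0], ids=["b"])
        scaled = bounds.transform(test_rows)
        assert scaled["lactate__mean"].iloc[0] == 1.0

    def test_constant_variable_maps_to_zero(self):
        t = _table([3.0, 3.0])
        out, _ = features.normalize(t)
        assert (out["lactate__mean"] == 0.0).all()

    def test_round_trip_within_tolerance(self):
        rng = np.random.default_rng(0)
        t = _table(rng.uniform(-5, 20, size=50).tolist())
        out, bounds = features.normalize(t)
        back = bounds.inverse(out)
        assert np.allclose(back.to_numpy(), t.to_numpy(), atol=1e-9)

    def test_no_leakage_from_validation_rows(self):
        vals = [1.0, 5.0, 2.0, 9.0]
        t = _table(vals, ids=["a", "a", "b", "b"])
        _, bounds1 = features.normalize(t, train_ids=["a"])
        t_mut = t.copy()
        t_mut.loc[("b", 2), "lactate__mean"] = 1e6
        _, bounds2 = features.normalize(t_mut, train_ids=["a"])
        pd.testing.assert_series_equal(bounds1.low, bounds2.low)
        pd.testing.assert_series_equal(bounds1.high, bounds2.high)


class TestDailyStates:
    def test_states_within_unit_interval_and_consistent_names(self, cohort_data):
        from corticorl.cohort import (compute_sofa_daily,
                                      detect_suspected_infection,
                                      flag_all_septic_shock, identify_sepsis)
        from corticorl.synthetic_ehr import admissions_frame
        admissions, events, _ = cohort_data
        adf = admissions_frame(admissions)
        eps = identify_sepsis(compute_sofa_daily(events, adf),
                              detect_suspected_infection(events), adf)
        included = [e.admission_id for e in eps if e.included]
        pipe = features.FeaturePipeline()
        normalized, observed = pipe.fit_transform(events, eps, adf,
                                                  included[: len(included) // 2])
        assert ((normalized >= -1) & (normalized <= 1)).all().all()
        states = features.to_daily_states(normalized.head(20), observed.head(20))
        names = states[0].feature_names
        assert all(s.feature_names == names for s in states)
        # steroid compounds never appear in the state
        assert not any("cortisone" in n or "dexamethasone" in n for n in names)
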