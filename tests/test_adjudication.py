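import numpy as np
import pandas as pd
import pytest

import ifnstrat as I
from ifnstrat.adjudication import AdjudicationError
from conftest import make_baseline_row, make_visits


class TestIldProgression:
    @pytest.mark.parametrize("rows,expected", [
        # absolute drop of 11 points within 10 months
        ([{"t": 0, "fvc_pct": 100}, {"t": 10, "fvc_pct": 89}], 10.0),
        # 7-point drop with a 16.7% relative DLco decline over 6 months
        ([{"t": 0, "fvc_pct": 100, "dlco_pct": 60},
          {"t": 6, "fvc_pct": 93, "dlco_pct": 50}], 6.0),
        # 9-point drop but outside the 12-month window
        ([{"t": 0, "fvc_pct": 100}, {"t": 14, "fvc_pct": 91}], None),
        # minor drop without DLco decline does not qualify
        ([{"t": 0, "fvc_pct": 100, "dlco_pct": 60},
          {"t": 6, "fvc_pct": 93, "dlco_pct": 58}], None),
        # rolling window: qualifying pair need not involve baseline
        ([{"t": 0, "fvc_pct": 100}, {"t": 24, "fvc_pct": 99},
          {"t": 30, "fvc_pct": 88}], 30.0),
    ])
    def test_rule(self, rows, expected):
        assert I.detect_ild_progression(make_visits(rows)) == expected

    def test_unsorted_contract_error(self):
        v = make_visits([{"t": 10, "fvc_pct": 90}, {"t": 0, "fvc_pct": 100}])
        with pytest.raises(AdjudicationError):
            I.detect_ild_progression(v)


class TestSkinWorsening:
    @pytest.mark.parametrize("baseline,visit_mrss,expected", [
        (4, 9, 6.0),      # +5 units, +125%
        (20, 24, None),   # +4 < 5 units
        (20, 25, 6.0),    # +5 units and exactly +25%: inclusive thresholds
        (0, 5, 6.0),      # baseline zero: +5 units qualifies
        (0, 4, None),
    ])
    def test_rule(self, baseline, visit_mrss, expected):
        v = make_visits([{"t": 0, "mrss": baseline}, {"t": 6, "mrss": visit_mrss}])
        assert I.detect_skin_worsening(baseline, v) == expected

    def test_negative_mrss_rejected(self):
        v = make_visits([{"t": 6, "mrss": -1}])
        with pytest.raises(ValueError):
            I.detect_skin_worsening(2, v)


class TestFlagEvents:
    def test_prevalent_pah_is_not_new(self):
        b = make_baseline_row(pah=True)
        v = make_visits([{"t": 30, "new_pah_rhc": True}])
        assert I.detect_flag_events(b, v) == []

    def test_incident_pah_counts(self):
        b = make_baseline_row(pah=False)
        v = make_visits([{"t": 30, "new_pah_rhc": True}])
        assert I.detect_flag_events(b, v) == [("pah", 30.0)]

    def test_arrhythmia_maps_to_cardiac(self):
        v = make_visits([{"t": 18, "arrhythmia_treated": True}])
        assert I.detect_flag_events(make_baseline_row(), v) == [("cardiac", 18.0)]

    @pytest.mark.parametrize("flag", ["enteral_nutrition_3wk", "parenteral_feeding",
                                      "gi_obstruction_admission"])
    def test_gi_flags(self, flag):
        v = make_visits([{"t": 12, flag: True}])
        assert I.detect_flag_events(make_baseline_row(), v) == [("gi", 12.0)]


class TestFirstEvent:
    def test_earliest_event_wins(self):
        b = make_baseline_row(mrss=4)
        v = make_visits([{"t": 0, "mrss": 4}, {"t": 18, "new_pah_rhc": True, "mrss": 4},
                         {"t": 24, "mrss": 9}])
        out = I.adjudicate_first_event(b, v)
        assert (out["event"], out["ttcw_months"]) == ("pah", 18.0)

    def test_no_event_censors_at_last_visit(self):
        v = make_visits([{"t": t} for t in np.arange(0, 90, 6)])
        out = I.adjudicate_first_event(make_baseline_row(), v)
        assert out == {"subject_id": "S1", "event": "none", "ttcw_months": 84.0,
                       "censored": True}

    def test_severity_tie_break(self):
        # ILD rule and cardiac flag both fire at t=36 -> ILD by severity order
        b = make_baseline_row()
        v = make_visits([{"t": 30, "fvc_pct": 100},
                         {"t": 36, "fvc_pct": 88, "arrhythmia_treated": True}])
        out = I.adjudicate_first_event(b, v)
        assert out["event"] == "ild_progression" and out["ttcw_months"] == 36.0

    def test_nonssc_death_censors(self):
        v = make_visits([{"t": 0}, {"t": 40, "nonssc_death": True}])
        out = I.adjudicate_first_event(make_baseline_row(), v)
        assert out["censored"] and out["ttcw_months"] == 40.0

    def test_empty_stream_warns(self):
        with pytest.warns(UserWarning, match="empty visit stream"):
            out = I.adjudicate_first_event(make_baseline_row(), make_visits([]))
        assert out["censored"] and out["ttcw_months"] == 0.0

    def test_event_input_order_invariant(self, small_cohort):
        """Permuting visit rows never changes any adjudicated outcome."""
        b, v = small_cohort["baseline"], small_cohort["visits"]
        ref = I.adjudicate_cohort(b, v)
        shuffled = v.sample(frac=1.0, random_state=5).reset_index(drop=True)
        again = I.adjudicate_cohort(b, shuffled)
        pd.testing.assert_frame_equal(ref, again)

    def test_monotone_in_extra_visits(self):
        """Adding a later visit never changes an already-detected event."""
        b = make_baseline_row()
        v = make_visits([{"t": 0, "fvc_pct": 100}, {"t": 6, "fvc_pct": 85}])
        first = I.adjudicate_first_event(b, v)
        v2 = make_visits([{"t": 0, "fvc_pct": 100}, {"t": 6, "fvc_pct": 85},
                          {"t": 12, "new_pah_rhc": True}])
        assert I.adjudicate_first_event(b, v2) == first

    def test_outcome_bounded_by_horizon(self, small_outcomes):
        assert (small_outcomes["ttcw_months"] <= 120.0).all()


class TestFiveYearFilter:
    def test_quoted_filter(self):
        out = pd.DataFrame({
            "subject_id": list("abcd"),
            "event": ["pah", "none", "none", "none"],
            "ttcw_months": [30.0, 48.0, 70.0, 60.0],
            "censored": [False, True, True, True],
        })
        kept = I.filter_complete_5yr(out)
        assert set(kept["subject_id"]) == {"a", "c", "d"}  # 60-month boundary kept

    def test_counting_identity(self, small_outcomes):
        dropped = (small_outcomes["censored"] &
                   (small_outcomes["ttcw_months"] < 60)).sum()
        assert len(I.filter_complete_5yr(small_outcomes)) == len(small_outcomes) - dropped
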