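"""ICD grouping, lab flags, event filtering, exclusions, analytical assembly."""

import numpy as np
import pandas as pd
import pytest

from twinsift.fixtures import CohortBundle
from twinsift.preprocess import (
    AttritionReport, IcdCombination, apply_exclusions, build_analytical,
    compute_aeb_outcome, consolidate_singletons, filter_events, flag_lab,
    icd_to_letter,
)

T0 = pd.Timestamp("2020-01-01 08:00:00")


def _events(rows):
    return pd.DataFrame(rows, columns=["subject_id", "start", "end", "kcal"])


def _bundle(demo_rows, icd_rows=(), lab_rows=(), ev_rows=()):
    demo = pd.DataFrame(demo_rows, columns=["subject_id", "age", "gender",
                                            "marital", "race", "ethnicity",
                                            "language", "height_cm", "weight_kg"])
    icd = pd.DataFrame(list(icd_rows), columns=["subject_id", "icd_code"])
    labs = pd.DataFrame(list(lab_rows), columns=["subject_id", "lab_name",
                                                 "result", "units",
                                                 "range_low", "range_high"])
    return CohortBundle(demo, icd, labs, _events(list(ev_rows)))


def _demo_row(sid, h=170.0, w=80.0):
    return (sid, 40.0, "Female", "Married", "Caucasian",
            "Not Hispanic or Latino", "English", h, w)


class TestIcdToLetter:
    @pytest.mark.parametrize("code,expected", [
        ("I25.10", "I"), ("z99.9", "Z"), ("E11.9", "E"), ("  a00 ", "A"),
    ])
    def test_parent_letter(self, code, expected):
        assert icd_to_letter(code) == expected

    @pytest.mark.parametrize("code", ["W19", "U07.1", "V89", "Y92", "P07", "X58"])
    def test_excluded_letters_dropped(self, code):
        assert icd_to_letter(code) is None

    @pytest.mark.parametrize("code", ["", "  ", "9A1", "125.10"])
    def test_malformed_codes_rejected(self, code):
        with pytest.raises(ValueError):
            icd_to_letter(code)


class TestConsolidateSingletons:
    def test_singleton_folds_into_highest_jaccard_candidate(self):
        combos = [IcdCombination(frozenset("ABC"), 1),
                  IcdCombination(frozenset("AB"), 5),
                  IcdCombination(frozenset("C"), 3)]
        res = consolidate_singletons(combos)
        # Jaccard {A,B}=2/3 beats {C}=1/3
        assert res.mapping[frozenset("ABC")] == frozenset("AB")
        assert not res.flagged

    def test_no_singletons_identity(self):
        combos = [IcdCombination(frozenset("AB"), 5),
                  IcdCombination(frozenset("C"), 3)]
        res = consolidate_singletons(combos)
        assert all(res.mapping[c.letters] == c.letters for c in combos)

    def test_disjoint_singleton_self_mapped_and_flagged(self):
        combos = [IcdCombination(frozenset("Q"), 1),
                  IcdCombination(frozenset("AB"), 5)]
        res = consolidate_singletons(combos)
        assert res.mapping[frozenset("Q")] == frozenset("Q")
        assert frozenset("Q") in res.flagged

    def test_tie_broken_by_frequency_then_letters(self):
        combos = [IcdCombination(frozenset("AB"), 1),
                  IcdCombination(frozenset("A"), 2),
                  IcdCombination(frozenset("B"), 7)]
        res = consolidate_singletons(combos)
        # equal Jaccard 1/2; higher frequency wins
        assert res.mapping[frozenset("AB")] == frozenset("B")

    def test_empty_input(self):
        assert consolidate_singletons([]).mapping == {}

    def test_combination_validation(self):
        with pytest.raises(ValueError):
            IcdCombination(frozenset(), 1)
        with pytest.raises(ValueError):
            IcdCombination(frozenset("W"), 1)


class TestFlagLab:
    @pytest.mark.parametrize("result,low,high,expected", [
        (10.0, 10.0, 20.0, "N"),   # boundary inclusive
        (20.0, 10.0, 20.0, "N"),
        (5.0, 10.0, 20.0, "L"),
        (25.0, 10.0, 20.0, "H"),
    ])
    def test_flags(self, result, low, high, expected):
        assert flag_lab(result, low, high) == expected

    def test_missing_range_unevaluable(self):
        with pytest.raises(ValueError):
            flag_lab(5.0, np.nan, 20.0)


class TestFilterEvents:
    def test_three_and_a_half_hour_event_removed(self):
        ev = _events([("s", T0, T0 + pd.Timedelta(hours=3.5), 100.0)])
        assert len(filter_events(ev)) == 0

    def test_exactly_three_hours_kept(self):
        ev = _events([("s", T0, T0 + pd.Timedelta(hours=3), 100.0)])
        assert len(filter_events(ev)) == 1

    def test_empty_stream(self):
        assert len(filter_events(_events([]))) == 0


class TestApplyExclusions:
    def test_rules_applied_in_order_with_counts(self):
        demo = [_demo_row("a"), _demo_row("b", h=np.nan), _demo_row("c"),
                _demo_row("d")]
        ev = [("a", T0, T0 + pd.Timedelta(hours=1), 50.0),
              ("b", T0, T0 + pd.Timedelta(hours=1), 50.0),
              ("c", T0, T0 + pd.Timedelta(hours=4), 400.0)]  # only long events
        bundle = _bundle(demo, ev_rows=ev)
        out, rep = apply_exclusions(bundle)
        assert rep == AttritionReport(4, 1, 1, 1, 1)
        assert set(out.demographics["subject_id"]) == {"a"}

    def test_no_exclusions_preserves_everyone(self):
        demo = [_demo_row("a"), _demo_row("b")]
        ev = [("a", T0, T0 + pd.Timedelta(hours=1), 50.0),
              ("b", T0, T0 + pd.Timedelta(hours=1), 60.0)]
        _, rep = apply_exclusions(_bundle(demo, ev_rows=ev))
        assert rep.n_final == rep.n_start == 2

    def test_report_reconciles(self, small_cohort):
        _, rep = apply_exclusions(small_cohort)
        assert rep.n_final == rep.n_start - (rep.n_excluded_no_wearable
                                             + rep.n_excluded_missing_anthro
                                             + rep.n_excluded_only_long_events)

    def test_inconsistent_report_rejected(self):
        with pytest.raises(ValueError):
            AttritionReport(10, 1, 1, 1, 8)


class TestComputeAebOutcome:
    def test_half_day_event(self):
        ev = _events([("s", T0, T0 + pd.Timedelta(seconds=43200), 500.0)])
        s, sec, avg = compute_aeb_outcome(ev)
        assert (s, sec, avg) == (500.0, 43200.0, 1000.0)

    def test_two_events_hand_arithmetic(self):
        ev = _events([("s", T0, T0 + pd.Timedelta(seconds=3600), 100.0),
                      ("s", T0 + pd.Timedelta(hours=2),
                       T0 + pd.Timedelta(hours=3), 100.0)])
        _, _, avg = compute_aeb_outcome(ev)
        assert avg == pytest.approx(2400.0)

    def test_zero_kcal(self):
        ev = _events([("s", T0, T0 + pd.Timedelta(hours=1), 0.0)])
        assert compute_aeb_outcome(ev)[2] == 0.0

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            compute_aeb_outcome(_events([]))


class TestBuildAnalytical:
    def _clean_bundle(self, demo, icd=(), ev=None):
        if ev is None:
            ev = [(r[0], T0, T0 + pd.Timedelta(hours=1), 100.0) for r in demo]
        return _bundle(demo, icd_rows=icd, ev_rows=ev)

    def test_bmi_from_averaged_anthropometrics(self):
        tab = build_analytical(self._clean_bundle([_demo_row("a", h=200.0, w=100.0)]))
        assert tab.loc[0, "bmi"] == pytest.approx(25.0)

    def test_repeated_heights_averaged(self):
        demo = [_demo_row("a", h=170.0), _demo_row("a", h=172.0)]
        tab = build_analytical(self._clean_bundle(demo))
        assert tab.loc[0, "height_cm"] == pytest.approx(171.0)

    def test_icd_codes_set_letter_flags(self):
        # two subjects share the combination so it is not a singleton
        demo = [_demo_row("a"), _demo_row("b")]
        icd = [("a", "I25.10"), ("a", "E11.9"), ("b", "I10"), ("b", "E66.9")]
        tab = build_analytical(self._clean_bundle(demo, icd=icd)).set_index("subject_id")
        assert tab.loc["a", "icd_I"] == 1
        assert tab.loc["a", "icd_E"] == 1
        assert tab.loc["a", "any_icd"] == 1
        flag_cols = [c for c in tab.columns if c.startswith("icd_")]
        assert tab.loc["a", flag_cols].sum() == 2

    def test_conflicting_categoricals_rejected(self):
        demo = [_demo_row("a"), _demo_row("a")]
        demo[1] = ("a", 40.0, "Male", "Married", "Caucasian",
                   "Not Hispanic or Latino", "English", 170.0, 80.0)
        with pytest.raises(ValueError, match="conflicting"):
            build_analytical(self._clean_bundle(demo))

    def test_any_icd_is_or_of_flags(self, analytical):
        flag_cols = [c for c in analytical.columns if c.startswith("icd_")]
        expected = (analytical[flag_cols].sum(axis=1) > 0).astype(int)
        assert (analytical["any_icd"] == expected).all()

    def test_avg_aeb_day_identity(self, analytical):
        recomputed = analytical["sum_aeb"] / (analytical["sum_seconds"] / 86400.0)
        assert np.allclose(analytical["avg_aeb_day"], recomputed, atol=1e-9)

    def test_bmi_identity(self, analytical):
        recomputed = analytical["weight_kg"] / (analytical["height_cm"] / 100.0) ** 2
        assert np.allclose(analytical["bmi"], recomputed, atol=1e-9)

    def test_idempotent_on_clean_bundle(self, clean_bundle):
        a = build_analytical(clean_bundle)
        b = build_analytical(clean_bundle)
        pd.testing.assert_frame_equal(a, b)
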