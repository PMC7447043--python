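"""Rule-engine unit and property tests: longitudinal ALT rules, ICD
matching, metabolic risk factors, classification and cohort accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nafldpheno import (
    DEFINITIONS,
    PhenotypeDefinition,
    alt_max,
    audit_c_misuse,
    classify,
    classify_cohort,
    cohort_accounting,
    has_exclusion,
    metabolic_flags,
    qualifying_alt_pair,
)
from nafldpheno.phenotyping import PhenotypeError, round_half_up

from conftest import make_codes, make_labs, make_meds

EMPTY_LABS = make_labs("p").iloc[0:0]


def brute_force_pair(alts, threshold, min_gap=183, window=730):
    """Independent oracle: enumerate every measurement pair."""
    hits = [(v, d) for v, d in alts if v > threshold]
    for i in range(len(hits)):
        for j in range(len(hits)):
            if i != j and min_gap <= abs(hits[j][1] - hits[i][1]) <= window:
                return True
    return False


class TestQualifyingAltPair:
    @pytest.mark.parametrize("alts,threshold,expected", [
        ([(45, -400), (45, -200)], 40, True),       # textbook male case
        ([], 40, False),                            # empty series
        ([(45, -900), (45, -100)], 40, False),      # gap 800 d too wide
        ([(41, -300), (39, -100)], 40, False),      # second value not elevated
        ([(45, -283), (45, -101)], 40, False),      # gap 182 d too short
        ([(45, -283), (45, -100)], 40, True),       # gap exactly 183 d
        ([(31, -400), (31, -200)], 30, True),       # female threshold
    ])
    def test_examples(self, alts, threshold, expected):
        assert qualifying_alt_pair(alts, threshold) is expected

    @given(st.lists(st.tuples(st.floats(1, 100), st.integers(-1000, 0)),
                    max_size=8),
           st.sampled_from([20.0, 30.0, 40.0]))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, alts, threshold):
        assert qualifying_alt_pair(alts, threshold) == \
            brute_force_pair(alts, threshold)


class TestAltMax:
    def test_max_within_window(self):
        assert alt_max([(20, -100), (35, -300), (28, -10)]) == 35

    def test_out_of_window_is_missing(self):
        assert alt_max([(50, -800)]) is None

    def test_empty_is_missing(self):
        assert alt_max([]) is None


class TestExclusion:
    def test_alcohol_cirrhosis_prefix(self):
        flag, reason = has_exclusion(["571.2"])
        assert flag and reason == "alcohol_related"

    def test_empty_codes(self):
        assert has_exclusion([]) == (False, None)

    def test_hypertension_is_not_an_exclusion(self):
        assert has_exclusion(["I10"])[0] is False

    def test_viral_hepatitis(self):
        flag, reason = has_exclusion(["B18.2"])
        assert flag and reason == "viral_hepatitis"


class TestMetabolicFlags:
    def flags(self, labs=None, codes=None, meds=None, sex="male", age=55.0):
        labs = EMPTY_LABS if labs is None else labs
        codes = make_codes("p").iloc[0:0] if codes is None else codes
        meds = make_meds("p").iloc[0:0] if meds is None else meds
        return metabolic_flags(labs, codes, meds, sex, age)

    def test_morning_triglycerides_dyslipidemia(self):
        prof = self.flags(make_labs("p", tg=(160, -5, "08:30")))
        assert prof.dyslipidemia

    def test_late_draw_triglycerides_not_dyslipidemia(self):
        prof = self.flags(make_labs("p", tg=(160, -5, "10:00")))
        assert not prof.dyslipidemia

    def test_missing_draw_time_is_conservative(self):
        prof = self.flags(make_labs("p", tg=(160, -5)))
        assert not prof.dyslipidemia

    def test_low_hdl_needs_two_codes(self):
        labs = make_labs("p", hdl=35)
        one = make_codes("p", ("ICD9", "272.0"))
        two = make_codes("p", ("ICD9", "272.0"), ("ICD10", "E78.5", -60))
        assert not self.flags(labs, one).dyslipidemia
        assert self.flags(labs, two).dyslipidemia

    def test_hdl_threshold_is_sex_specific(self):
        labs = make_labs("p", hdl=45)
        codes = make_codes("p", ("ICD9", "272.0"), ("ICD10", "E78.5", -60))
        assert not metabolic_flags(labs, codes, make_meds("p").iloc[0:0],
                                   "male", 55).dyslipidemia
        assert metabolic_flags(labs, codes, make_meds("p").iloc[0:0],
                               "female", 55).dyslipidemia

    def test_fibrate_prescription_dyslipidemia(self):
        prof = self.flags(meds=make_meds("p", ("fibrate", -90)))
        assert prof.dyslipidemia

    def test_statin_only_not_dyslipidemia(self):
        prof = self.flags(meds=make_meds("p", ("statin", -90)))
        assert not prof.dyslipidemia

    def test_prediabetes_hba1c_band(self):
        prof = self.flags(make_labs("p", hba1c=6.0))
        assert prof.prediabetes and not prof.t2d

    def test_t2d_hba1c(self):
        prof = self.flags(make_labs("p", hba1c=6.7))
        assert prof.t2d and not prof.prediabetes

    def test_two_diabetes_prescription_days_t2d(self):
        prof = self.flags(meds=make_meds("p", ("diabetes_oral", -30),
                                         ("diabetes_oral", -200)))
        assert prof.t2d

    def test_same_day_prescriptions_insufficient(self):
        prof = self.flags(meds=make_meds("p", ("diabetes_oral", -30),
                                         ("diabetes_oral", -30)))
        assert not prof.t2d

    def test_t1d_pattern_blocks_code_route(self):
        codes = make_codes("p", ("ICD10", "E11.9"))
        insulin_only = make_meds("p", ("insulin", -30))
        prof = self.flags(codes=codes, meds=insulin_only)
        assert not prof.t2d

    def test_code_route_with_oral_agent(self):
        codes = make_codes("p", ("ICD10", "E11.9"))
        meds = make_meds("p", ("insulin", -30), ("diabetes_oral", -30))
        # BMI above the type-1 cutoff so the pattern does not fire
        prof = self.flags(make_labs("p", bmi=28), codes, meds)
        assert prof.t2d

    def test_young_onset_blocks_code_route(self):
        codes = make_codes("p", ("ICD10", "E11.9", -3650))
        prof = metabolic_flags(make_labs("p", bmi=28), codes,
                               make_meds("p").iloc[0:0], "male",
                               age_at_enrollment=45.0)
        assert not prof.t2d  # onset age 35 < 40

    def test_obesity_and_htn(self):
        prof = self.flags(make_labs("p", bmi=31),
                          make_codes("p", ("ICD9", "401.9")))
        assert prof.obesity and prof.hypertension

    def test_hypertension_not_in_any_metabolic(self):
        prof = self.flags(codes=make_codes("p", ("ICD10", "I10")))
        assert prof.hypertension and not prof.any_metabolic

    def test_missing_analytes_never_error(self):
        prof = self.flags()
        assert not prof.any_metabolic


class TestAuditC:
    @pytest.mark.parametrize("score,sex,expected", [
        (4, "male", True), (3, "male", False), (3, "female", True),
        (2, "female", False), (0, "male", False), (12, "female", True),
    ])
    def test_standard_cutoffs(self, score, sex, expected):
        assert audit_c_misuse(score, sex) is expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            audit_c_misuse(13, "male")


class TestClassify:
    def test_male_qualifying_pair_is_case(self):
        call = classify({"id": "p", "sex": "male"},
                        make_labs("p", [(45, -400), (45, -200)]))
        assert call.stratum == "case"

    def test_male_low_alt_is_control(self):
        call = classify({"id": "p", "sex": "male"},
                        make_labs("p", [(23, -400), (20, -100)]))
        assert call.stratum == "control"

    def test_intermediate_band_is_indeterminate(self):
        call = classify({"id": "p", "sex": "male"},
                        make_labs("p", [(35, -400), (22, -100)]))
        assert call.stratum == "indeterminate"
        assert "intermediate ALT" in call.reasons

    def test_viral_hepatitis_code_excludes_case(self):
        call = classify({"id": "p", "sex": "female"},
                        make_labs("p", [(35, -400), (35, -200)]),
                        make_codes("p", ("ICD10", "B18.2")))
        assert call.stratum == "excluded"
        assert call.reasons

    def test_no_alt_is_indeterminate(self):
        call = classify({"id": "p", "sex": "male"}, EMPTY_LABS)
        assert call.stratum == "indeterminate"
        assert "no ALT" in call.reasons

    def test_missing_sex_raises(self):
        with pytest.raises(PhenotypeError):
            classify({"id": "p"}, EMPTY_LABS)

    def test_metabolic_definition_requires_factor(self):
        labs = make_labs("p", [(45, -400), (45, -200)])
        call = classify({"id": "p", "sex": "male"}, labs,
                        definition="alt_metabolic")
        assert call.stratum == "indeterminate"
        labs_with_bmi = make_labs("p", [(45, -400), (45, -200)], bmi=32)
        call = classify({"id": "p", "sex": "male"}, labs_with_bmi,
                        definition="alt_metabolic")
        assert call.stratum == "case"

    def test_alt_max_reported(self):
        call = classify({"id": "p", "sex": "male"},
                        make_labs("p", [(45, -400), (52, -200), (60, -800)]))
        assert call.alt_max == 52  # the −800 d value is outside the window


class TestCohortInvariants:
    def test_partition(self, small_cohort):
        calls = classify_cohort(small_cohort.participants, small_cohort.labs,
                                small_cohort.codes, small_cohort.meds)
        assert len(calls) == len(small_cohort.participants)
        assert set(calls["stratum"]) <= {"case", "control", "indeterminate",
                                         "excluded"}
        acc = cohort_accounting(calls)
        assert acc["eligible"] == (acc["cases"] + acc["controls"]
                                   + acc["indeterminate"] + acc["excluded"])

    def test_case_threshold_monotonicity(self, small_cohort):
        base = DEFINITIONS["alt_threshold"]
        raised = PhenotypeDefinition(
            "raised", {"male": 60.0, "female": 50.0}, base.control_ceiling)
        calls_base = classify_cohort(small_cohort.participants,
                                     small_cohort.labs, small_cohort.codes,
                                     small_cohort.meds, base, with_flags=False)
        calls_up = classify_cohort(small_cohort.participants,
                                   small_cohort.labs, small_cohort.codes,
                                   small_cohort.meds, raised, with_flags=False)
        assert (calls_up["stratum"] == "case").sum() <= \
            (calls_base["stratum"] == "case").sum()

    def test_phenotype_nesting(self, small_cohort):
        args = (small_cohort.participants, small_cohort.labs,
                small_cohort.codes, small_cohort.meds)
        cases = {name: set(calls.loc[calls["stratum"] == "case", "id"])
                 for name, calls in
                 ((n, classify_cohort(*args, n))
                  for n in ("alt_threshold", "alt_metabolic", "abalt"))}
        assert cases["alt_threshold"] <= cases["abalt"]
        assert cases["alt_metabolic"] <= cases["alt_threshold"]

    def test_round_trip_recovery(self, clean_cohort):
        calls = classify_cohort(clean_cohort.participants, clean_cohort.labs,
                                clean_cohort.codes, clean_cohort.meds)
        merged = calls.merge(clean_cohort.truth, on="id")
        predicted = merged["stratum"].map({"case": True, "control": False})
        assert (predicted == merged["case"]).all()


class TestAccounting:
    def test_empty_calls(self):
        empty = pd.DataFrame({"id": [], "stratum": []})
        acc = cohort_accounting(empty)
        assert acc["eligible"] == 0 and acc["analytic"] == 0

    def test_duplicate_ids_rejected(self):
        calls = pd.DataFrame({"id": ["a", "a"], "stratum": ["case", "case"]})
        with pytest.raises(ValueError):
            cohort_accounting(calls)

    @pytest.mark.parametrize("x,nd,expected", [
        (18.785, 0, 19.0), (31.43, 0, 31.0), (97.35, 1, 97.4), (0.5, 0, 1.0),
    ])
    def test_round_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected
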