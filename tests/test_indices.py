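import numpy as np
import pytest

from upcr import (
    ValidationError,
    classify_late_onset_fgr,
    composite_adverse_outcome,
    compute_cpr,
    compute_index_set,
    compute_upcr,
    estimate_fetal_weight,
    exclusion_filter,
    triplicate_mean,
)
from upcr.indices import OUTCOME_COMPONENTS

from conftest import make_exam, make_record


class TestTriplicateMean:
    @pytest.mark.parametrize("reps,expected", [((1.0, 1.1, 1.2), 1.1), ((0.8, 0.8, 0.8), 0.8)])
    def test_arithmetic_mean(self, reps, expected):
        assert triplicate_mean(reps) == pytest.approx(expected)

    @pytest.mark.parametrize("reps", [(1.0, 1.0), (1.0, 1.0, 1.0, 1.0), (1.0, -0.1, 1.0), (1.0, 0.0, 1.0)])
    def test_bad_replicates_rejected(self, reps):
        with pytest.raises(ValidationError):
            triplicate_mean(reps)


class TestRatios:
    def test_cpr_is_mca_over_ua(self):
        assert compute_cpr(1.4, 0.7) == pytest.approx(2.0)
        assert compute_cpr(0.9, 0.9) == pytest.approx(1.0)

    def test_upcr_combines_three_vessels(self):
        assert compute_upcr(1.2, 1.5, 1.7, 0.8) == pytest.approx(3.5)
        assert compute_upcr(1.0, 1.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_upcr_equals_inverse_cpr_plus_uterine_term(self):
        # 1/cpr + uta_mean/mca = 1/(0.8/1.2) + 1.6/0.8 = 1.5 + 2.0 = 3.5
        ua, uta_l, uta_r, mca = 1.2, 1.5, 1.7, 0.8
        upcr = compute_upcr(ua, uta_l, uta_r, mca)
        cpr = compute_cpr(mca, ua)
        uta = 0.5 * (uta_l + uta_r)
        assert upcr == pytest.approx(1.0 / cpr + uta / mca, rel=1e-12)
        assert upcr == pytest.approx(3.5)

    @pytest.mark.parametrize("fn,args", [
        (compute_cpr, (1.4, 0.0)),
        (compute_cpr, (-1.0, 0.7)),
        (compute_upcr, (0.0, 1.5, 1.7, 0.8)),
        (compute_upcr, (1.2, 1.5, 1.7, 0.0)),
    ])
    def test_non_positive_inputs_rejected(self, fn, args):
        with pytest.raises(ValidationError):
            fn(*args)


class TestIndexSet:
    def test_algebraic_identities_hold_on_generated_cohort(self, default_cohort):
        analyzed, _ = exclusion_filter(default_cohort.records)
        for rec in analyzed:
            idx = compute_index_set(rec.exam)
            assert idx.cpr * idx.ua_pi == pytest.approx(idx.mca_pi, rel=1e-9)
            assert idx.upcr * idx.mca_pi == pytest.approx(idx.ua_pi + idx.uta_mean_pi, rel=1e-9)
            assert idx.upcr == pytest.approx(1 / idx.cpr + idx.uta_mean_pi / idx.mca_pi, rel=1e-9)

    def test_mom_standardisation_modes_agree_when_curves_are_consistent(self):
        # the ratio medians are derived from the vessel medians at the knots,
        # so at a knot GA the two CPR standardisations coincide
        exam = make_exam(ga_weeks=34.0)
        a = compute_index_set(exam, ratio_mom="mom_of_ratio")
        b = compute_index_set(exam, ratio_mom="ratio_of_moms")
        assert a.cpr_mom == pytest.approx(b.cpr_mom, rel=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            compute_index_set(make_exam(), ratio_mom="bogus")


class TestEstimateFetalWeight:
    def test_matches_direct_formula_evaluation(self):
        # frozen from an independent evaluation of the shipped log10 regression
        assert estimate_fetal_weight(8.5, 31.0, 30.0, 6.5) == pytest.approx(2311.2664, abs=0.01)

    def test_strictly_increasing_in_each_argument(self):
        base = (8.5, 31.0, 30.0, 6.5)
        ref = estimate_fetal_weight(*base)
        for j in range(4):
            bumped = list(base)
            bumped[j] += 0.5
            assert estimate_fetal_weight(*bumped) > ref

    def test_non_positive_measurement_rejected(self):
        with pytest.raises(ValidationError):
            estimate_fetal_weight(8.5, 31.0, 30.0, 0.0)

    def test_implausible_measurement_warns(self):
        with pytest.warns(UserWarning):
            estimate_fetal_weight(8.5, 31.0, 30.0, 2.0)


class TestFgrClassifier:
    def test_severe_smallness_alone_is_sufficient(self):
        positive, crit = classify_late_onset_fgr(2.0, 50.0, False, 50.0, 50.0)
        assert positive and crit.severe_smallness

    def test_two_of_three_minor_criteria(self):
        positive, crit = classify_late_onset_fgr(8.0, 50.0, False, 50.0, 96.0)
        assert positive
        assert crit.mild_smallness and crit.abnormal_doppler and not crit.severe_smallness

    def test_single_minor_criterion_insufficient(self):
        positive, _ = classify_late_onset_fgr(8.0, 50.0, False, 50.0, 50.0)
        assert not positive

    def test_ac_and_efw_percentiles_are_or_combined(self):
        positive, _ = classify_late_onset_fgr(50.0, 2.0, False, 50.0, 50.0)
        assert positive

    def test_percentile_domain_enforced(self):
        with pytest.raises(ValidationError):
            classify_late_onset_fgr(0.0, 50.0, False, 50.0, 50.0)


class TestCompositeOutcome:
    def test_low_apgar_alone_triggers(self):
        assert composite_adverse_outcome(make_record(apgar5=6)) is True

    def test_acidotic_cord_ph_alone_triggers(self):
        assert composite_adverse_outcome(make_record(ua_ph=7.05)) is True

    def test_thresholds_are_strict(self):
        rec = make_record(apgar5=7, ua_ph=7.10)
        assert composite_adverse_outcome(rec) is False

    def test_monotone_in_components(self):
        # setting any single component positive never flips true -> false
        for flag in ("stillbirth", "emergency_cs_fetal_distress", "nicu_admission"):
            assert composite_adverse_outcome(make_record(**{flag: True})) is True

    def test_missing_component_raises(self):
        with pytest.raises(ValidationError):
            composite_adverse_outcome(make_record(ua_ph=None))


class TestExclusionFilter:
    def test_study_fixture_counts(self, default_cohort):
        analyzed, ledger = exclusion_filter(default_cohort.records)
        assert len(default_cohort.records) == 186
        assert len(analyzed) == 114
        assert ledger == {"early_fgr": 58, "lost_followup": 7,
                          "missing_data": 4, "malformation": 3}

    def test_conserves_records(self, default_cohort):
        analyzed, ledger = exclusion_filter(default_cohort.records)
        assert len(analyzed) + sum(ledger.values()) == len(default_cohort.records)

    def test_all_eligible_is_identity(self):
        records = [make_record(record_id=f"T{i:04d}") for i in range(5)]
        analyzed, ledger = exclusion_filter(records)
        assert analyzed == records
        assert sum(ledger.values()) == 0

    def test_empty_input(self):
        analyzed, ledger = exclusion_filter([])
        assert analyzed == [] and sum(ledger.values()) == 0

    def test_idempotent_on_analyzed_output(self, default_cohort):
        analyzed, _ = exclusion_filter(default_cohort.records)
        again, ledger = exclusion_filter(analyzed)
        assert again == analyzed and sum(ledger.values()) == 0

    def test_precedence_early_fgr_over_malformation(self):
        rec = make_record(ga_detection=30.0, exam=None, malformation=True)
        _, ledger = exclusion_filter([rec])
        assert ledger["early_fgr"] == 1 and ledger["malformation"] == 0
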