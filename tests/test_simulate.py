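import copy

import numpy as np
import pandas as pd
import pytest

from upcr import (
    ConfigurationError,
    SimConfig,
    composite_adverse_outcome,
    generate_cohort,
    simulate_index_marginal,
)
from upcr.io import cohort_to_frame, read_cohort_csv, write_cohort_csv
from upcr.pipeline import build_analysis_frame


class TestDefaultCohort:
    def test_study_counts(self, default_cohort, analysis_frame):
        assert default_cohort.n_recruited == 186
        assert default_cohort.n_analyzed == 114
        assert int(analysis_frame["adverse"].sum()) == 37

    def test_exclusion_ledger_matches_config(self, default_cohort, default_config):
        assert default_cohort.ledger == default_config.exclusion_counts

    def test_outcome_component_counts_are_exact(self, default_cohort):
        analyzed = default_cohort.analyzed
        nicu = sum(r.nicu_admission for r in analyzed)
        apgar = sum(r.apgar5 < 7 for r in analyzed)
        ph = sum(r.ua_ph < 7.10 for r in analyzed)
        cs = sum(r.emergency_cs_fetal_distress for r in analyzed)
        sb = sum(r.stillbirth for r in analyzed)
        assert (nicu, apgar, ph, cs, sb) == (27, 14, 4, 16, 0)

    def test_adverse_label_consistent_with_composite_outcome(self, default_cohort):
        adverse = [composite_adverse_outcome(r) for r in default_cohort.analyzed]
        assert sum(adverse) == 37

    def test_same_seed_gives_identical_cohort(self, default_config, default_cohort):
        again = generate_cohort(copy.deepcopy(default_config))
        f1, f2 = cohort_to_frame(default_cohort), cohort_to_frame(again)
        pd.testing.assert_frame_equal(f1, f2)

    def test_different_seed_gives_different_cohort(self, default_config):
        cfg = copy.deepcopy(default_config)
        cfg.seed = 7
        other = cohort_to_frame(generate_cohort(cfg))
        base = cohort_to_frame(generate_cohort(default_config))
        assert not base.equals(other)


def test_zero_noise_zero_correlation_limit():
    cfg = SimConfig(seed=3)
    cfg.replicate_cv = 0.0
    cfg.vessel_corr = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    cohort = generate_cohort(cfg)
    for rec in cohort.analyzed:
        for vessel in ("ua_pi", "mca_pi", "uta_left_pi", "uta_right_pi"):
            reps = getattr(rec.exam, vessel)
            assert reps[0] == reps[1] == reps[2]


def test_ledger_conservation_under_modified_counts():
    cfg = SimConfig(seed=11)
    cfg.n_recruited = 60
    cfg.n_analyzed_target = 40
    cfg.n_adverse = 13
    cfg.exclusion_counts = {"early_fgr": 10, "lost_followup": 5, "missing_data": 3, "malformation": 2}
    cfg.outcome_counts = None  # component counts are tied to the full-size cohort
    cohort = generate_cohort(cfg)
    assert cohort.n_analyzed + sum(cohort.ledger.values()) == cohort.n_recruited == 60


class TestConfigValidation:
    def test_exclusion_sum_mismatch_rejected(self):
        cfg = SimConfig()
        cfg.exclusion_counts = {"early_fgr": 1, "lost_followup": 0, "missing_data": 0, "malformation": 0}
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_all_zero_component_probabilities_infeasible(self):
        cfg = SimConfig()
        cfg.outcome_counts = None
        cfg.outcome_probs = {k: 0.0 for k in cfg.outcome_probs}
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg)

    def test_component_counts_below_adverse_total_infeasible(self):
        cfg = SimConfig()
        cfg.outcome_counts = {k: 0 for k in cfg.outcome_counts}
        cfg.outcome_counts["nicu_admission"] = 5  # 5 < 37 adverse records
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_asymmetric_correlation_rejected(self):
        cfg = SimConfig()
        cfg.vessel_corr = ((1.0, 0.5, 0.0), (0.2, 1.0, 0.0), (0.0, 0.0, 1.0))
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_non_psd_correlation_rejected(self):
        cfg = SimConfig()
        cfg.vessel_corr = ((1.0, 0.99, -0.99), (0.99, 1.0, 0.99), (-0.99, 0.99, 1.0))
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestYamlConfig:
    def test_omitted_fields_take_defaults(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("seed: 9\nreplicate_cv: 0.02\n")
        cfg = SimConfig.from_yaml(path)
        assert cfg.seed == 9
        assert cfg.replicate_cv == 0.02
        assert cfg.n_recruited == 186

    def test_nested_override_merges(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("mom_means:\n  adverse:\n    upcr: 3.0\n")
        cfg = SimConfig.from_yaml(path)
        assert cfg.mom_means["adverse"]["upcr"] == 3.0
        assert cfg.mom_means["normal"]["upcr"] == 1.74

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("not_a_field: 1\n")
        with pytest.raises(ConfigurationError):
            SimConfig.from_yaml(path)


def test_csv_round_trip(default_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    write_cohort_csv(default_cohort, path)
    back = read_cohort_csv(path)
    f1, f2 = cohort_to_frame(default_cohort), cohort_to_frame(back)
    pd.testing.assert_frame_equal(f1, f2, check_dtype=False)
    assert back.ledger == default_cohort.ledger


class TestMomentCalibration:
    """At 100x scale the recovered vessel MoM moments must sit within three
    standard errors of the configured group values."""

    def test_vessel_moments(self, big_frame):
        cfg = SimConfig()
        for adverse, group in ((0, "normal"), (1, "adverse")):
            sub = big_frame[big_frame["adverse"] == adverse]
            n = len(sub)
            for col in ("ua_mom", "mca_mom", "uta_mom"):
                vessel = col.split("_")[0]
                target_mean = cfg.mom_means[group][vessel]
                target_sd = cfg.mom_sds[group][vessel]
                mean = sub[col].mean()
                sd_ = sub[col].std(ddof=1)
                se_mean = sd_ / np.sqrt(n)
                se_sd = sd_ / np.sqrt(2 * n)
                assert abs(mean - target_mean) <= 3 * se_mean, (group, col, "mean")
                assert abs(sd_ - target_sd) <= 3 * se_sd, (group, col, "sd")

    def test_derived_upcr_mean_tracks_group_target(self, big_frame):
        adverse = big_frame[big_frame["adverse"] == 1]["upcr_mom"]
        se = adverse.std(ddof=1) / np.sqrt(len(adverse))
        assert abs(adverse.mean() - 2.74) <= 3 * se


class TestIndexMarginalMode:
    def test_group_moments_match_configuration(self):
        rng = np.random.default_rng(5)
        scores, labels = simulate_index_marginal("upcr", 100_000, 100_000, rng=rng)
        cfg = SimConfig()
        for lab, group in ((0, "normal"), (1, "adverse")):
            s = scores[labels == lab]
            assert s.mean() == pytest.approx(cfg.mom_means[group]["upcr"], abs=0.01)
            assert s.std(ddof=1) == pytest.approx(cfg.mom_sds[group]["upcr"], abs=0.01)

    def test_scores_positive_and_labels_partitioned(self):
        scores, labels = simulate_index_marginal("cpr", 500, 200, rng=1)
        assert (scores > 0).all()
        assert (labels == 1).sum() == 200 and (labels == 0).sum() == 500

    def test_unknown_index_rejected(self):
        with pytest.raises(Exception):
            simulate_index_marginal("nope", 10, 10, rng=0)
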