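import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from upcr import SimConfig, generate_cohort
from upcr.pipeline import build_analysis_frame
from upcr.records import DopplerExam, PregnancyRecord

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """The study-conditions cohort: 186 recruited / 114 analyzed / 37 adverse."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def analysis_frame(default_cohort):
    return build_analysis_frame(default_cohort)


@pytest.fixture(scope="session")
def big_frame():
    """100x-scaled cohort for moment-calibration checks."""
    return build_analysis_frame(generate_cohort(SimConfig().scaled(100)))


def make_exam(**kw):
    base = dict(
        ga_weeks=34.0,
        ua_pi=(0.95, 1.0, 1.05),
        mca_pi=(1.5, 1.55, 1.6),
        uta_left_pi=(0.7, 0.72, 0.74),
        uta_right_pi=(0.66, 0.68, 0.70),
    )
    base.update(kw)
    return DopplerExam(**base)


def make_record(**kw):
    base = dict(
        record_id="T0001",
        maternal_age=30.0, bmi=27.0,
        nulliparous=True, previous_fgr=False, previous_stillbirth=False,
        gestational_diabetes=False, liver_disease=False,
        hypertensive_disease=False, preeclampsia=False,
        ga_detection=34.0, ga_delivery=37.0,
        bpd_cm=8.0, hc_cm=29.0, ac_cm=28.5, fl_cm=6.4,
        birthweight=2300.0, birthweight_percentile=5.0,
        efw_percentile=4.0, ac_percentile=5.0, crossed_quartiles=False,
        exam=make_exam(),
        stillbirth=False, emergency_cs_fetal_distress=False,
        nicu_admission=False, apgar5=9, ua_ph=7.25,
    )
    base.update(kw)
    return PregnancyRecord(**base)
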