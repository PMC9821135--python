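"""Domain types: one pregnancy, its Doppler exam, and a cohort of records."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, List, Optional, Tuple

from .errors import ValidationError

EXCLUSION_REASONS = ("early_fgr", "lost_followup", "missing_data", "malformation")
#: Controlled vocabulary for the CSV ``exclusion_reason`` column.
EXCLUSION_VOCAB = EXCLUSION_REASONS + ("none",)

Triple = Tuple[float, float, float]


def _check_triple(name: str, values) -> Triple:
    vals = tuple(float(v) for v in values)
    if len(vals) != 3:
        raise ValidationError(f"{name}: expected exactly 3 replicates, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise ValidationError(f"{name}: all PI replicates must be positive, got {vals}")
    return vals


@dataclass(frozen=True)
class DopplerExam:
    """Triplicate pulsatility indices for the three vessels at one visit.

    ``ga_weeks`` must lie in the late-onset eligibility window [32, 37];
    each vessel carries exactly three positive replicates (the analysis
    uses their arithmetic mean).
    """

    ga_weeks: float
    ua_pi: Triple
    mca_pi: Triple
    uta_left_pi: Triple
    uta_right_pi: Triple

    def __post_init__(self):
        if not 32.0 <= self.ga_weeks <= 37.0:
            raise ValidationError(
                f"exam gestational age {self.ga_weeks} outside [32, 37] weeks"
            )
        for name in ("ua_pi", "mca_pi", "uta_left_pi", "uta_right_pi"):
            object.__setattr__(self, name, _check_triple(name, getattr(self, name)))


@dataclass(frozen=True)
class IndexSet:
    """Per-pregnancy Doppler indices on the raw and MoM scales.

    The raw values satisfy (to 1e-9 relative):
    ``cpr * ua_pi = mca_pi``, ``upcr * mca_pi = ua_pi + uta_mean_pi`` and
    ``upcr = 1/cpr + uta_mean_pi/mca_pi``.
    """

    ua_pi: float
    mca_pi: float
    uta_mean_pi: float
    cpr: float
    upcr: float
    ua_mom: float
    mca_mom: float
    uta_mom: float
    cpr_mom: float
    upcr_mom: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValidationError(f"IndexSet.{f.name} must be positive, got {v}")

        def close(a, b):
            return abs(a - b) <= 1e-9 * max(abs(a), abs(b))

        if not close(self.cpr * self.ua_pi, self.mca_pi):
            raise ValidationError("IndexSet violates cpr * ua_pi = mca_pi")
        if not close(self.upcr * self.mca_pi, self.ua_pi + self.uta_mean_pi):
            raise ValidationError("IndexSet violates upcr * mca_pi = ua_pi + uta_mean_pi")
        if not close(self.upcr, 1.0 / self.cpr + self.uta_mean_pi / self.mca_pi):
            raise ValidationError("IndexSet violates upcr = 1/cpr + uta_mean/mca")


@dataclass
class PregnancyRecord:
    """One pregnancy: characteristics, biometry, Doppler exam and outcomes.

    Outcome fields are ``None`` when unknown (lost to follow-up / missing
    data); the composite-outcome evaluator refuses records with missing
    components, which is what routes them into the exclusion ledger.
    ``ga_detection`` is the gestational age at which growth restriction was
    first suspected; records detected before 32 weeks are early-onset and
    carry no study exam (``exam is None``).
    """

    record_id: str
    maternal_age: float
    bmi: float
    nulliparous: bool
    previous_fgr: bool
    previous_stillbirth: bool
    gestational_diabetes: bool
    liver_disease: bool
    hypertensive_disease: bool
    preeclampsia: bool
    ga_detection: float
    ga_delivery: Optional[float]
    bpd_cm: float
    hc_cm: float
    ac_cm: float
    fl_cm: float
    birthweight: Optional[float]
    birthweight_percentile: Optional[float]
    efw_percentile: float
    ac_percentile: float
    crossed_quartiles: bool
    exam: Optional[DopplerExam]
    stillbirth: Optional[bool]
    emergency_cs_fetal_distress: Optional[bool]
    nicu_admission: Optional[bool]
    apgar5: Optional[int]
    ua_ph: Optional[float]
    lost_followup: bool = False
    malformation: bool = False
    eligibility: str = "analyzed"

    def __post_init__(self):
        if self.birthweight is not None and not self.birthweight > 0:
            raise ValidationError(f"birthweight must be positive, got {self.birthweight}")
        if self.ua_ph is not None and not 6.5 < self.ua_ph < 7.8:
            raise ValidationError(f"umbilical pH {self.ua_ph} outside (6.5, 7.8)")
        if self.apgar5 is not None and not 0 <= int(self.apgar5) <= 10:
            raise ValidationError(f"apgar5 {self.apgar5} outside [0, 10]")
        if self.eligibility == "analyzed" and (
            self.ga_delivery is None or self.ga_delivery < 32.0
        ):
            raise ValidationError(
                "analyzed records must be delivered at >= 32 weeks"
            )

    @property
    def exclusion_reason(self) -> str:
        if self.eligibility.startswith("excluded:"):
            return self.eligibility.split(":", 1)[1]
        return "none"


@dataclass
class Cohort:
    """All recruited records plus the exclusion ledger."""

    records: List[PregnancyRecord]
    ledger: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        tallies = {r: 0 for r in EXCLUSION_REASONS}
        for rec in self.records:
            reason = rec.exclusion_reason
            if reason != "none":
                if reason not in tallies:
                    raise ValidationError(f"unknown exclusion reason {reason!r}")
                tallies[reason] += 1
        if self.ledger:
            for reason in EXCLUSION_REASONS:
                if self.ledger.get(reason, 0) != tallies[reason]:
                    raise ValidationError(
                        f"ledger[{reason!r}]={self.ledger.get(reason, 0)} "
                        f"disagrees with record tally {tallies[reason]}"
                    )
        self.ledger = tallies

    @property
    def analyzed(self) -> List[PregnancyRecord]:
        return [r for r in self.records if r.eligibility == "analyzed"]

    @property
    def n_recruited(self) -> int:
        return len(self.records)

    @property
    def n_analyzed(self) -> int:
        return len(self.analyzed)
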