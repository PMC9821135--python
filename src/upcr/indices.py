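"""Per-pregnancy Doppler index computation and clinical classifiers.

This module turns a triplicate Doppler exam into the analysis quantities:
replicate means, the cerebroplacental ratio CPR = MCA-PI / UA-PI, the
uteroplacental-cerebral ratio

    UPCR = (UA-PI + mean(left UtA-PI, right UtA-PI)) / MCA-PI,

their gestational-age-standardised MoM versions, plus estimated fetal
weight, the late-onset growth-restriction classifier, the composite
adverse perinatal outcome, and the recruitment exclusion filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

from .errors import ValidationError
from .records import Cohort, DopplerExam, IndexSet, PregnancyRecord
from .reference import ReferenceCurve, ReferenceCurves, default_reference_curves

# Hadlock-type four-parameter regression for estimated fetal weight
# (biometry in cm, weight in grams):
#   log10(EFW) = c0 + c1*AC*FL + c2*HC + c3*BPD*AC + c4*AC + c5*FL
HADLOCK4_COEFFS = (1.3596, -0.00386, 0.0064, 0.00061, 0.0424, 0.174)

#: Plausible third-trimester biometry ranges (cm) used for soft validation.
_BIOMETRY_RANGES = {"bpd": (5.5, 11.0), "hc": (22.0, 38.0), "ac": (20.0, 40.0), "fl": (4.0, 9.0)}


def triplicate_mean(replicates: Iterable[float]) -> float:
    """Arithmetic mean of exactly three positive replicate measurements."""
    vals = tuple(float(v) for v in replicates)
    if len(vals) != 3:
        raise ValidationError(f"expected exactly 3 replicates, got {len(vals)}")
    if any(v <= 0 for v in vals):
        raise ValidationError(f"replicates must all be positive, got {vals}")
    return sum(vals) / 3.0


def to_mom(value: float, ga_weeks: float, curve: ReferenceCurve) -> float:
    """Standardise a value as a multiple of the GA-specific reference median."""
    if not value > 0:
        raise ValidationError(f"value must be positive, got {value}")
    return value / curve.median_at(ga_weeks)


def compute_cpr(mca_pi: float, ua_pi: float) -> float:
    """Cerebroplacental ratio: MCA-PI divided by UA-PI."""
    if not (mca_pi > 0 and ua_pi > 0):
        raise ValidationError(f"PIs must be positive, got mca={mca_pi}, ua={ua_pi}")
    return mca_pi / ua_pi


def compute_upcr(ua_pi: float, uta_left_pi: float, uta_right_pi: float, mca_pi: float) -> float:
    """Uteroplacental-cerebral ratio: (UA-PI + mean L/R UtA-PI) / MCA-PI."""
    for name, v in (("ua", ua_pi), ("uta_left", uta_left_pi),
                    ("uta_right", uta_right_pi), ("mca", mca_pi)):
        if not v > 0:
            raise ValidationError(f"{name} PI must be positive, got {v}")
    return (ua_pi + 0.5 * (uta_left_pi + uta_right_pi)) / mca_pi


def compute_index_set(
    exam: DopplerExam,
    curves: ReferenceCurves | None = None,
    ratio_mom: str = "mom_of_ratio",
) -> IndexSet:
    """All raw and MoM indices for one exam.

    ``ratio_mom`` selects how CPR/UPCR are standardised:

    - ``"mom_of_ratio"`` (default): compute the ratio from raw PIs, then
      divide by the GA-specific median curve of that ratio.
    - ``"ratio_of_moms"``: form the ratio directly from vessel MoMs.
    """
    if curves is None:
        curves = default_reference_curves()
    if ratio_mom not in ("mom_of_ratio", "ratio_of_moms"):
        raise ValidationError(f"unknown ratio_mom mode {ratio_mom!r}")

    ga = exam.ga_weeks
    ua = triplicate_mean(exam.ua_pi)
    mca = triplicate_mean(exam.mca_pi)
    uta_l = triplicate_mean(exam.uta_left_pi)
    uta_r = triplicate_mean(exam.uta_right_pi)
    uta = 0.5 * (uta_l + uta_r)

    cpr = compute_cpr(mca, ua)
    upcr = compute_upcr(ua, uta_l, uta_r, mca)

    ua_mom = to_mom(ua, ga, curves.ua)
    mca_mom = to_mom(mca, ga, curves.mca)
    uta_mom = to_mom(uta, ga, curves.uta)
    if ratio_mom == "mom_of_ratio":
        cpr_mom = to_mom(cpr, ga, curves.cpr)
        upcr_mom = to_mom(upcr, ga, curves.upcr)
    else:
        cpr_mom = mca_mom / ua_mom
        upcr_mom = (ua_mom + uta_mom) / mca_mom

    return IndexSet(
        ua_pi=ua, mca_pi=mca, uta_mean_pi=uta, cpr=cpr, upcr=upcr,
        ua_mom=ua_mom, mca_mom=mca_mom, uta_mom=uta_mom,
        cpr_mom=cpr_mom, upcr_mom=upcr_mom,
    )


def estimate_fetal_weight(bpd: float, hc: float, ac: float, fl: float) -> float:
    """Estimated fetal weight (grams) from BPD/HC/AC/FL in centimetres.

    Uses the classical four-parameter log10 regression (coefficients in
    :data:`HADLOCK4_COEFFS`); strictly increasing in each argument over
    the plausible third-trimester range.
    """
    import warnings

    vals = {"bpd": bpd, "hc": hc, "ac": ac, "fl": fl}
    for name, v in vals.items():
        if not v > 0:
            raise ValidationError(f"{name} must be positive, got {v}")
        lo, hi = _BIOMETRY_RANGES[name]
        if not lo <= v <= hi:
            warnings.warn(
                f"{name}={v} cm outside the plausible third-trimester range [{lo}, {hi}]",
                stacklevel=2,
            )
    c0, c1, c2, c3, c4, c5 = HADLOCK4_COEFFS
    log10_efw = c0 + c1 * ac * fl + c2 * hc + c3 * bpd * ac + c4 * ac + c5 * fl
    return 10.0 ** log10_efw


@dataclass(frozen=True)
class FgrCriteria:
    """Which diagnostic criteria fired for a late-onset FGR call."""

    severe_smallness: bool   # AC or EFW percentile < 3
    mild_smallness: bool     # AC or EFW percentile < 10
    crossed_quartiles: bool  # growth trajectory crossed > 2 quartiles
    abnormal_doppler: bool   # CPR < 5th pct or UA-PI > 95th pct

    @property
    def positive(self) -> bool:
        minor = sum((self.mild_smallness, self.crossed_quartiles, self.abnormal_doppler))
        return self.severe_smallness or minor >= 2


def classify_late_onset_fgr(
    efw_percentile: float,
    ac_percentile: float,
    crossed_quartiles: bool,
    cpr_percentile: float,
    ua_pi_percentile: float,
) -> Tuple[bool, FgrCriteria]:
    """Consensus late-onset FGR call from precomputed percentiles.

    Positive when AC or EFW is below the 3rd percentile, or when at least
    two of the following hold: AC/EFW below the 10th percentile, growth
    crossing more than two quartiles, or abnormal Doppler (CPR below the
    5th or UA-PI above the 95th percentile).
    """
    for name, p in (("efw_percentile", efw_percentile), ("ac_percentile", ac_percentile),
                    ("cpr_percentile", cpr_percentile), ("ua_pi_percentile", ua_pi_percentile)):
        if not 0 < p < 100:
            raise ValidationError(f"{name} must lie in (0, 100), got {p}")
    crit = FgrCriteria(
        severe_smallness=min(efw_percentile, ac_percentile) < 3.0,
        mild_smallness=min(efw_percentile, ac_percentile) < 10.0,
        crossed_quartiles=bool(crossed_quartiles),
        abnormal_doppler=cpr_percentile < 5.0 or ua_pi_percentile > 95.0,
    )
    return crit.positive, crit


#: Outcome components of the composite adverse perinatal outcome.  Apgar and
#: cord pH enter through strict thresholds (< 7 and < 7.10 respectively).
OUTCOME_COMPONENTS = (
    "stillbirth",
    "emergency_cs_fetal_distress",
    "nicu_admission",
    "apgar5",
    "ua_ph",
)


def composite_adverse_outcome(record: PregnancyRecord) -> bool:
    """True when any component of the composite adverse outcome is present.

    Components: stillbirth, emergency caesarean for fetal distress, 5-min
    Apgar < 7, umbilical-artery pH < 7.10, special-care (NICU) admission.
    Raises :class:`ValidationError` when a component is missing, which is
    what routes incomplete records to the ``missing_data`` exclusion.
    """
    for name in OUTCOME_COMPONENTS:
        if getattr(record, name) is None:
            raise ValidationError(f"outcome component {name!r} missing on {record.record_id}")
    return bool(
        record.stillbirth
        or record.emergency_cs_fetal_distress
        or record.nicu_admission
        or record.apgar5 < 7
        or record.ua_ph < 7.10
    )


def _exclusion_reason(record: PregnancyRecord) -> str:
    """First matching reason under precedence early_fgr > malformation >
    lost_followup > missing_data; 'none' if eligible."""
    if record.ga_detection < 32.0:
        return "early_fgr"
    if record.malformation:
        return "malformation"
    if record.lost_followup:
        return "lost_followup"
    if any(getattr(record, n) is None for n in OUTCOME_COMPONENTS) or record.exam is None:
        return "missing_data"
    return "none"


def exclusion_filter(records: Iterable[PregnancyRecord]) -> Tuple[List[PregnancyRecord], Dict[str, int]]:
    """Partition recruited records into the analyzed set and an exclusion ledger.

    Returns the analyzed records (eligibility stamped ``analyzed``) and a
    ledger mapping each exclusion reason to its count.  Conserves records:
    ``len(analyzed) + sum(ledger.values()) == len(records)``.
    """
    ledger = {"early_fgr": 0, "lost_followup": 0, "missing_data": 0, "malformation": 0}
    analyzed: List[PregnancyRecord] = []
    for rec in records:
        reason = _exclusion_reason(rec)
        if reason == "none":
            rec.eligibility = "analyzed"
            analyzed.append(rec)
        else:
            rec.eligibility = f"excluded:{reason}"
            ledger[reason] += 1
    return analyzed, ledger
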