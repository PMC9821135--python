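"""Seeded synthetic cohort generator for the late-onset FGR analysis.

The generator emulates a single-centre prospective cohort of pregnancies
with suspected growth restriction: 186 recruited, 72 excluded (58 early
onset, 7 lost to follow-up, 4 missing data, 3 malformation/aneuploidy),
114 analyzed of whom 37 experienced the composite adverse perinatal
outcome.  Analyzed records draw their (UA, MCA, UtA) MoM triple from a
truncated multivariate Gaussian with group-specific means/SDs and a shared
inter-vessel correlation matrix; raw pulsatility indices are back-computed
through the reference median curves at the record's gestational age, and
every vessel gets three replicates with multiplicative measurement noise.

Randomness is organised as documented substreams spawned from one master
seed (characteristics, vessels, replicates, outcomes, excluded records,
ordering), so extending one stage never perturbs the draws of another.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .indices import composite_adverse_outcome
from .records import Cohort, DopplerExam, PregnancyRecord
from .reference import ReferenceCurves, default_reference_curves

VESSELS = ("ua", "mca", "uta")
INDICES = ("ua", "mca", "uta", "cpr", "upcr")
GROUPS = ("normal", "adverse")

# Group moments of the Doppler MoMs (normal outcome n=77 / adverse n=37).
_DEFAULT_MOM_MEANS = {
    "normal": {"ua": 1.21, "mca": 0.84, "uta": 1.59, "cpr": 0.69, "upcr": 1.74},
    "adverse": {"ua": 1.48, "mca": 0.69, "uta": 2.23, "cpr": 0.49, "upcr": 2.74},
}
_DEFAULT_MOM_SDS = {
    "normal": {"ua": 0.32, "mca": 0.19, "uta": 0.70, "cpr": 0.24, "upcr": 0.73},
    "adverse": {"ua": 0.48, "mca": 0.14, "uta": 0.53, "cpr": 0.20, "upcr": 0.76},
}

# Inter-vessel MoM correlations, order (ua, mca, uta): placental impedance
# couples UA and UtA positively; cerebral redistribution opposes both.
_DEFAULT_CORR = ((1.0, -0.2, 0.3), (-0.2, 1.0, -0.2), (0.3, -0.2, 1.0))

# Outcome component prevalences conditional on adverse status (counts among
# the 37 adverse: emergency CS 16, cord pH < 7.10 in 4, Apgar < 7 in 14,
# special-care admission 27, no stillbirth).
_DEFAULT_OUTCOME_COUNTS = {
    "stillbirth": 0,
    "emergency_cs_fetal_distress": 16,
    "apgar_low": 14,
    "ua_ph_low": 4,
    "nicu_admission": 27,
}

_DEFAULT_CHARACTERISTICS = {
    "maternal_age": {"normal": (30.1, 4.6), "adverse": (29.8, 5.7)},
    "bmi": {"normal": (28.4, 4.5), "adverse": (29.3, 5.6)},
    "ga_detection": {"normal": (34.0, 1.4), "adverse": (33.6, 1.5)},
    "ga_delivery": {"normal": (37.3, 1.7), "adverse": (35.5, 1.5)},
    "birthweight": {"normal": (2358.7, 296.1), "adverse": (2059.7, 232.4)},
    "birthweight_percentile": {"normal": (5.7, 2.8), "adverse": (4.1, 2.2)},
    "nulliparous": {"normal": 48 / 77, "adverse": 19 / 37},
    "previous_fgr": {"normal": 3 / 77, "adverse": 4 / 37},
    "previous_stillbirth": {"normal": 0 / 77, "adverse": 1 / 37},
    "gestational_diabetes": {"normal": 6 / 77, "adverse": 3 / 37},
    "liver_disease": {"normal": 5 / 77, "adverse": 2 / 37},
    "hypertensive_disease": {"normal": 46 / 77, "adverse": 26 / 37},
    # Preeclampsia is modelled as a subset of hypertensive disease.
    "preeclampsia_given_htn": {"normal": 0.5, "adverse": 0.5},
    "efw_lt3": {"normal": 20 / 77, "adverse": 18 / 37},
    "crossed_quartiles": {"normal": 0.15, "adverse": 0.35},
}


@dataclass
class SimConfig:
    """All generator parameters; the defaults ARE the study conditions.

    ``outcome_counts`` (when set, the default) allocates the exact printed
    component counts among the adverse records; set it to ``None`` to draw
    components independently from ``outcome_probs`` instead (each adverse
    record is redrawn until it has at least one positive component).
    """

    n_recruited: int = 186
    n_analyzed_target: int = 114
    n_adverse: int = 37
    exclusion_counts: Dict[str, int] = field(
        default_factory=lambda: {
            "early_fgr": 58, "lost_followup": 7, "missing_data": 4, "malformation": 3,
        }
    )
    mom_means: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_MOM_MEANS))
    mom_sds: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_MOM_SDS))
    vessel_corr: Tuple[Tuple[float, ...], ...] = _DEFAULT_CORR
    outcome_counts: Optional[Dict[str, int]] = field(
        default_factory=lambda: dict(_DEFAULT_OUTCOME_COUNTS))
    outcome_probs: Dict[str, float] = field(
        default_factory=lambda: {k: v / 37 for k, v in _DEFAULT_OUTCOME_COUNTS.items()})
    replicate_cv: float = 0.05
    uta_side_asymmetry_sd: float = 0.08
    ga_detection_range: Tuple[float, float] = (32.0, 37.0)
    characteristics: Dict[str, Dict] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_CHARACTERISTICS))
    truncation_floor: float = 0.05
    seed: int = 42

    # -- derived -----------------------------------------------------------
    @property
    def n_normal(self) -> int:
        return self.n_analyzed_target - self.n_adverse

    @property
    def n_excluded(self) -> int:
        return self.n_recruited - self.n_analyzed_target

    def validate(self) -> None:
        if self.n_analyzed_target <= 0 or self.n_adverse < 0 or self.n_adverse > self.n_analyzed_target:
            raise ConfigurationError("need 0 <= n_adverse <= n_analyzed_target > 0")
        if sum(self.exclusion_counts.values()) != self.n_excluded:
            raise ConfigurationError(
                "sum of exclusion_counts must equal n_recruited - n_analyzed_target"
            )
        if any(c < 0 for c in self.exclusion_counts.values()):
            raise ConfigurationError("exclusion counts must be non-negative")
        for group in GROUPS:
            for idx in INDICES:
                if not self.mom_sds[group][idx] > 0:
                    raise ConfigurationError(f"mom_sds[{group}][{idx}] must be > 0")
                if not self.mom_means[group][idx] > 0:
                    raise ConfigurationError(f"mom_means[{group}][{idx}] must be > 0")
        corr = np.asarray(self.vessel_corr, dtype=float)
        if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
            raise ConfigurationError("vessel correlation matrix must be 3x3 symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConfigurationError("vessel correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("vessel correlation matrix must be positive semi-definite")
        if not 0 <= self.replicate_cv < 0.5:
            raise ConfigurationError("replicate_cv must lie in [0, 0.5)")
        expected_keys = set(_DEFAULT_OUTCOME_COUNTS)
        if set(self.outcome_probs) != expected_keys:
            raise ConfigurationError(f"outcome_probs must have keys {sorted(expected_keys)}")
        if self.outcome_counts is not None and set(self.outcome_counts) != expected_keys:
            raise ConfigurationError(f"outcome_counts must have keys {sorted(expected_keys)}")
        for k, p in self.outcome_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"outcome_probs[{k}] must lie in [0, 1]")
        if self.n_adverse > 0:
            if self.outcome_counts is not None:
                counts = self.outcome_counts
                if any(c < 0 or c > self.n_adverse for c in counts.values()):
                    raise ConfigurationError("outcome counts must lie in [0, n_adverse]")
                if sum(counts.values()) < self.n_adverse:
                    raise ConfigurationError(
                        "sum of outcome component counts must be >= n_adverse so every "
                        "adverse record can carry at least one component"
                    )
            elif all(p == 0 for p in self.outcome_probs.values()):
                raise ConfigurationError(
                    "all outcome component probabilities are zero but adverse records "
                    "must have at least one positive component"
                )

    def scaled(self, factor: int) -> "SimConfig":
        """Scale every count by ``factor`` (moments and probabilities unchanged)."""
        cfg = copy.deepcopy(self)
        cfg.n_recruited *= factor
        cfg.n_analyzed_target *= factor
        cfg.n_adverse *= factor
        cfg.exclusion_counts = {k: v * factor for k, v in cfg.exclusion_counts.items()}
        if cfg.outcome_counts is not None:
            cfg.outcome_counts = {k: v * factor for k, v in cfg.outcome_counts.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a config from YAML; omitted fields keep their defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown config field {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                merged = copy.deepcopy(default)
                for k, v in value.items():
                    if isinstance(merged.get(k), dict) and isinstance(v, dict):
                        merged[k].update(v)
                    else:
                        merged[k] = v
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# sampling helpers


def _substreams(seed: int) -> Dict[str, np.random.Generator]:
    """Named, independent random substreams spawned from one master seed."""
    names = ("characteristics", "vessels", "replicates", "outcomes", "excluded", "order")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _matched_truncation_params(mean: float, sd: float, floor: float):
    """Pre-truncation (mu, sigma) whose below-``floor``-truncated normal has
    the requested mean and SD.

    Fixed-point iteration on the truncated-normal moment identities
    (mean = mu + sigma*lam, var = sigma^2 * (1 - lam*(lam - alpha)) with
    alpha = (floor - mu)/sigma, lam = phi(alpha)/(1 - Phi(alpha))).  For
    floors several SDs below the mean the adjustment is negligible.
    """
    from scipy.stats import norm

    mu, sigma = float(mean), float(sd)
    for _ in range(200):
        alpha = (floor - mu) / sigma
        lam = float(norm.pdf(alpha) / norm.sf(alpha)) if alpha > -12 else 0.0
        var_factor = 1.0 - lam * (lam - alpha)
        if var_factor <= 0:
            raise ConfigurationError(
                f"cannot match moments: floor {floor} too close to mean {mean}"
            )
        sigma_new = sd / math.sqrt(var_factor)
        mu_new = mean - sigma_new * lam
        if abs(sigma_new - sigma) < 1e-12 and abs(mu_new - mu) < 1e-12:
            return mu_new, sigma_new
        mu, sigma = mu_new, sigma_new
    return mu, sigma


def _truncated_mvn(rng, mean, cov, floor, size):
    """Multivariate normal draws with every coordinate resampled above ``floor``."""
    out = rng.multivariate_normal(mean, cov, size=size, method="cholesky")
    bad = (out < floor).any(axis=1)
    while bad.any():
        out[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="cholesky")
        bad = (out < floor).any(axis=1)
    return out


def _allocate_components(n: int, counts: Dict[str, int], rng) -> Dict[str, np.ndarray]:
    """0/1 component matrix with exact column sums and every row sum >= 1.

    Columns are filled by sampling ``counts[c]`` rows without replacement;
    rows left empty then steal one positive from a row holding two or more
    (column sums are preserved).  Feasible iff sum(counts) >= n.
    """
    comps = list(counts)
    mat = np.zeros((n, len(comps)), dtype=bool)
    for j, c in enumerate(comps):
        k = counts[c]
        if k > 0:
            mat[rng.choice(n, size=k, replace=False), j] = True
    if sum(counts.values()) < n:
        raise ConfigurationError("fewer outcome component positives than adverse records")
    empty = np.flatnonzero(~mat.any(axis=1))
    for i in empty:
        donors = np.flatnonzero(mat.sum(axis=1) >= 2)
        donor = int(rng.choice(donors))
        j = int(rng.choice(np.flatnonzero(mat[donor])))
        mat[donor, j] = False
        mat[i, j] = True
    return {c: mat[:, j] for j, c in enumerate(comps)}


def _draw_components(n: int, probs: Dict[str, float], rng) -> Dict[str, np.ndarray]:
    """Independent Bernoulli components, redrawing rows until each has >= 1."""
    comps = list(probs)
    p = np.array([probs[c] for c in comps])
    if n > 0 and (p == 0).all():
        raise ConfigurationError("all outcome component probabilities are zero")
    mat = rng.random((n, len(comps))) < p
    empty = np.flatnonzero(~mat.any(axis=1))
    while empty.size:
        mat[empty] = rng.random((empty.size, len(comps))) < p
        empty = empty[~mat[empty].any(axis=1)]
    return {c: mat[:, j] for j, c in enumerate(comps)}


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: SimConfig, curves: ReferenceCurves | None = None) -> Cohort:
    """Generate one synthetic recruited cohort (deterministic given the seed).

    Exactly ``n_analyzed_target`` records pass the exclusion filter, split
    ``n_adverse`` / ``n_normal``; the remaining records carry exactly the
    configured exclusion-reason markers.
    """
    config.validate()
    if curves is None:
        curves = default_reference_curves()
    rngs = _substreams(config.seed)

    records = []
    counter = 0

    def next_id():
        nonlocal counter
        counter += 1
        return f"P{counter:05d}"

    for group, n_group in (("normal", config.n_normal), ("adverse", config.n_adverse)):
        if n_group == 0:
            continue
        records.extend(
            _analyzed_records(group, n_group, config, curves, rngs, next_id)
        )
    records.extend(_excluded_records(config, curves, rngs, next_id))

    order = rngs["order"].permutation(len(records))
    records = [records[i] for i in order]
    return Cohort(records=records)


def _analyzed_records(group, n, config, curves, rngs, next_id):
    ch = config.characteristics
    crng, vrng, rrng, orng = (rngs["characteristics"], rngs["vessels"],
                              rngs["replicates"], rngs["outcomes"])

    # --- maternal characteristics & delivery data
    age = _truncated_normal(crng, *ch["maternal_age"][group], 15.0, 50.0, n)
    bmi = _truncated_normal(crng, *ch["bmi"][group], 15.0, 50.0, n)
    ga_det = _truncated_normal(crng, *ch["ga_detection"][group], *config.ga_detection_range, n)
    mu_del, sd_del = ch["ga_delivery"][group]
    ga_del = np.array([
        float(_truncated_normal(crng, mu_del, sd_del, max(32.0, g), 41.5, 1)[0])
        for g in ga_det
    ])
    bw = _truncated_normal(crng, *ch["birthweight"][group], 800.0, 4200.0, n)
    bw_pct = _truncated_normal(crng, *ch["birthweight_percentile"][group], 0.1, 25.0, n)
    flags = {
        name: crng.random(n) < ch[name][group]
        for name in ("nulliparous", "previous_fgr", "previous_stillbirth",
                     "gestational_diabetes", "liver_disease", "hypertensive_disease")
    }
    pe = flags["hypertensive_disease"] & (crng.random(n) < ch["preeclampsia_given_htn"][group])
    efw_lt3 = crng.random(n) < ch["efw_lt3"][group]
    efw_pct = np.where(efw_lt3, crng.uniform(0.5, 2.99, n), crng.uniform(3.01, 12.0, n))
    ac_pct = np.clip(efw_pct * np.exp(crng.normal(0.0, 0.2, n)), 0.2, 30.0)
    crossed = crng.random(n) < ch["crossed_quartiles"][group]

    # --- biometry: schematic GA trends for a growth-restricted fetus (cm)
    biom_noise = np.exp(crng.normal(0.0, 0.02, (n, 4)))
    bpd = (0.22 * ga_det + 0.35) * biom_noise[:, 0]
    hc = (0.80 * ga_det + 1.80) * biom_noise[:, 1]
    ac = (0.95 * ga_det - 3.50) * biom_noise[:, 2]
    fl = (0.21 * ga_det - 0.70) * biom_noise[:, 3]

    # --- vessel MoM triples from the truncated correlated Gaussian; the
    # pre-truncation parameters are moment-matched so the truncated draws
    # reproduce the configured group means/SDs.
    matched = [
        _matched_truncation_params(config.mom_means[group][v],
                                   config.mom_sds[group][v],
                                   config.truncation_floor)
        for v in VESSELS
    ]
    mean = np.array([m for m, _ in matched])
    sd = np.array([s for _, s in matched])
    corr = np.asarray(config.vessel_corr, dtype=float)
    cov = corr * np.outer(sd, sd)
    moms = _truncated_mvn(vrng, mean, cov, config.truncation_floor, n)
    uta_delta = np.clip(vrng.normal(0.0, config.uta_side_asymmetry_sd, n), -0.4, 0.4)

    # --- outcome components
    if group == "adverse":
        if config.outcome_counts is not None:
            comp = _allocate_components(n, config.outcome_counts, orng)
        else:
            comp = _draw_components(n, config.outcome_probs, orng)
    else:
        comp = {k: np.zeros(n, dtype=bool) for k in config.outcome_probs}
    apgar_ok = orng.integers(7, 11, n)
    apgar_bad = orng.integers(3, 7, n)
    ph_ok = orng.uniform(7.12, 7.42, n)
    ph_bad = orng.uniform(6.90, 7.095, n)

    out = []
    for i in range(n):
        ga = float(ga_det[i])
        raw = {v: moms[i, j] * curves.curve(v).median_at(ga) for j, v in enumerate(VESSELS)}
        uta_l = raw["uta"] * (1.0 + uta_delta[i])
        uta_r = raw["uta"] * (1.0 - uta_delta[i])

        def reps(value):
            factors = np.clip(1.0 + config.replicate_cv * rrng.standard_normal(3), 0.05, None)
            return tuple(float(value * f) for f in factors)

        exam = DopplerExam(
            ga_weeks=ga, ua_pi=reps(raw["ua"]), mca_pi=reps(raw["mca"]),
            uta_left_pi=reps(uta_l), uta_right_pi=reps(uta_r),
        )
        stillbirth = bool(comp["stillbirth"][i])
        apgar = 0 if stillbirth else int(apgar_bad[i] if comp["apgar_low"][i] else apgar_ok[i])
        rec = PregnancyRecord(
            record_id=next_id(),
            maternal_age=float(age[i]), bmi=float(bmi[i]),
            nulliparous=bool(flags["nulliparous"][i]),
            previous_fgr=bool(flags["previous_fgr"][i]),
            previous_stillbirth=bool(flags["previous_stillbirth"][i]),
            gestational_diabetes=bool(flags["gestational_diabetes"][i]),
            liver_disease=bool(flags["liver_disease"][i]),
            hypertensive_disease=bool(flags["hypertensive_disease"][i]),
            preeclampsia=bool(pe[i]),
            ga_detection=ga, ga_delivery=float(ga_del[i]),
            bpd_cm=float(bpd[i]), hc_cm=float(hc[i]), ac_cm=float(ac[i]), fl_cm=float(fl[i]),
            birthweight=float(bw[i]), birthweight_percentile=float(bw_pct[i]),
            efw_percentile=float(efw_pct[i]), ac_percentile=float(ac_pct[i]),
            crossed_quartiles=bool(crossed[i]),
            exam=exam,
            stillbirth=stillbirth,
            emergency_cs_fetal_distress=bool(comp["emergency_cs_fetal_distress"][i]),
            nicu_admission=bool(comp["nicu_admission"][i]),
            apgar5=apgar,
            ua_ph=float(ph_bad[i] if comp["ua_ph_low"][i] else ph_ok[i]),
            eligibility="analyzed",
        )
        assert composite_adverse_outcome(rec) == (group == "adverse")
        out.append(rec)
    return out


def _excluded_records(config, curves, rngs, next_id):
    """Records that must fall out of the analysis, one exclusion marker each."""
    erng = rngs["excluded"]
    ch = config.characteristics
    out = []
    for reason, count in config.exclusion_counts.items():
        for _ in range(count):
            ga = float(_truncated_normal(erng, *ch["ga_detection"]["normal"],
                                         *config.ga_detection_range, 1)[0])
            exam = None
            if reason == "early_fgr":
                ga = float(erng.uniform(26.0, 31.9))
            else:
                mom = np.maximum(erng.normal(
                    [config.mom_means["normal"][v] for v in VESSELS],
                    [config.mom_sds["normal"][v] for v in VESSELS],
                ), config.truncation_floor)
                raw = {v: mom[j] * curves.curve(v).median_at(ga) for j, v in enumerate(VESSELS)}
                exam = DopplerExam(
                    ga_weeks=ga,
                    ua_pi=(raw["ua"],) * 3, mca_pi=(raw["mca"],) * 3,
                    uta_left_pi=(raw["uta"],) * 3, uta_right_pi=(raw["uta"],) * 3,
                )
            known = reason not in ("lost_followup",)
            missing = reason == "missing_data"
            rec = PregnancyRecord(
                record_id=next_id(),
                maternal_age=float(_truncated_normal(erng, *ch["maternal_age"]["normal"], 15, 50, 1)[0]),
                bmi=float(_truncated_normal(erng, *ch["bmi"]["normal"], 15, 50, 1)[0]),
                nulliparous=bool(erng.random() < ch["nulliparous"]["normal"]),
                previous_fgr=False, previous_stillbirth=False,
                gestational_diabetes=bool(erng.random() < ch["gestational_diabetes"]["normal"]),
                liver_disease=False,
                hypertensive_disease=bool(erng.random() < ch["hypertensive_disease"]["normal"]),
                preeclampsia=False,
                ga_detection=ga,
                ga_delivery=float(erng.uniform(34.0, 41.0)) if known else None,
                bpd_cm=float(0.22 * ga + 0.35), hc_cm=float(0.80 * ga + 1.80),
                ac_cm=float(max(0.95 * ga - 3.50, 1.0)), fl_cm=float(max(0.21 * ga - 0.70, 1.0)),
                birthweight=float(erng.uniform(1200, 3000)) if known else None,
                birthweight_percentile=float(erng.uniform(0.5, 15)) if known else None,
                efw_percentile=float(erng.uniform(0.5, 12)),
                ac_percentile=float(erng.uniform(0.5, 12)),
                crossed_quartiles=False,
                exam=exam,
                stillbirth=False if known and not missing else None,
                emergency_cs_fetal_distress=False if known and not missing else None,
                nicu_admission=False if known and not missing else None,
                apgar5=9 if known and not missing else None,
                ua_ph=float(erng.uniform(7.15, 7.40)) if known and not missing else None,
                lost_followup=reason == "lost_followup",
                malformation=reason == "malformation",
                eligibility=f"excluded:{reason}",
            )
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# index-marginal mode


def simulate_index_marginal(
    index: str,
    n_normal: int,
    n_adverse: int,
    config: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate one Doppler index directly as group Gaussian MoM scores.

    Returns ``(scores, labels)`` with ``labels`` 1 for the adverse group.
    This is the companion model for marker-level performance questions:
    each group's MoM distribution is Gaussian with the configured group
    mean/SD, truncated below at the configured floor.
    """
    if config is None:
        config = SimConfig()
    if index not in INDICES:
        raise ValidationError(f"unknown index {index!r}; expected one of {INDICES}")
    if n_normal < 1 or n_adverse < 1:
        raise ValidationError("both groups need at least one observation")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    floor = config.truncation_floor
    mu0, sd0 = _matched_truncation_params(
        config.mom_means["normal"][index], config.mom_sds["normal"][index], floor)
    mu1, sd1 = _matched_truncation_params(
        config.mom_means["adverse"][index], config.mom_sds["adverse"][index], floor)
    s0 = _truncated_normal(rng, mu0, sd0, floor, np.inf, n_normal)
    s1 = _truncated_normal(rng, mu1, sd1, floor, np.inf, n_adverse)
    scores = np.concatenate([s0, s1])
    labels = np.concatenate([np.zeros(n_normal, dtype=int), np.ones(n_adverse, dtype=int)])
    return scores, labels
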