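"""End-to-end orchestration: simulate -> indices -> exclusion -> report tables.

``run_pipeline`` produces an :class:`AnalysisReport` holding the four
report tables: baseline characteristics (bootstrap t / chi-square /
Fisher), Doppler MoM comparisons (Mann-Whitney plus the severe-smallness
cross-tab), logistic regression with backward-stepwise selection, and
per-marker ROC summaries with paired DeLong comparisons against the
uteroplacental-cerebral ratio.  Everything is deterministic given the
configured seed; the report JSON is byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, ValidationError
from .indices import compute_index_set, composite_adverse_outcome, exclusion_filter
from .io import read_cohort_csv, write_cohort_csv
from .logistic import LogisticFit, StepwiseResult, backward_stepwise_lr, fit_logistic_irls
from .records import Cohort
from .reference import default_reference_curves
from .roc import RocSummary, delong_paired_test, youden_summary
from .simulate import SimConfig, generate_cohort
from .stats import GroupComparison, fisher_exact_2x2, mann_whitney, pearson_chi2_2x2, welch_t

log = logging.getLogger("upcr.pipeline")

#: Doppler markers carried through the comparison and ROC tables; the
#: orientation records which direction of the MoM predicts an adverse
#: outcome (cerebral redistribution lowers MCA PI and CPR).
MARKERS: Dict[str, str] = {
    "mca_mom": "lower",
    "ua_mom": "higher",
    "uta_mom": "higher",
    "cpr_mom": "lower",
    "upcr_mom": "higher",
}

REFERENCE_MARKER = "upcr_mom"
BOOTSTRAP_T_ITERATIONS = 10_000

_CONTINUOUS_T1 = [
    ("maternal_age", "Age (years)"),
    ("bmi", "BMI (kg/m2)"),
    ("ga_detection", "Gestational age at detection (weeks)"),
    ("ga_delivery", "Gestational age at birth (weeks)"),
    ("birthweight", "Birthweight (g)"),
    ("birthweight_percentile", "Birthweight percentile (%)"),
]
_CATEGORICAL_T1 = [
    ("nulliparous", "Nulliparous"),
    ("previous_fgr", "Previous FGR"),
    ("previous_stillbirth", "Previous stillbirth"),
    ("gestational_diabetes", "Gestational diabetes"),
    ("liver_disease", "Liver diseases"),
    ("hypertensive_disease", "Hypertensive diseases"),
]


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance."""

    n_recruited: int
    n_analyzed: int
    n_adverse: int
    ledger: Dict[str, int]
    table1: List[GroupComparison]
    table2: List[GroupComparison]
    table3_full: LogisticFit
    table3_stepwise: StepwiseResult
    table4: Dict[str, RocSummary]
    table4_vs_reference: Dict[str, Dict[str, float]]
    provenance: Dict[str, str] = field(default_factory=dict)


def build_analysis_frame(cohort: Cohort, ratio_mom: str = "mom_of_ratio") -> pd.DataFrame:
    """Analysis-ready frame: one row per analyzed record with index columns."""
    analyzed, ledger = exclusion_filter(cohort.records)
    curves = default_reference_curves()
    rows = []
    for rec in analyzed:
        idx = compute_index_set(rec.exam, curves, ratio_mom=ratio_mom)
        rows.append({
            "record_id": rec.record_id,
            "adverse": int(composite_adverse_outcome(rec)),
            "maternal_age": rec.maternal_age,
            "bmi": rec.bmi,
            "nulliparous": rec.nulliparous,
            "previous_fgr": rec.previous_fgr,
            "previous_stillbirth": rec.previous_stillbirth,
            "gestational_diabetes": rec.gestational_diabetes,
            "liver_disease": rec.liver_disease,
            "hypertensive_disease": rec.hypertensive_disease,
            "preeclampsia": rec.preeclampsia,
            "ga_detection": rec.ga_detection,
            "ga_delivery": rec.ga_delivery,
            "birthweight": rec.birthweight,
            "birthweight_percentile": rec.birthweight_percentile,
            "efw_lt3": rec.efw_percentile < 3.0,
            "ua_pi": idx.ua_pi, "mca_pi": idx.mca_pi, "uta_mean_pi": idx.uta_mean_pi,
            "cpr": idx.cpr, "upcr": idx.upcr,
            "ua_mom": idx.ua_mom, "mca_mom": idx.mca_mom, "uta_mom": idx.uta_mom,
            "cpr_mom": idx.cpr_mom, "upcr_mom": idx.upcr_mom,
        })
    frame = pd.DataFrame(rows)
    frame.attrs["ledger"] = ledger
    frame.attrs["n_recruited"] = len(cohort.records)
    return frame


def _crosstab(frame: pd.DataFrame, column: str) -> np.ndarray:
    """2x2 counts, row 0 = normal outcome, row 1 = adverse outcome (columns:
    flag present / absent), matching the normal-first column order of the
    emitted tables."""
    adv = frame["adverse"] == 1
    flag = frame[column].astype(bool)
    return np.array([
        [int((~adv & flag).sum()), int((~adv & ~flag).sum())],
        [int((adv & flag).sum()), int((adv & ~flag).sum())],
    ])


def _expected_counts_ok(table: np.ndarray) -> bool:
    t = np.asarray(table, dtype=float)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    return bool((expected >= 5).all())


def _categorical_comparison(frame, column, label, seed) -> GroupComparison:
    table = _crosstab(frame, column)
    # Degenerate margins (flag absent or universal) cannot be tested by
    # chi-square; Fisher handles them (p = 1).
    degenerate = min(table[:, 0].sum(), table[:, 1].sum()) == 0
    if not degenerate and _expected_counts_ok(table):
        gc = pearson_chi2_2x2(table, variable=label)
    else:
        gc = fisher_exact_2x2(table, variable=label)
    return gc


def build_table1(frame: pd.DataFrame, seed: int = 0) -> List[GroupComparison]:
    """Baseline-characteristic comparisons between outcome groups."""
    adverse = frame[frame["adverse"] == 1]
    normal = frame[frame["adverse"] == 0]
    out = []
    for i, (col, label) in enumerate(_CONTINUOUS_T1):
        out.append(welch_t(
            normal[col].to_numpy(float), adverse[col].to_numpy(float),
            bootstrap=BOOTSTRAP_T_ITERATIONS, seed=seed + i, variable=label,
        ))
    for col, label in _CATEGORICAL_T1:
        out.append(_categorical_comparison(frame, col, label, seed))
    return out


def build_table2(frame: pd.DataFrame) -> List[GroupComparison]:
    """Doppler index comparisons: severe-smallness cross-tab + MoM Mann-Whitney."""
    out = [pearson_chi2_2x2(_crosstab(frame, "efw_lt3"), variable="EFW < 3rd centile")]
    labels = {
        "mca_mom": "MCA PI MoM", "ua_mom": "UA PI MoM", "uta_mom": "Mean UtA PI MoM",
        "cpr_mom": "CPR MoM", "upcr_mom": "UPCR MoM",
    }
    adverse = frame[frame["adverse"] == 1]
    normal = frame[frame["adverse"] == 0]
    for col in MARKERS:
        out.append(mann_whitney(
            normal[col].to_numpy(float), adverse[col].to_numpy(float),
            variable=labels[col],
        ))
    return out


#: Candidate predictors of the multivariable model (Doppler MoMs plus the
#: clinical confounders carried in the published model).
TABLE3_PREDICTORS = [
    "mca_mom", "ua_mom", "uta_mom", "cpr_mom", "upcr_mom",
    "ga_delivery", "birthweight_percentile", "preeclampsia",
]


def build_table3(frame: pd.DataFrame, alpha_remove: float = 0.10) -> StepwiseResult:
    x = frame[TABLE3_PREDICTORS].astype(float).to_numpy()
    y = frame["adverse"].to_numpy(int)
    return backward_stepwise_lr(x, y, names=TABLE3_PREDICTORS, alpha_remove=alpha_remove)


def build_table4(frame: pd.DataFrame):
    """Per-marker ROC summaries plus paired DeLong tests against the UPCR MoM."""
    y = frame["adverse"].to_numpy(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ConfigurationError("ROC analysis needs both outcome classes present")
    summaries: Dict[str, RocSummary] = {}
    oriented: Dict[str, np.ndarray] = {}
    for col, orientation in MARKERS.items():
        s = frame[col].to_numpy(float)
        summaries[col] = youden_summary(
            s, y, marker=col, higher_predicts_adverse=orientation == "higher")
        oriented[col] = s if orientation == "higher" else -s
    comparisons = {}
    for col in MARKERS:
        if col == REFERENCE_MARKER:
            continue
        comparisons[col] = delong_paired_test(oriented[col], oriented[REFERENCE_MARKER], y)
    return summaries, comparisons


def run_pipeline(
    config: SimConfig | str | Path | None = None,
    out_dir: str | Path | None = None,
    cohort: Cohort | None = None,
    quiet: bool = False,
) -> AnalysisReport:
    """Run the full analysis; optionally write CSV/JSON artifacts to ``out_dir``.

    ``config`` may be a :class:`SimConfig`, a YAML path, or None for the
    default study conditions.  Pass ``cohort`` to analyze an existing
    cohort instead of simulating one.
    """
    if not quiet:
        logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    if isinstance(config, (str, Path)):
        config = SimConfig.from_yaml(config)
    if config is None:
        config = SimConfig()
    config.validate()

    if cohort is None:
        cohort = generate_cohort(config)
        log.info("simulate: %d records recruited (seed=%d)", len(cohort.records), config.seed)
    frame = build_analysis_frame(cohort)
    ledger = frame.attrs["ledger"]
    n_adverse = int(frame["adverse"].sum())
    log.info("exclusion: %d analyzed, ledger=%s", len(frame), ledger)
    if n_adverse == 0 or n_adverse == len(frame):
        raise ConfigurationError(
            "analysis needs both outcome groups; got "
            f"{n_adverse} adverse of {len(frame)} analyzed"
        )

    table1 = build_table1(frame, seed=config.seed)
    table2 = build_table2(frame)
    table3 = build_table3(frame)
    table4, table4_vs = build_table4(frame)
    log.info("tables built: %d markers in the ROC table", len(table4))

    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    report = AnalysisReport(
        n_recruited=frame.attrs["n_recruited"],
        n_analyzed=len(frame),
        n_adverse=n_adverse,
        ledger=ledger,
        table1=table1,
        table2=table2,
        table3_full=table3.initial,
        table3_stepwise=table3,
        table4=table4,
        table4_vs_reference=table4_vs,
        provenance={
            "seed": str(config.seed),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "version": __version__,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(cohort, out_dir / "cohort.csv")
        frame.to_csv(out_dir / "analysis.csv", index=False)
        emit_tables(report, out_dir)
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("artifacts written to %s", out_dir)
    return report


# ---------------------------------------------------------------------------
# serialization


def _gc_row(gc: GroupComparison) -> dict:
    def fmt(side):
        if "mean" in side:
            return f"{side['mean']:.2f} +/- {side['sd']:.2f}"
        return f"{side['count']} ({side['pct']:.1f})"

    return {
        "variable": gc.variable,
        "normal_outcome": fmt(gc.group_a),
        "adverse_outcome": fmt(gc.group_b),
        "test": gc.test,
        "statistic": None if np.isnan(gc.statistic) else round(gc.statistic, 4),
        "p": round(gc.p, 4),
    }


def _fit_rows(fit: LogisticFit) -> List[dict]:
    lo, hi = fit.ci
    rows = []
    for j, name in enumerate(fit.names):
        rows.append({
            "variable": name,
            "B": round(float(fit.beta[j]), 4),
            "SE": round(float(fit.se[j]), 4),
            "aOR": round(float(fit.aor[j]), 4),
            "ci_low": round(float(lo[j]), 4),
            "ci_high": round(float(hi[j]), 4),
            "p": round(float(fit.wald_p[j]), 4),
        })
    return rows


def _roc_row(s: RocSummary, comparison: Optional[Dict[str, float]]) -> dict:
    row = {
        "marker": s.marker,
        "orientation": s.orientation,
        "auc": round(s.auc, 4),
        "auc_ci_low": round(s.auc_ci[0], 4),
        "auc_ci_high": round(s.auc_ci[1], 4),
        "youden_j": round(s.youden_j, 4),
        "sensitivity_pct": round(100 * s.sensitivity, 1),
        "sensitivity_ci": f"{100 * s.sensitivity_ci[0]:.1f}-{100 * s.sensitivity_ci[1]:.1f}",
        "specificity_pct": round(100 * s.specificity, 1),
        "specificity_ci": f"{100 * s.specificity_ci[0]:.1f}-{100 * s.specificity_ci[1]:.1f}",
        "ppv_pct": round(100 * s.ppv, 1),
        "ppv_ci": f"{100 * s.ppv_ci[0]:.1f}-{100 * s.ppv_ci[1]:.1f}",
        "npv_pct": round(100 * s.npv, 1),
        "npv_ci": f"{100 * s.npv_ci[0]:.1f}-{100 * s.npv_ci[1]:.1f}",
        "prevalence": round(s.prevalence, 4),
    }
    if comparison is not None:
        row["p_vs_upcr"] = round(comparison["p"], 4)
        row["delta_auc_vs_upcr"] = round(comparison["delta_auc"], 4)
    return row


def report_to_dict(report: AnalysisReport) -> dict:
    """Versioned JSON-ready dict (full precision for the key quantities)."""
    return {
        "schema": "upcr-report/1",
        "counts": {
            "recruited": report.n_recruited,
            "analyzed": report.n_analyzed,
            "adverse": report.n_adverse,
            "ledger": report.ledger,
        },
        "table1": [_gc_row(g) for g in report.table1],
        "table2": [_gc_row(g) for g in report.table2],
        "table3": {
            "full_model": _fit_rows(report.table3_full),
            "final_model": _fit_rows(report.table3_stepwise.final),
            "removal_trace": [
                {"removed": name, "p": round(p, 6)} for name, p in report.table3_stepwise.trace
            ],
        },
        "table4": {
            "markers": [
                _roc_row(report.table4[m], report.table4_vs_reference.get(m))
                for m in report.table4
            ],
        },
        "aucs_full_precision": {m: report.table4[m].auc for m in report.table4},
        "provenance": report.provenance,
    }


def emit_tables(report: AnalysisReport, out_dir) -> List[Path]:
    """Write the four per-table CSV files; idempotent."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    d = report_to_dict(report)
    for name, rows in (
        ("table1", d["table1"]),
        ("table2", d["table2"]),
        ("table3", d["table3"]["full_model"] + [{"variable": "--- final model ---"}]
         + d["table3"]["final_model"]),
        ("table4", d["table4"]["markers"]),
    ):
        path = out_dir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        paths.append(path)
    return paths
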