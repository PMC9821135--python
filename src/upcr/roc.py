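"""ROC construction, AUC estimation, DeLong inference, and Youden cutoffs.

The empirical AUC is the tie-adjusted Mann-Whitney probability that a
marker value from the adverse group exceeds one from the normal group
(ties count one half).  DeLong's structural-component estimator supplies
the AUC variance, Wald confidence intervals, and the paired z-test for
comparing two markers measured on the same subjects.  The Youden-optimal
cutoff maximises J = sensitivity + specificity - 1 over midpoints between
consecutive distinct scores; sensitivity/specificity and the predictive
values carry exact (Clopper-Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be 1-D arrays of equal length")
    if set(np.unique(y).tolist()) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if not ((y == 1).any() and (y == 0).any()):
        raise ValidationError("both outcome classes must be present")
    return s, y.astype(int)


def empirical_auc(scores, labels) -> float:
    """Tie-adjusted empirical AUC (Mann-Whitney formulation).

    Equals U / (n0 * n1) with ties counted one half, which is also the
    trapezoidal area under the empirical ROC curve.
    """
    s, y = _check_scores_labels(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    # midrank formulation: O(n log n)
    ranks = sps.rankdata(s)
    r1 = ranks[y == 1].sum()
    n1, n0 = pos.size, neg.size
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def binormal_auc(mu0: float, sd0: float, mu1: float, sd1: float) -> float:
    """Closed-form AUC when both groups are Gaussian: Phi(dmu / sqrt(sd0^2+sd1^2))."""
    if sd0 <= 0 or sd1 <= 0:
        raise ValidationError("group standard deviations must be positive")
    return float(sps.norm.cdf((mu1 - mu0) / math.hypot(sd0, sd1)))


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r, neg_r = _midrank(pos), _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def delong_variance(scores, labels) -> Tuple[float, float]:
    """(AUC, DeLong variance) for a single marker."""
    s, y = _check_scores_labels(scores, labels)
    auc, v10, v01 = _delong_components(s, y)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    return auc, float(var)


def delong_ci(scores, labels, level: float = 0.95) -> Dict[str, float]:
    """AUC with a DeLong Wald confidence interval truncated to [0, 1]."""
    if not 0 < level < 1:
        raise ValidationError("confidence level must lie in (0, 1)")
    s, y = _check_scores_labels(scores, labels)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValidationError("DeLong CI needs at least two subjects per class")
    auc, var = delong_variance(s, y)
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    half = z * math.sqrt(var)
    return {
        "auc": auc,
        "var": var,
        "ci_low": max(0.0, auc - half),
        "ci_high": min(1.0, auc + half),
        "degenerate": var == 0.0,
    }


def delong_paired_test(scores_a, scores_b, labels) -> Dict[str, float]:
    """Paired DeLong z-test for the AUC difference of two markers
    measured on the same subjects; two-sided p."""
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValidationError("paired markers must have the same length")
    sa, y = _check_scores_labels(sa, labels)
    sb, _ = _check_scores_labels(sb, labels)
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    m, n = v10a.size, v01a.size
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = 0.0
    if m > 1:
        var += d10.var(ddof=1) / m
    if n > 1:
        var += d01.var(ddof=1) / n
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else math.copysign(math.inf, delta)
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / math.sqrt(var)
        p = 2.0 * float(sps.norm.sf(abs(z)))
    return {"delta_auc": float(delta), "auc_a": auc_a, "auc_b": auc_b,
            "z": float(z), "p": min(p, 1.0), "var": float(var)}


# ---------------------------------------------------------------------------
# ROC curve, Youden cutoff, predictive values


@dataclass
class RocCurve:
    """Empirical ROC: candidate cutoffs with sensitivity/specificity arrays.

    A subject is called positive when its (oriented) score exceeds the
    cutoff; cutoffs are midpoints between consecutive distinct scores plus
    -inf/+inf sentinels, so the endpoints (1,1) and (0,0) are always present.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    higher_predicts_adverse: bool


def roc_curve(scores, labels, higher_predicts_adverse: bool = True) -> RocCurve:
    s, y = _check_scores_labels(scores, labels)
    if not higher_predicts_adverse:
        s = -s
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    pos, neg = s[y == 1], s[y == 0]
    sens = np.array([(pos > c).mean() for c in cutoffs])
    spec = np.array([(neg <= c).mean() for c in cutoffs])
    return RocCurve(cutoffs=cutoffs, sensitivity=sens, specificity=spec,
                    higher_predicts_adverse=higher_predicts_adverse)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if not 0 <= k <= n or n <= 0:
        raise ValidationError("need 0 <= k <= n with n > 0")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


@dataclass
class RocSummary:
    """Marker performance at the Youden-optimal cutoff."""

    marker: str
    auc: float
    auc_ci: Tuple[float, float]
    auc_var: float
    cutoff: float
    youden_j: float
    orientation: str  # 'higher' or 'lower' = which direction predicts adverse
    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    ppv: float
    ppv_ci: Tuple[float, float]
    npv: float
    npv_ci: Tuple[float, float]
    prevalence: float
    counts: Dict[str, int] = field(default_factory=dict)


def youden_summary(
    scores,
    labels,
    marker: str = "",
    higher_predicts_adverse: Optional[bool] = None,
    level: float = 0.95,
) -> RocSummary:
    """Full marker summary at the Youden-optimal cutoff.

    If ``higher_predicts_adverse`` is None the marker is oriented so the
    AUC is at least 0.5 and the orientation is recorded.  Cutoff ties on
    J are broken toward the cutoff with the higher sensitivity (then the
    lower cutoff), which is deterministic.
    """
    s, y = _check_scores_labels(scores, labels)
    if higher_predicts_adverse is None:
        higher_predicts_adverse = empirical_auc(s, y) >= 0.5
    oriented = s if higher_predicts_adverse else -s

    curve = roc_curve(oriented, y, higher_predicts_adverse=True)
    j = curve.sensitivity + curve.specificity - 1.0
    order = sorted(
        range(curve.cutoffs.size),
        key=lambda i: (-j[i], -curve.sensitivity[i], curve.cutoffs[i]),
    )
    best = order[0]
    cutoff = float(curve.cutoffs[best])

    pred_pos = oriented > cutoff
    tp = int(np.sum(pred_pos & (y == 1)))
    fn = int(np.sum(~pred_pos & (y == 1)))
    fp = int(np.sum(pred_pos & (y == 0)))
    tn = int(np.sum(~pred_pos & (y == 0)))
    n1, n0 = tp + fn, fp + tn

    ci = delong_ci(oriented, y, level=level)
    sens = tp / n1
    spec = tn / n0
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return RocSummary(
        marker=marker,
        auc=ci["auc"], auc_ci=(ci["ci_low"], ci["ci_high"]), auc_var=ci["var"],
        cutoff=cutoff, youden_j=float(j[best]),
        orientation="higher" if higher_predicts_adverse else "lower",
        sensitivity=sens, sensitivity_ci=clopper_pearson(tp, n1, level),
        specificity=spec, specificity_ci=clopper_pearson(tn, n0, level),
        ppv=ppv, ppv_ci=clopper_pearson(tp, tp + fp, level) if tp + fp else (float("nan"),) * 2,
        npv=npv, npv_ci=clopper_pearson(tn, tn + fn, level) if tn + fn else (float("nan"),) * 2,
        prevalence=n1 / (n1 + n0),
        counts={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )
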