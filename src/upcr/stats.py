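"""From-scratch univariable comparisons and the Cohen kappa agreement statistic.

Only distribution tails/quantiles are delegated to ``scipy.stats``
(Student t, chi-square, normal); the statistics themselves — Welch t with
optional seeded bootstrap, Mann-Whitney U with exact small-sample
enumeration and tie-corrected normal approximation, Pearson chi-square for
2x2 tables with an optional exact (permutation) p, Fisher's exact test,
and Cohen's kappa — are implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: Pooled-sample threshold below which the Mann-Whitney p is computed by
#: exact enumeration of all label assignments.
EXACT_MW_LIMIT = 12


@dataclass
class GroupComparison:
    """Result of one between-group comparison for the report tables."""

    variable: str
    group_a: Dict[str, float]
    group_b: Dict[str, float]
    test: str
    statistic: float
    p: float
    flags: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


def _summary(sample: np.ndarray) -> Dict[str, float]:
    return {"n": int(sample.size), "mean": float(sample.mean()),
            "sd": float(sample.std(ddof=1)) if sample.size > 1 else 0.0}


def welch_t(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    bootstrap: Optional[int] = None,
    seed: Optional[int] = None,
    variable: str = "",
) -> GroupComparison:
    """Two-sided Welch t-test; optional seeded bootstrap p.

    The analytic p uses the Welch statistic with Satterthwaite degrees of
    freedom.  When ``bootstrap`` is given, the p-value is instead taken
    from ``bootstrap`` resamples under the mean-shifted (centered) null:
    both samples are translated to the pooled grand mean and resampled
    with replacement within group; p is the fraction of resampled |t*|
    at or above the observed |t| (add-one correction).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("welch_t needs two finite samples of size >= 2")

    va, vb = a.var(ddof=1), b.var(ddof=1)
    flags = {}
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
        flags["degenerate_zero_variance"] = True
        return GroupComparison(variable, _summary(a), _summary(b),
                               "welch_t", stat, p, flags)

    se2 = va / a.size + vb / b.size
    stat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1))
    p = 2.0 * float(sps.t.sf(abs(stat), df))
    test = "welch_t"

    if bootstrap is not None:
        if bootstrap < 1:
            raise ValidationError("bootstrap iteration count must be >= 1")
        rng = np.random.default_rng(seed)
        grand = np.concatenate([a, b]).mean()
        a0, b0 = a - a.mean() + grand, b - b.mean() + grand
        ra = a0[rng.integers(0, a.size, size=(bootstrap, a.size))]
        rb = b0[rng.integers(0, b.size, size=(bootstrap, b.size))]
        va_s, vb_s = ra.var(axis=1, ddof=1), rb.var(axis=1, ddof=1)
        se2_s = va_s / a.size + vb_s / b.size
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = (ra.mean(axis=1) - rb.mean(axis=1)) / np.sqrt(se2_s)
        t_star = t_star[np.isfinite(t_star)]
        p = (1.0 + float(np.sum(np.abs(t_star) >= abs(stat)))) / (t_star.size + 1.0)
        test = "student_t_bootstrap"

    return GroupComparison(variable, _summary(a), _summary(b), test, float(stat), float(p), flags)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for 'a over b' with ties counted one-half."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(sample_a, sample_b, variable: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of label assignments when the pooled size
    is at most 12 (two-sidedness measured as distance of U from its null
    mean); otherwise the tie-corrected normal approximation without
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("mann_whitney needs both samples non-empty")
    na, nb = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = na * nb / 2.0

    if na + nb <= EXACT_MW_LIMIT:
        pooled = np.concatenate([a, b])
        idx = range(na + nb)
        total = 0
        hits = 0
        d_obs = abs(u_obs - mu)
        for combo in itertools.combinations(idx, na):
            mask = np.zeros(na + nb, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                hits += 1
        p = hits / total
        test = "mann_whitney_exact"
    else:
        n = na + nb
        pooled = np.concatenate([a, b])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts ** 3 - counts)) / (n * (n - 1))
        var = na * nb / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u_obs - mu) / math.sqrt(var)
            p = 2.0 * float(sps.norm.sf(abs(z)))
        test = "mann_whitney"

    return GroupComparison(variable, _summary(a), _summary(b), test, u_obs, min(p, 1.0))


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValidationError("table entries must be non-negative integers")
    return t.astype(np.int64)


def _chi2_stat(t: np.ndarray, yates: bool = False) -> float:
    n = t.sum()
    r1, r2 = t[0].sum(), t[1].sum()
    c1, c2 = t[:, 0].sum(), t[:, 1].sum()
    det = abs(float(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]))
    if yates:
        det = max(det - n / 2.0, 0.0)
    return n * det ** 2 / float(r1 * r2 * c1 * c2)


def pearson_chi2_2x2(table, exact: bool = False, yates: bool = False,
                     variable: str = "") -> GroupComparison:
    """Pearson chi-square for a 2x2 table (no continuity correction by default).

    ``exact=True`` computes the permutation p: the statistic's null
    distribution over all tables with the observed margins, weighted by
    the hypergeometric probability of each table.
    """
    t = _check_2x2(table)
    n = int(t.sum())
    r1, c1 = int(t[0].sum()), int(t[:, 0].sum())
    if min(r1, n - r1, c1, n - c1) == 0:
        raise ValidationError("both margins of the 2x2 table must be positive")
    stat = _chi2_stat(t, yates=yates)
    if exact:
        p = 0.0
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
            tk = np.array([[k, r1 - k], [c1 - k, n - r1 - c1 + k]])
            if _chi2_stat(tk, yates=yates) >= stat - 1e-12:
                p += _hypergeom_pmf(k, n, r1, c1)
        test = "pearson_chi2_exact"
    else:
        p = float(sps.chi2.sf(stat, df=1))
        test = "pearson_chi2"
    return GroupComparison(
        variable,
        {"n": r1, "count": int(t[0, 0]), "pct": 100.0 * t[0, 0] / r1},
        {"n": n - r1, "count": int(t[1, 0]), "pct": 100.0 * t[1, 0] / (n - r1)},
        test, float(stat), min(float(p), 1.0),
    )


def _hypergeom_pmf(k: int, n: int, r1: int, c1: int) -> float:
    return math.comb(r1, k) * math.comb(n - r1, c1 - k) / math.comb(n, c1)


def fisher_exact_2x2(table, variable: str = "") -> GroupComparison:
    """Fisher's exact test, two-sided by summing tables no more probable
    than the observed one under the hypergeometric null."""
    t = _check_2x2(table)
    n = int(t.sum())
    r1, c1 = int(t[0].sum()), int(t[:, 0].sum())
    if n == 0:
        raise ValidationError("empty table")
    if min(r1, n - r1, c1, n - c1) == 0:
        p = 1.0  # degenerate margin: only one table is possible
    else:
        p_obs = _hypergeom_pmf(int(t[0, 0]), n, r1, c1)
        p = sum(
            pk for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if (pk := _hypergeom_pmf(k, n, r1, c1)) <= p_obs * (1.0 + 1e-9)
        )
    return GroupComparison(
        variable,
        {"n": max(r1, 1), "count": int(t[0, 0]), "pct": 100.0 * t[0, 0] / r1 if r1 else 0.0},
        {"n": max(n - r1, 1), "count": int(t[1, 0]),
         "pct": 100.0 * t[1, 0] / (n - r1) if n - r1 else 0.0},
        "fisher_exact", float("nan"), min(float(p), 1.0),
    )


@dataclass
class AgreementTable:
    """Square rater-by-rater cross-tabulation with chance-corrected agreement."""

    table: np.ndarray
    p_observed: float
    p_expected: float
    kappa: float


def cohens_kappa(table) -> AgreementTable:
    """Cohen's kappa for a square cross-tabulation of two raters' calls."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValidationError("agreement table must be square")
    n = t.sum()
    if n <= 0:
        raise ValidationError("agreement table must contain at least one observation")
    if np.any(t < 0):
        raise ValidationError("agreement table entries must be non-negative")
    p = t / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    kappa = 1.0 if p_e == 1.0 and p_o == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementTable(table=t, p_observed=p_o, p_expected=p_e, kappa=float(kappa))
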