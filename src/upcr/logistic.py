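"""Binary logistic regression by IRLS, with Wald inference, likelihood-ratio
tests, and backward-stepwise (likelihood-ratio) variable selection.

The fitter is a plain Newton / iteratively-reweighted-least-squares
maximum-likelihood routine with step halving; standard errors come from
the inverse observed information, Wald confidence intervals from
exp(B +/- z * SE).  Quasi-separation (|B| > 15 on any coefficient) and
non-convergence are flagged rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

MAX_ITER = 50
GRAD_TOL = 1e-8
SEPARATION_BOUND = 15.0
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class LogisticFit:
    """Maximum-likelihood fit of a binary logistic model."""

    names: List[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    iterations: int
    n_obs: int
    separation: bool
    has_intercept: bool

    @property
    def aor(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.exp(self.beta - Z_95 * self.se)
        hi = np.exp(self.beta + Z_95 * self.se)
        return lo, hi

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, np.inf)
        return 2.0 * sps.norm.sf(np.abs(z))

    def term_names(self) -> List[str]:
        """Predictor names excluding the intercept."""
        return [n for n in self.names if n != "(intercept)"]


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # Numerically stable: sum y*eta - log(1 + exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _find_collinear(x: np.ndarray, names: Sequence[str]) -> List[str]:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[j] for j in range(len(names)) if j < diag.size and diag[j] <= tol]


def fit_logistic_irls(
    design: np.ndarray,
    outcome: Sequence[int],
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
) -> LogisticFit:
    """Fit a binary logistic regression by Newton/IRLS.

    ``design`` is the n x p predictor matrix (without intercept unless
    ``add_intercept=False``).  Iterates until the gradient infinity-norm
    drops below 1e-8 or 50 iterations; rank-deficient designs raise a
    :class:`ValidationError` naming the collinear columns.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if y.shape[0] != x.shape[0]:
        raise ValidationError("design and outcome lengths differ")
    if names is None:
        names = [f"x{j}" for j in range(x.shape[1])]
    names = list(names)
    if len(names) != x.shape[1]:
        raise ValidationError("one name per design column required")
    if add_intercept:
        if any(np.ptp(x[:, j]) == 0 for j in range(x.shape[1])):
            raise ValidationError("constant column in design besides the intercept")
        x = np.column_stack([np.ones(x.shape[0]), x])
        names = ["(intercept)"] + names
    n, p = x.shape
    if n <= p:
        raise ValidationError(f"need more observations ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(x) < p:
        collinear = _find_collinear(x, names)
        raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")

    beta = np.zeros(p)
    eta = x @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - mu)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving guards against overshoot near separation
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik(y, x @ cand)
            if ll_new >= ll - 1e-12:
                beta, ll, eta = cand, ll_new, x @ cand
                break
            scale *= 0.5
        else:
            break

    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    separation = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    return LogisticFit(
        names=names, beta=beta, se=se, loglik=ll,
        converged=converged and not separation,
        iterations=it, n_obs=n, separation=separation,
        has_intercept=add_intercept,
    )


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> Tuple[float, int, float]:
    """Likelihood-ratio test of nested logistic fits: returns (G, df, p)."""
    if full.n_obs != reduced.n_obs:
        raise ValidationError("models fit on different numbers of observations")
    if not set(reduced.names) <= set(full.names):
        raise ValidationError("reduced model's predictors are not a subset of the full model's")
    df = len(full.names) - len(reduced.names)
    if df < 0:
        raise ValidationError("reduced model has more parameters than full model")
    g = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(g, df=df))
    return g, df, p


@dataclass
class StepwiseResult:
    """Final model plus the removal trace of backward-stepwise selection."""

    final: LogisticFit
    initial: LogisticFit
    trace: List[Tuple[str, float]] = field(default_factory=list)
    term_p: dict = field(default_factory=dict)


def backward_stepwise_lr(
    design: np.ndarray,
    outcome: Sequence[int],
    names: Sequence[str],
    alpha_remove: float = 0.10,
) -> StepwiseResult:
    """Backward-stepwise selection on single-term likelihood-ratio tests.

    Starting from the full model, repeatedly drop the term with the
    largest LR-test p-value exceeding ``alpha_remove`` (ties broken by
    design-column order); stop when every remaining term has p at or
    below the threshold.  ``alpha_remove >= 1`` degenerates to removing
    every term down to the intercept.
    """
    if alpha_remove <= 0:
        raise ValidationError("alpha_remove must be positive")
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    names = list(names)
    y = np.asarray(outcome, dtype=float)

    current = list(range(x.shape[1]))
    initial = fit_logistic_irls(x, y, names=names)
    fit = initial
    trace: List[Tuple[str, float]] = []

    while current:
        term_p = {}
        for j in current:
            keep = [k for k in current if k != j]
            if keep:
                reduced = fit_logistic_irls(x[:, keep], y, names=[names[k] for k in keep])
            else:
                reduced = fit_logistic_irls(np.zeros((x.shape[0], 0)), y,
                                            names=[], add_intercept=True)
            _, _, p = likelihood_ratio_test(fit, reduced)
            term_p[j] = p
        worst = max(current, key=lambda j: (term_p[j], -j))  # ties -> earliest column
        if term_p[worst] > alpha_remove or alpha_remove >= 1.0:
            trace.append((names[worst], term_p[worst]))
            current = [k for k in current if k != worst]
            if current:
                fit = fit_logistic_irls(x[:, current], y, names=[names[k] for k in current])
            else:
                fit = fit_logistic_irls(np.zeros((x.shape[0], 0)), y, names=[], add_intercept=True)
        else:
            break

    final_term_p = {names[j]: term_p[j] for j in current} if current else {}
    return StepwiseResult(final=fit, initial=initial, trace=trace, term_p=final_term_p)
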