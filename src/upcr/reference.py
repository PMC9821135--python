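"""Gestational-age reference medians for Doppler indices.

Pulsatility indices fall (UA, MCA) or stay low and flat (UtA) across the
late third trimester, so raw values are standardised as multiples of the
gestational-age-specific median (MoM) before any between-group comparison.
The curves shipped here are piecewise-linear in gestational age over the
late-onset window [32, 37] weeks, with magnitudes typical of published
obstetric reference ranges.  The same curves are used by the cohort
simulator and the analysis, so a healthy pregnancy has MoM ~ 1 by
construction.  All knots and values are plain data and can be replaced
wholesale for a different reference population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import DomainError, ValidationError

GA_MIN = 32.0
GA_MAX = 37.0


@dataclass(frozen=True)
class ReferenceCurve:
    """Median of one index as a piecewise-linear function of gestational age.

    Parameters
    ----------
    ga_knots : strictly increasing gestational ages (decimal weeks) whose
        span must cover [32, 37].
    medians : positive median index value at each knot.
    """

    ga_knots: Tuple[float, ...]
    medians: Tuple[float, ...]

    def __post_init__(self) -> None:
        knots = np.asarray(self.ga_knots, dtype=float)
        meds = np.asarray(self.medians, dtype=float)
        if knots.size != meds.size or knots.size < 2:
            raise ValidationError("curve needs >= 2 (knot, median) pairs of equal length")
        if not np.all(np.diff(knots) > 0):
            raise ValidationError("ga_knots must be strictly increasing")
        if not np.all(meds > 0):
            raise ValidationError("all medians must be positive")
        if knots[0] > GA_MIN or knots[-1] < GA_MAX:
            raise ValidationError(f"curve domain must cover [{GA_MIN}, {GA_MAX}] weeks")

    def median_at(self, ga_weeks) -> float | np.ndarray:
        """Linear interpolation of the median at ``ga_weeks``.

        Raises
        ------
        DomainError
            If any gestational age lies outside [32, 37] weeks.
        """
        ga = np.asarray(ga_weeks, dtype=float)
        if np.any(ga < GA_MIN) or np.any(ga > GA_MAX):
            raise DomainError(
                f"gestational age {ga_weeks!r} outside the reference domain "
                f"[{GA_MIN}, {GA_MAX}] weeks"
            )
        out = np.interp(ga, self.ga_knots, self.medians)
        return float(out) if np.isscalar(ga_weeks) else out


@dataclass(frozen=True)
class ReferenceCurves:
    """Median curves for the three insonated vessels and the two ratios."""

    ua: ReferenceCurve
    mca: ReferenceCurve
    uta: ReferenceCurve
    cpr: ReferenceCurve
    upcr: ReferenceCurve

    def curve(self, name: str) -> ReferenceCurve:
        try:
            return getattr(self, name)
        except AttributeError:
            raise ValidationError(f"unknown index {name!r}") from None


_GA_KNOTS = (32.0, 33.0, 34.0, 35.0, 36.0, 37.0)
# Vessel medians: UA PI declines slowly, MCA PI declines from its
# mid-third-trimester peak, UtA PI is flat and low at term.
_UA_MED = (0.97, 0.95, 0.93, 0.91, 0.89, 0.87)
_MCA_MED = (1.95, 1.92, 1.86, 1.78, 1.68, 1.56)
_UTA_MED = (0.66, 0.65, 0.64, 0.64, 0.63, 0.62)


def _ratio_knots(num, den):
    return tuple(n / d for n, d in zip(num, den))


_DEFAULT = ReferenceCurves(
    ua=ReferenceCurve(_GA_KNOTS, _UA_MED),
    mca=ReferenceCurve(_GA_KNOTS, _MCA_MED),
    uta=ReferenceCurve(_GA_KNOTS, _UTA_MED),
    # Ratio medians are derived from the vessel medians at the same knots so
    # the two standardisations (MoM of ratio vs ratio of MoMs) stay coherent.
    cpr=ReferenceCurve(_GA_KNOTS, _ratio_knots(_MCA_MED, _UA_MED)),
    upcr=ReferenceCurve(
        _GA_KNOTS,
        tuple((a + u) / m for a, u, m in zip(_UA_MED, _UTA_MED, _MCA_MED)),
    ),
)


def default_reference_curves() -> ReferenceCurves:
    """Return the shipped default curves (the same object on every call)."""
    return _DEFAULT
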