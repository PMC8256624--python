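"""Four-parameter sigmoidal Emax curve for binary outcomes.

The event probability at (positive) dose-level ``x`` is

    p(x) = p_lo + (p_hi - p_lo) * x**hill / (ed50**hill + x**hill)

where ``p_lo`` and ``p_hi`` are the floor and ceiling probabilities (the
event probabilities approached at zero and infinite dose), ``ed50`` is the
dose-level at which the curve sits halfway between floor and ceiling, and
``hill`` controls steepness.  ``p_hi < p_lo`` encodes a decreasing curve;
``p_lo == p_hi`` a flat one.  With ``p_lo = 0`` and ``p_hi = 1`` the curve
reduces to a logistic function of ``hill * (log x - log ed50)``, so logit
regression is the special case in which the event probability is forced to
approach 1 at high dose.

The curve-height statistic summarising monotonicity is the fitted
probability at the highest investigated level minus that at the lowest;
positive heights mean the event becomes more likely as dose increases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .series import AnalysisSeries

__all__ = ["EmaxParams", "CurveHeight", "emax_prob", "log_likelihood", "curve_height"]


@dataclass(frozen=True)
class EmaxParams:
    """Parameters of the four-parameter binary-outcome Emax curve.

    Attributes
    ----------
    p_lo : float
        Floor event probability (approached as dose -> 0), in [0, 1].
    p_hi : float
        Ceiling event probability (approached as dose -> inf), in [0, 1].
        May be below ``p_lo``, giving a decreasing curve.
    ed50 : float
        Dose-level at which the curve is halfway between floor and
        ceiling; strictly positive, on the ordinal level scale.
    hill : float
        Steepness (Hill coefficient); strictly positive.
    """

    p_lo: float
    p_hi: float
    ed50: float
    hill: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lo <= 1.0):
            raise ValueError(f"p_lo must be in [0, 1], got {self.p_lo}")
        if not (0.0 <= self.p_hi <= 1.0):
            raise ValueError(f"p_hi must be in [0, 1], got {self.p_hi}")
        if not (np.isfinite(self.ed50) and self.ed50 > 0):
            raise ValueError(f"ed50 must be positive and finite, got {self.ed50}")
        if not (np.isfinite(self.hill) and self.hill > 0):
            raise ValueError(f"hill must be positive and finite, got {self.hill}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_lo, self.p_hi, self.ed50, self.hill], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "EmaxParams":
        p_lo, p_hi, ed50, hill = (float(v) for v in theta)
        return cls(p_lo=p_lo, p_hi=p_hi, ed50=ed50, hill=hill)


@dataclass(frozen=True)
class CurveHeight:
    """Curve height: fitted event probability at the highest dose-level
    minus that at the lowest.

    For maximum-likelihood fits ``mean`` is the plug-in point statistic and
    ``draws`` is None.  For Bayesian fits ``draws`` holds the draw-wise
    height distribution and ``mean`` / ``interval`` summarise it.
    """

    mean: float
    interval_lo: float
    interval_hi: float
    interval_level: float = 0.90
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        vals = [self.mean, self.interval_lo, self.interval_hi]
        if self.draws is not None:
            vals = vals + list(np.atleast_1d(self.draws))
        arr = np.asarray(vals, dtype=float)
        if np.any(arr < -1.0 - 1e-12) or np.any(arr > 1.0 + 1e-12):
            raise ValueError("curve heights must lie in [-1, 1]")


def _emax_core(p_lo, p_hi, ed50, hill, x):
    # computed on the log scale to keep x**hill finite for steep curves
    t = hill * (np.log(x) - np.log(ed50))
    frac = 1.0 / (1.0 + np.exp(-t))
    return p_lo + (p_hi - p_lo) * frac


def emax_prob(params: EmaxParams, x) -> np.ndarray | float:
    """Event probability at dose-level(s) ``x > 0``.

    Monotone in ``x`` with direction ``sign(p_hi - p_lo)``; equals
    ``(p_lo + p_hi) / 2`` at ``x = ed50``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("dose-level x must be positive and finite")
    out = _emax_core(params.p_lo, params.p_hi, params.ed50, params.hill, x)
    return float(out) if out.ndim == 0 else out


def log_likelihood(params: EmaxParams, series: "AnalysisSeries") -> float:
    """Binomial log-likelihood of an analysis series under the curve.

    The combinatorial constant is omitted (constant in the parameters).
    Returns ``-inf`` when a boundary probability (0 or 1) contradicts the
    observed counts.  Requires a fittable series (at least two levels).
    """
    if not series.fittable:
        raise ValueError(
            f"series {series.series_id!r} is not fittable (needs >= 2 dose-levels)"
        )
    levels = np.array([p.level for p in series.points], dtype=float)
    n = np.array([p.n for p in series.points], dtype=float)
    events = np.array([p.events for p in series.points], dtype=float)
    p = np.asarray(emax_prob(params, levels))
    return float(_binom_loglik(p, n, events))


def _binom_loglik(p, n, events):
    """Vectorised kernel: sum(events*log p + (n-events)*log(1-p)) with
    0*log 0 treated as 0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(events > 0, events * np.log(p), 0.0)
        term0 = np.where(n - events > 0, (n - events) * np.log1p(-p), 0.0)
    ll = np.sum(term1 + term0, axis=-1)
    return np.where(np.isnan(ll), -np.inf, ll)


def curve_height(params: EmaxParams, levels: Sequence[float]) -> float:
    """Probability at the highest level minus at the lowest; in [-1, 1]."""
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2:
        raise ValueError("curve height needs at least two dose-levels")
    lo, hi = float(np.min(levels)), float(np.max(levels))
    return float(emax_prob(params, hi) - emax_prob(params, lo))
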