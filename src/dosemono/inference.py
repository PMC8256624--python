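"""Fitting the binary-outcome Emax curve to an analysis series.

Two routes are provided.  Maximum likelihood (:func:`fit_mle`) maximises
the binomial likelihood from a deterministic lattice of starting points
and reports explicit failure flags — non-convergence, boundary estimates,
exploding standard errors — rather than raising, mirroring how ML fits
behave on the very small cohorts typical of dose-escalation trials.
Bayesian fitting (:func:`fit_bayes`) samples the posterior under uniform
priors on the floor and ceiling probabilities and weakly informative
priors on location and steepness; it returns a usable fit on every series,
including those with all-zero or all-event cells where the likelihood
alone is unbounded or flat.

:func:`posterior_from_grid` is a deterministic 4-D quadrature of the same
posterior used as an independent cross-check of the MCMC, and
:func:`prior_predictive` draws candidate curves from the prior alone to
show how little the priors constrain the curve shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .emax import CurveHeight, EmaxParams, _binom_loglik, emax_prob
from .series import AnalysisSeries

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "MLEConfig",
    "GridConfig",
    "MLEFit",
    "PosteriorFit",
    "fit_mle",
    "fit_bayes",
    "posterior_from_grid",
    "prior_predictive",
    "fitted_curve",
    "height_of_fit",
]

PARAM_NAMES = ("p_lo", "p_hi", "ed50", "hill")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the four curve parameters.

    Floor and ceiling probabilities get uniform priors on [0, 1]: every
    event probability at the lowest and highest dose is a priori equally
    likely.  The location (ED50) gets a log-normal prior centred at the
    middle dose-level with log-scale ``ed50_sigma``, and the steepness a
    half-normal with scale ``hill_sigma`` — enough spread to admit
    near-step curves over a single level span, but keeping estimation in
    the feasible region.
    """

    ed50_log_mu: float
    ed50_sigma: float = 1.0
    hill_sigma: float = 5.0

    @classmethod
    def default(cls, n_levels: int) -> "PriorSpec":
        if n_levels < 2:
            raise ValueError("priors are defined for series with >= 2 levels")
        return cls(ed50_log_mu=math.log((1.0 + n_levels) / 2.0))

    # log density of the (ed50, hill) part; the uniform asymptote part is
    # constant on its support.  Closed forms (up to constants) rather than
    # scipy frozen distributions: this sits in the MCMC inner loop.
    def log_density(self, ed50: np.ndarray, hill: np.ndarray) -> np.ndarray:
        z = (np.log(ed50) - self.ed50_log_mu) / self.ed50_sigma
        ld = -0.5 * z**2 - np.log(ed50)
        lh = -0.5 * (hill / self.hill_sigma) ** 2
        return ld + lh

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` joint parameter vectors (columns p_lo, p_hi, ed50, hill)."""
        p_lo = rng.uniform(0.0, 1.0, size)
        p_hi = rng.uniform(0.0, 1.0, size)
        ed50 = np.exp(rng.normal(self.ed50_log_mu, self.ed50_sigma, size))
        hill = np.abs(rng.normal(0.0, self.hill_sigma, size))
        return np.column_stack([p_lo, p_hi, ed50, hill])

    def ppf(self, u: np.ndarray, which: str) -> np.ndarray:
        """Quantile function of one marginal, used by the grid oracle."""
        if which in ("p_lo", "p_hi"):
            return u
        if which == "ed50":
            return stats.lognorm.ppf(u, s=self.ed50_sigma, scale=math.exp(self.ed50_log_mu))
        if which == "hill":
            return stats.halfnorm.ppf(u, scale=self.hill_sigma)
        raise KeyError(which)


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings for :func:`fit_bayes`."""

    walkers: int = 32
    warmup: int = 800
    draws_per_walker: int = 300
    min_draws: int = 1000
    interval_level: float = 0.90

    @property
    def total_draws(self) -> int:
        return self.walkers * self.draws_per_walker


@dataclass(frozen=True)
class MLEConfig:
    """Optimiser settings for :func:`fit_mle`."""

    se_threshold: float = 10.0
    ed50_bounds: tuple[float, float] = (1e-3, 100.0)
    hill_bounds: tuple[float, float] = (1e-2, 50.0)
    boundary_tol: float = 1e-4


@dataclass(frozen=True)
class GridConfig:
    """Quadrature settings for :func:`posterior_from_grid`."""

    resolution: int = 20
    min_resolution: int = 8
    interval_level: float = 0.90


@dataclass(frozen=True)
class MLEFit:
    """A maximum-likelihood fit with explicit failure flags."""

    params: EmaxParams
    std_errors: dict[str, float] | None
    loglik: float
    converged: bool
    failure_reason: str  # none | no_convergence | se_explosion | boundary
    series_id: str = ""

    def __post_init__(self) -> None:
        if self.failure_reason not in ("none", "no_convergence", "se_explosion", "boundary"):
            raise ValueError(f"unknown failure_reason {self.failure_reason!r}")
        if self.converged and self.failure_reason != "none":
            raise ValueError("converged fits cannot carry a failure reason")


@dataclass(frozen=True)
class PosteriorFit:
    """Posterior draws for one series with convergence diagnostics.

    ``draws`` is (S, 4) with columns p_lo, p_hi, ed50, hill; every row
    satisfies the parameter constraints.  Diagnostics are split-R-hat and
    bulk effective sample size per parameter (walkers treated as chains)
    plus the mean ensemble acceptance fraction.
    """

    draws: np.ndarray
    seed: int
    diagnostics: dict[str, float]
    interval_level: float = 0.90
    series_id: str = ""

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def param_draws(self, name: str) -> np.ndarray:
        return self.draws[:, PARAM_NAMES.index(name)]

    def posterior_mean_params(self) -> dict[str, float]:
        return {n: float(np.mean(self.draws[:, i])) for i, n in enumerate(PARAM_NAMES)}


# ---------------------------------------------------------------------------
# shared likelihood machinery


def _series_arrays(series: AnalysisSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    levels = np.array([p.level for p in series.points], dtype=float)
    n = np.array([p.n for p in series.points], dtype=float)
    events = np.array([p.events for p in series.points], dtype=float)
    return levels, n, events


def _loglik_theta(theta: np.ndarray, levels, n, events, clip: bool = False) -> np.ndarray:
    """Vectorised binomial log-likelihood over parameter rows (N, 4)."""
    theta = np.atleast_2d(theta)
    p_lo, p_hi, ed50, hill = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3], theta[:, 3:4]
    with np.errstate(over="ignore"):
        t = hill * (np.log(levels)[None, :] - np.log(ed50))
        frac = 1.0 / (1.0 + np.exp(-t))
    p = p_lo + (p_hi - p_lo) * frac
    if clip:
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return _binom_loglik(p, n[None, :], events[None, :])


def _require_fittable(series: AnalysisSeries) -> None:
    if not series.fittable:
        raise ValueError(
            f"series {series.series_id!r} has {series.n_levels} dose-level(s); "
            "fitting needs at least 2"
        )


# ---------------------------------------------------------------------------
# maximum likelihood


def fit_mle(series: AnalysisSeries, config: MLEConfig | None = None) -> MLEFit:
    """Maximise the binomial Emax likelihood from a deterministic lattice
    of starting points.

    Standard errors come from the observed information (finite-difference
    Hessian) when it is invertible.  Numerical failure never raises: the
    fit is returned with ``converged=False`` and a ``failure_reason`` of
    ``no_convergence`` (optimiser failure), ``boundary`` (estimate pinned
    to the parameter-space edge) or ``se_explosion`` (standard errors
    above the configured threshold, or a singular Hessian).
    """
    _require_fittable(series)
    cfg = config or MLEConfig()
    levels, n, events = _series_arrays(series)
    K = series.n_levels
    mid = (1.0 + K) / 2.0

    def negll(theta: np.ndarray) -> float:
        return -float(_loglik_theta(theta[None, :], levels, n, events, clip=True)[0])

    bounds = [(0.0, 1.0), (0.0, 1.0), cfg.ed50_bounds, cfg.hill_bounds]
    starts = [
        np.array([a, b, e, h])
        for a in (0.1, 0.5, 0.9)
        for b in (0.1, 0.5, 0.9)
        for e in (0.5 * mid, mid)
        for h in (1.0, 5.0)
    ]

    best = None
    any_success = False
    for x0 in starts:
        try:
            res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        except Exception:  # pragma: no cover - L-BFGS-B rarely raises
            continue
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or bool(res.success)

    if best is None or not np.isfinite(best.fun):
        params = EmaxParams(0.5, 0.5, mid, 1.0)
        return MLEFit(params, None, -np.inf, False, "no_convergence", series.series_id)

    theta = np.clip(best.x, [0, 0, cfg.ed50_bounds[0], cfg.hill_bounds[0]],
                    [1, 1, cfg.ed50_bounds[1], cfg.hill_bounds[1]])
    params = EmaxParams.from_array(theta)
    loglik = -float(best.fun)

    at_boundary = _boundary_flags(theta, bounds, cfg.boundary_tol)
    std_errors = _observed_info_se(negll, theta, bounds)

    if not any_success:
        reason = "no_convergence"
    elif any(at_boundary):
        reason = "boundary"
    elif std_errors is None or any(se > cfg.se_threshold for se in std_errors.values()):
        reason = "se_explosion"
    else:
        reason = "none"
    return MLEFit(params, std_errors, loglik, reason == "none", reason, series.series_id)


def _boundary_flags(theta, bounds, tol) -> list[bool]:
    flags = []
    for value, (lo, hi) in zip(theta, bounds):
        span = hi - lo
        flags.append(value - lo < tol * span or hi - value < tol * span)
    return flags


def _observed_info_se(negll, theta, bounds) -> dict[str, float] | None:
    from statsmodels.tools.numdiff import approx_hess2

    try:
        hess = approx_hess2(theta, negll)
        cov = np.linalg.inv(hess)
        var = np.diag(cov)
        if np.any(~np.isfinite(var)) or np.any(var <= 0):
            return None
        return dict(zip(PARAM_NAMES, np.sqrt(var)))
    except (np.linalg.LinAlgError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Bayesian sampling


def _log_posterior_factory(priors: PriorSpec, levels, n, events):
    """Log posterior in the sampling parameterisation
    (p_lo, p_hi, log ed50, log hill).

    Location and steepness are sampled on the log scale, where the
    posterior geometry is far better behaved than on the heavy-tailed
    natural scale; the prior densities carry the Jacobian of the
    transform (the log-normal ED50 prior becomes Gaussian in log ED50,
    the half-normal steepness prior gains a factor of hill).
    """

    def log_post(z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        p_lo, p_hi, log_ed50, log_hill = z.T
        ok = (
            (p_lo >= 0) & (p_lo <= 1) & (p_hi >= 0) & (p_hi <= 1)
            & np.isfinite(log_ed50) & (log_ed50 < 10.0)
            & np.isfinite(log_hill) & (log_hill < 6.0)
        )
        out = np.full(z.shape[0], -np.inf)
        if np.any(ok):
            sub = z[ok]
            hill = np.exp(sub[:, 3])
            theta = np.column_stack(
                [sub[:, 0], sub[:, 1], np.exp(sub[:, 2]), hill])
            ll = _loglik_theta(theta, levels, n, events)
            zz = (sub[:, 2] - priors.ed50_log_mu) / priors.ed50_sigma
            lp = (-0.5 * zz**2
                  - 0.5 * (hill / priors.hill_sigma) ** 2 + sub[:, 3])
            out[ok] = ll + lp
        return out

    return log_post


def fit_bayes(
    series: AnalysisSeries,
    priors: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorFit:
    """Sample the Emax posterior with an affine-invariant ensemble sampler.

    Reproducible given (seed, config): the same call yields bit-identical
    draws.  Pathological diagnostics are reported in
    :attr:`PosteriorFit.diagnostics`, never raised, so a usable fit comes
    back even for series where maximum likelihood fails (tiny cohorts,
    all-zero or all-event cells).
    """
    import emcee

    _require_fittable(series)
    cfg = config or SamplerConfig()
    pri = priors or PriorSpec.default(series.n_levels)
    levels, n, events = _series_arrays(series)
    log_post = _log_posterior_factory(pri, levels, n, events)

    rng = np.random.RandomState(seed & 0x7FFFFFFF)
    theta0 = pri.sample(np.random.default_rng(rng.randint(0, 2**31 - 1)), cfg.walkers)
    # starting positions strictly inside the support, then to sampling scale
    z0 = np.column_stack([
        np.clip(theta0[:, 0], 1e-3, 1 - 1e-3),
        np.clip(theta0[:, 1], 1e-3, 1 - 1e-3),
        np.log(np.clip(theta0[:, 2], 1e-3, None)),
        np.log(np.clip(theta0[:, 3], 1e-2, None)),
    ])

    moves = [(emcee.moves.DEMove(), 0.9), (emcee.moves.StretchMove(), 0.1)]
    sampler = emcee.EnsembleSampler(cfg.walkers, 4, log_post, vectorize=True, moves=moves)
    state = emcee.State(z0, random_state=rng.get_state())
    state = sampler.run_mcmc(state, cfg.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, cfg.draws_per_walker, progress=False)

    chain = sampler.get_chain().copy()  # (draws_per_walker, walkers, 4)
    chain[:, :, 2] = np.exp(chain[:, :, 2])
    chain[:, :, 3] = np.exp(chain[:, :, 3])
    draws = chain.reshape(-1, 4)
    if draws.shape[0] < cfg.min_draws:
        raise ValueError("sampler configuration yields fewer than min_draws draws")

    diagnostics = _ensemble_diagnostics(chain, float(np.mean(sampler.acceptance_fraction)))
    return PosteriorFit(
        draws=draws,
        seed=seed,
        diagnostics=diagnostics,
        interval_level=cfg.interval_level,
        series_id=series.series_id,
    )


def _ensemble_diagnostics(chain: np.ndarray, accept_frac: float) -> dict[str, float]:
    """Split-R-hat and bulk ESS per parameter, walkers treated as chains."""
    import warnings

    import arviz as az

    posterior = {
        name: np.moveaxis(chain[:, :, i], 0, 1)  # (chain, draw)
        for i, name in enumerate(PARAM_NAMES)
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=posterior)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diagnostics = {"accept_frac": accept_frac}
    for name in PARAM_NAMES:
        diagnostics[f"rhat_{name}"] = float(rhat[name].values)
        diagnostics[f"ess_{name}"] = float(ess[name].values)
    return diagnostics


# ---------------------------------------------------------------------------
# grid-quadrature oracle


def posterior_from_grid(
    series: AnalysisSeries,
    priors: PriorSpec | None = None,
    config: GridConfig | None = None,
) -> dict[str, float]:
    """Deterministic 4-D quadrature of the unnormalised posterior.

    The grid is laid out uniformly in each prior's quantile scale
    (mid-point rule), so node weights reduce to the likelihood alone.
    Returns posterior means of the parameters and mean/median/central
    interval of the curve height — an MCMC-free cross-check for
    :func:`fit_bayes`.
    """
    _require_fittable(series)
    cfg = config or GridConfig()
    if cfg.resolution < cfg.min_resolution:
        raise ValueError(
            f"grid resolution {cfg.resolution} below minimum {cfg.min_resolution}"
        )
    pri = priors or PriorSpec.default(series.n_levels)
    levels, n, events = _series_arrays(series)

    m = cfg.resolution
    u = (np.arange(m) + 0.5) / m
    axes = [pri.ppf(u, name) for name in PARAM_NAMES]
    grids = np.meshgrid(*axes, indexing="ij")
    theta = np.column_stack([g.ravel() for g in grids])

    logw = _loglik_theta(theta, levels, n, events)
    logw -= np.max(logw)
    w = np.exp(logw)
    w /= np.sum(w)

    lo, hi = float(np.min(levels)), float(np.max(levels))
    heights = _vector_heights(theta, lo, hi)

    alpha = 1.0 - cfg.interval_level
    summary = {f"mean_{name}": float(np.sum(w * theta[:, i]))
               for i, name in enumerate(PARAM_NAMES)}
    summary["height_mean"] = float(np.sum(w * heights))
    for q, key in ((alpha / 2, "height_lo"), (0.5, "height_median"), (1 - alpha / 2, "height_hi")):
        summary[key] = _weighted_quantile(heights, w, q)
    return summary


def _vector_heights(theta: np.ndarray, lo: float, hi: float) -> np.ndarray:
    p_lo, p_hi, ed50, hill = theta.T
    with np.errstate(over="ignore"):
        def at(x):
            t = hill * (math.log(x) - np.log(ed50))
            return p_lo + (p_hi - p_lo) / (1.0 + np.exp(-t))
        return at(hi) - at(lo)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    return float(np.interp(q, cum, values[order]))


# ---------------------------------------------------------------------------
# prior predictive


def prior_predictive(
    priors: PriorSpec,
    levels: Sequence[float],
    n_curves: int,
    seed: int = 0,
) -> np.ndarray:
    """Curves drawn from the prior alone, evaluated at ``levels``.

    Returns an (n_curves, len(levels)) array of event probabilities;
    reproducible by seed.  Used to verify the priors encode only modest
    information about curve shape.
    """
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    theta = priors.sample(rng, n_curves)
    theta[:, 3] = np.maximum(theta[:, 3], 1e-12)  # half-normal can draw 0
    p_lo, p_hi, ed50, hill = theta.T
    t = hill[:, None] * (np.log(levels)[None, :] - np.log(ed50)[:, None])
    return p_lo[:, None] + (p_hi - p_lo)[:, None] / (1.0 + np.exp(-t))


# ---------------------------------------------------------------------------
# fitted curves and heights


def fitted_curve(fit: MLEFit | PosteriorFit, levels: Sequence[float]) -> dict[str, np.ndarray]:
    """Per-level fitted probabilities.

    Maximum-likelihood fits give the plug-in curve; Bayesian fits the
    posterior-mean curve with a central credible band.  A failed MLE fit
    raises with a pointer to the Bayesian route.
    """
    levels = np.asarray(levels, dtype=float)
    if isinstance(fit, MLEFit):
        if not fit.converged:
            raise ValueError(
                f"MLE fit for series {fit.series_id!r} failed "
                f"({fit.failure_reason}); use fit_bayes for a usable curve"
            )
        return {"levels": levels, "mean": np.asarray(emax_prob(fit.params, levels))}
    curves = _draw_curves(fit.draws, levels)
    alpha = 1.0 - fit.interval_level
    return {
        "levels": levels,
        "mean": curves.mean(axis=0),
        "lo": np.quantile(curves, alpha / 2, axis=0),
        "hi": np.quantile(curves, 1 - alpha / 2, axis=0),
    }


def _draw_curves(draws: np.ndarray, levels: np.ndarray) -> np.ndarray:
    p_lo, p_hi, ed50, hill = draws.T
    with np.errstate(over="ignore"):
        t = hill[:, None] * (np.log(levels)[None, :] - np.log(ed50)[:, None])
        return p_lo[:, None] + (p_hi - p_lo)[:, None] / (1.0 + np.exp(-t))


def height_of_fit(fit: MLEFit | PosteriorFit, levels: Sequence[float]) -> CurveHeight:
    """Curve height of a fit: scalar for MLE, draw-wise distribution with
    mean and central interval for Bayes."""
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2:
        raise ValueError("curve height needs at least two dose-levels")
    lo, hi = float(np.min(levels)), float(np.max(levels))
    if isinstance(fit, MLEFit):
        if not fit.converged:
            raise ValueError(
                f"MLE fit for series {fit.series_id!r} failed "
                f"({fit.failure_reason}); use fit_bayes for a usable height"
            )
        value = float(emax_prob(fit.params, hi) - emax_prob(fit.params, lo))
        return CurveHeight(mean=value, interval_lo=value, interval_hi=value,
                           interval_level=float("nan"))
    heights = _vector_heights(fit.draws, lo, hi)
    alpha = 1.0 - fit.interval_level
    return CurveHeight(
        mean=float(np.mean(heights)),
        interval_lo=float(np.quantile(heights, alpha / 2)),
        interval_hi=float(np.quantile(heights, 1 - alpha / 2)),
        interval_level=fit.interval_level,
        draws=heights,
    )
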