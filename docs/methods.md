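# Methods

## The question and the data model

Dose-escalation (phase I) oncology trials are designed around two
monotonicity assumptions: that the probability of a dose-limiting
toxicity (DLT) rises with dose, and — implicitly, through the pursuit of
a maximum tolerable dose — that the probability of an objective response
(OR) does too. `dosemono` implements a pipeline for testing those
assumptions across a landscape of published trials, where each study
contributes a table of dose-levels with the number of patients evaluated
and the number of DLT and OR events at each.

A dose is a map from agent name to amount. Within a study, doses are
compared component-wise (product order): dose *a* is below dose *b* when
every agent's amount in *a* is at most that in *b*, strictly for at
least one agent; two doses that each exceed the other in one agent are
incomparable. Amounts are stored as given and never unit-converted;
comparability is only ever asserted within one study.

## Analysis series: chain decomposition of partially ordered dose sets

A dose-event curve can only be fit over doses that are fully orderable.
When a study's dose set is only partially ordered (combination
escalations), it is decomposed into fully ordered chains ("analysis
series") under these rules:

1. the longest emitted series is a maximum-length chain of the partial
   order;
2. every dose appears in at least one series;
3. a dose is shared between series only when the alternative is an
   orphan (a series of size one);
4. every series is inclusion-maximal — a series absorbs each dose
   comparable with all its members, because truncating a series would
   discard observed outcomes.

Among covers satisfying these rules the implementation minimises the
number of orphans, then the total number of repeated doses, then breaks
remaining ties by lexicographic order of dose labels, so output is
deterministic. The search is an exact branch-and-bound over the
inclusion-maximal chains, seeded with each maximum-length chain;
realistic dose sets (≤ ~12 doses) are solved instantly. Note that rule 4
is ranked above global repetition-minimisation: in a diamond
d1 < {d2, d3} < d4 the decomposition is (d1,d2,d4) + (d1,d3,d4), not
(d1,d2,d4) + (d3,d4), even though the latter repeats fewer doses.
Orphan series are emitted but flagged non-fittable and excluded from
curve fitting: a single dose carries no gradient information.

Within each series doses are re-indexed to ordinal levels 1..K, and the
ordinal level is the dose metric for all fitting. Combination doses have
no common scalar scale, and using the ordinal index makes curve heights
comparable across series. The "centralise at zero" transform used in
the curve panels is presentation-only and never enters fitting.

## The curve model

The event probability at level x > 0 is the four-parameter sigmoidal
Emax curve

    p(x) = p_lo + (p_hi − p_lo) · x^h / (ED50^h + x^h)

with floor `p_lo` ∈ [0,1], ceiling `p_hi` ∈ [0,1], location `ED50 > 0`
and steepness (Hill coefficient) `h > 0`. `p_hi < p_lo` encodes a
decreasing curve and `p_hi = p_lo` a flat one, so the model spans
rising, falling and dose-independent relationships. With `p_lo = 0`,
`p_hi = 1` the curve is exactly the logistic function of
h·(log x − log ED50) — the logit model is the special case in which the
event probability is forced to 1 at high dose, an assumption that is
defensible for toxicity but not for efficacy; the free ceiling is the
point of using Emax. Internally the curve is evaluated on the log scale
(a logistic of h·(log x − log ED50)) so that steep curves never
overflow.

The likelihood of a series is the product-binomial likelihood of the
per-level event counts, with the combinatorial constant omitted (it is
constant in the parameters, and omitting it keeps the ML and Bayesian
targets directly comparable).

The monotonicity statistic is the **curve height**: the fitted event
probability at the highest investigated level minus that at the lowest,
a number in [−1, 1]. Zero means no dose-event relationship over the
investigated range; the statistic deliberately measures the curve over
the range actually studied, not the asymptotes.

## Maximum-likelihood fitting and its failure modes

`fit_mle` maximises the likelihood with L-BFGS-B from a deterministic
lattice of 36 starting points (floor and ceiling in {0.1, 0.5, 0.9},
ED50 at half/full mid-level, steepness in {1, 5}), with bounds
p ∈ [0,1], ED50 ∈ [10⁻³, 100], h ∈ [10⁻², 50]. Standard errors come
from the finite-difference observed-information matrix
(statsmodels' numerical Hessian) when it is invertible. Failures are
flagged, never raised:

- `no_convergence` — no start converged;
- `boundary` — the estimate is pinned to the edge of the parameter
  space (relative tolerance 10⁻⁴), e.g. a ceiling of exactly 1 on the
  classic Emax ridge, or a floor of 0 when no events were seen;
- `se_explosion` — any standard error above 10 (on the probability /
  level scales), or a singular Hessian.

On trial-sized cohorts (3–6 patients per level) these failures are the
norm, not the exception — which is precisely why the Bayesian route
exists. Even on failed fits the *plug-in curve height* over the observed
range is often still identified (the ridge moves the asymptotes and
location together), but downstream reporting uses only converged ML
fits.

## Bayesian fitting

Priors: uniform on [0,1] for floor and ceiling — every event probability
at the lowest and highest dose equally likely a priori; log-normal on
ED50 centred at the middle level, log-scale σ = 1, so the half-maximum
point is expected within the investigated range but may sit outside it;
half-normal with scale 5 on the steepness, admitting near-step curves
over a single level span. The latter two are deliberately weak — their
job is only to keep estimation in the feasible region — and are
configurable through `PriorSpec`. `prior_predictive` draws candidate
curves from the priors alone; under the defaults the prior-mean event
probability is ~0.5 at every level with curves spread over the whole
unit band.

Sampling uses the emcee affine-invariant ensemble sampler, 32 walkers,
vectorised log-posterior, in the parameterisation
(p_lo, p_hi, log ED50, log h) with Jacobian-corrected priors — the log
scale removes the heavy right tails that cripple mixing on the natural
scale. Moves are differential-evolution (90%) plus stretch (10%).
The snooker variant was evaluated and rejected: on a multimodal
three-level series it produced a posterior-mean height of 0.42 where
three independent routes (grid quadrature, prior importance sampling,
and a plain random-walk Metropolis on the identical log-posterior) all
agreed on 0.187. Defaults are 800 warmup steps and 300 retained steps
per walker (9 600 draws). Draws are returned on the natural scale and
always satisfy the parameter constraints.

Reproducibility is bit-exact: the same (series, priors, config, seed)
yields identical draws. Diagnostics — split-R̂ and bulk effective sample
size per parameter with walkers treated as chains, plus the mean
acceptance fraction — are reported, never raised; walkers are correlated
so these R̂ values are an optimistic-leaning screen, which is why the
grid oracle below exists.

## The deterministic oracle

`posterior_from_grid` integrates the same unnormalised posterior by
quadrature on a 4-D grid laid out uniformly in each prior's quantile
scale (mid-point rule, 20 points per dimension = 160 000 nodes), where
node weights reduce to the likelihood alone. It is MCMC-free and
deterministic, and every Bayesian result in the acceptance suite is
checked against it (posterior-mean height agreement within 0.05; in
practice the mean absolute disagreement is ~0.01). The grid truncates
each prior's extreme 2.5% tail mass; on series that concentrate
posterior mass on near-step curves this costs at most ~0.01 on the
height.

## Synthetic data generator

`sample_database` emulates the published trial landscape; it is the
package's stand-in for a deposited literature database and defines the
study conditions for all simulation-based checks:

- dose-levels per study drawn from {2..8} with probabilities
  (.30, .15, .22, .18, .08, .04, .03), calibrated once so the series-size
  summary reproduces the documented landscape value of median 4 with
  quartiles (2, 5);
- cohorts of 3–6 patients per dose (the field's typical cohort size;
  the true per-dose sample-size distribution of the literature is not
  published, so this is a convention);
- 15% of studies get a partially ordered two-agent dose set — the
  crossed-pair topology (two incomparable doses under a common
  escalation) or a diamond — optionally extended by joint escalations;
  the latent dose strength driving event simulation for such studies is
  the dose's depth in the partial order, so shared doses stay consistent
  across the series that contain them;
- true DLT curves are monotone increasing with heights uniform on
  (0.1, 0.5) and floors on (0.02, 0.15); true OR curves are flat for 85%
  of studies (levels 0.05–0.35) with a small positive minority; OR is
  reported by 60% of studies, matching the scarcity of response-by-dose
  reporting;
- study metadata (year, rule/model-based design, disease class,
  treatment class) is drawn with frequencies mirroring the published
  landscape.

Everything is a pure function of (spec, seed); event counts are
Binomial(n, p_truth(level)). What the generator does *not* emulate:
sequential escalation dynamics (cohort allocation does not depend on
interim toxicity, so there is no dose-selection bias toward the MTD),
between-study heterogeneity in DLT definitions, and reporting-driven
missingness correlated with outcomes. Passing recovery tests therefore
demonstrate estimator correctness under the stated conditions, not
robustness to those real-data artefacts.

## Simulation results bundled as acceptance checks

With 200 monotone series of 4 levels × 100 patients, the Bayesian
posterior-mean height has bias ≈ −0.03 (criterion |bias| < 0.05) and
90%-interval coverage ≈ 0.84–0.86: the uniform asymptote priors shrink
large heights toward zero, visibly but within tolerance. On 200 flat
series the mean estimated height is within ±0.01 of zero. At
trial-realistic cohort sizes (3–6 per level) the shrinkage is much
stronger — posterior-mean heights average roughly a third of the
generating truth — so the end-to-end check on the packaged scenario
asserts the *direction and separation* of the DLT/OR contrast, not the
truth scale. Problem sizes (200 replicates, 20-series oracle set, one
~100-study landscape) were chosen as the smallest that make the checks
statistically meaningful.

## Numerical conventions and edge cases

- 0·log 0 is treated as 0 in the likelihood; a boundary probability that
  contradicts observed counts yields −∞ (and for the ML objective,
  probabilities are clipped to [10⁻¹², 1−10⁻¹²] so the optimiser sees
  finite values).
- Quantiles everywhere (series-size IQR, posterior intervals) use linear
  interpolation (type 7), the numpy default, recorded so that summaries
  like "4 (2, 5)" are reproducible.
- Interval level defaults to 90% (central, equal-tailed) and is
  configurable; dot plots show posterior means (not medians),
  configurable likewise.
- Missing outcome counts are empty cells, never 0 — zero events is
  information, absence is not.
- The curve-panel transform centres each series' levels at zero and,
  when K > 9, keeps the middle nine levels
  (⌈(K−9)/2⌉+1 … ⌈(K−9)/2⌉+9).
- Figures are artifacts; all tested quantities live in the tables the
  figures are drawn from.

## Known limitations

- Curve heights are on the ordinal level scale; a "level" is not a
  fixed dose increment, so heights measure within-series gradients, not
  pharmacological potency.
- The ML route's standard errors come from a finite-difference Hessian
  at a possibly-boundary optimum; they are reported for failure
  detection, not inference.
- Orphan (single-dose) series are excluded from fitting; the analysis
  presumes this loses gradient information that never existed, but their
  event counts do not inform any curve.
- Ensemble-sampler R̂/ESS with walkers-as-chains understate
  autocorrelation; the grid oracle is the authoritative correctness
  check for posterior summaries.
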