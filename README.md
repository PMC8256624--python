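# dosemono

**Do toxicity and response really rise with dose?** Dose-escalation
(phase I) oncology trials are built on two monotonicity assumptions:
that the probability of a dose-limiting toxicity (DLT) increases with
dose, and — through the pursuit of a maximum tolerable dose — that the
probability of an objective response (OR) does too. `dosemono` is a
toolkit for testing those assumptions across a landscape of
dose-finding trials, given only what trial reports publish: per
dose-level, the number of patients evaluated and the number of DLT and
OR events.

It is aimed at biostatisticians and trial methodologists who want to
run, extend or stress-test this kind of landscape analysis. The
pipeline:

1. **Series construction.** Combination-therapy dose sets are only
   partially ordered (is 10 mg A + 20 mg B more or less than
   20 mg A + 10 mg B?). Each study's doses are compared component-wise
   and decomposed into fully orderable *analysis series* — maximum-length
   chains covering every dose, sharing a dose between series only when
   the alternative is an orphan series of size one.
2. **Curve fitting.** Within each series, the per-level event counts are
   fit with the four-parameter sigmoidal Emax model for a binomial
   outcome,

       p(x) = p_lo + (p_hi − p_lo) · x^h / (ED50^h + x^h),

   whose floor `p_lo` and ceiling `p_hi` live in [0,1]: unlike logit
   regression, the event probability may plateau below 1 — essential
   when asking whether efficacy keeps rising. Fitting is by maximum
   likelihood (with explicit failure flags: non-convergence, boundary
   estimates, exploding standard errors) and by Bayesian posterior
   sampling under uniform priors on floor and ceiling, which returns a
   usable curve for every series, however small.
3. **The height statistic.** Each fitted curve is summarised by its
   *height*: fitted event probability at the highest investigated level
   minus that at the lowest. Positive heights mean the event becomes
   more likely as dose increases.
4. **Aggregation.** Heights are pooled into grouped summaries and
   plots by treatment class and outcome — never pooled across studies at
   the likelihood level.

Because the package is developed against simulations, it ships a
first-class synthetic-trial generator (`dosemono.synthetic`) that
emulates the published landscape — ~4 dose-levels per series
(quartiles 2 and 5), cohorts of 3–6 patients, monotone-increasing true
toxicity curves, flat-majority response curves, and partially ordered
combination dose sets — with known ground truth for every study.

See `docs/methods.md` for the model, priors, algorithms and their
limitations.

## Worked example

The analysis scripts under `analysis/` run the full pipeline on the
packaged synthetic landscape and write tables and figures to
`results/`:

```
$ python analysis/01_simulate.py
100 studies (12 with combination doses), 387 dose rows -> results/synth_db.csv
156 truth records -> results/truth.csv

$ python analysis/02_build_series.py
112 DLT series, 63 OR series (112 / 63 fittable)
dose-levels per series, median (IQR): DLT 4 (2, 5), OR 4 (2, 5)

$ python analysis/03_fit_curves.py
Bayesian fits succeeded for all 175 fittable series
ML fit outcomes: {'boundary': 118, 'se_explosion': 56, 'none': 1}

$ python analysis/04_heights_report.py
DLT: 112 series, mean height +0.071, share positive 0.77
OR: 63 series, mean height +0.011, share positive 0.54
```

Reading those numbers: the 100 simulated studies yield 112 fully
orderable toxicity series (partial orders split into more than one
series per study) with the documented landscape's series-size summary,
median 4 dose-levels, IQR (2, 5). Maximum likelihood fails on nearly
every trial-sized series — estimates pinned to the parameter boundary
or standard errors beyond any use — while the Bayesian route fits all
of them. The headline contrast: 77% of toxicity curves rise with dose
(mean height +0.07), while response heights straddle zero (mean +0.01,
share positive 0.54) — higher doses were more toxic but, in the
flat-truth majority the generator plants, not more effective, and the
pipeline recovers exactly that.

`analysis/05_recovery.py` quantifies the estimator itself: over 200
monotone series (4 levels × 100 patients) the posterior-mean height has
bias −0.03 and 90%-interval coverage 0.84; over 200 flat series the
mean estimated height is +0.001.

The same steps are available as a CLI for your own data
(`dosemono validate | summarize | build-series | fit | simulate |
report`); the input is a CSV with one row per study-dose (schema in
`dosemono.database`).

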