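# Methods

This note documents the statistical models implemented in `surgelag`,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

The unit of the count analyses is the *SA episode*: attempts occurring
within the 7 days before one emergency admission collapse to a single
episode carrying the characteristics of the first attempt, and attempts
more than 7 days before their admission are excluded. Episodes are
binned by the calendar month of the attempt date (not the admission
date), because the scientific quantity of interest is when attempts
happen. Repeat attempts by one patient more than 7 days apart, each
leading to an admission, count as separate episodes. Records lacking a
patient identifier cannot be linked, so each is treated as its own
episode; this is logged, since it can overcount in registries with
repeat attenders.

OxCGRT policy indicators are read from the tracker's daily wide CSV and
reduced to monthly values. The daily-to-monthly reduction for ordinal
policy scales is not a settled convention; the default is the most
frequent daily level with ties broken toward the higher (more
restrictive) level, configurable to `max` or end-of-month. Cumulative
confirmed cases/deaths become monthly new counts (negative corrections
clipped to zero) and are transformed `log10(x+1)`: a death count rising
within one order of magnitude is treated as a comparable stimulus, an
order-of-magnitude rise as a larger one. Natural log is available as an
option.

## Stage 1: changepoint detection

Monthly counts are segmented with PELT under a Gaussian cost in which
each segment has its own mean and variance,

    C(seg) = -2 max_{mu, sigma^2 >= eps} log N(x_seg | mu, sigma^2),

and the objective is `sum C(seg) + beta * (#changepoints)`. Named
penalties follow the conventions of the standard changepoint literature
for this cost: `BIC` is `(p+1) log n` with `p = 2` distribution
parameters (the extra unit counts the changepoint location); `MBIC`
(default) is `(p+2) log n` with `log(segment length)` added to each
segment cost. The minimum segment length defaults to 2, the smallest
that identifies a variance.

Two numerical points matter:

* **Variance floor.** The unconstrained variance MLE of a tied pair of
  integer counts is 0, which would give the segment an arbitrarily
  large negative cost and make every tied pair split out as its own
  segment. The cost therefore maximises the likelihood under
  `sigma^2 >= eps` with `eps = 0.25` by default — below the granularity
  of integer counts, so no information is lost, but large enough that
  constant pairs cannot dominate the objective. The constrained form
  (likelihood evaluated at `eps` when the MLE variance falls below it)
  rather than a clamped plug-in keeps the cost subadditive, which the
  next point requires.
* **Exactness of pruning.** PELT's pruning rule is only valid when the
  cost is subadditive, and with a minimum segment length `m > 1` a
  candidate pruned at time `t` may still be needed for ends in
  `(t, t+m)`; removal is therefore delayed by `m`. The MBIC
  log-segment-length term is not subadditive, so pruning under MBIC
  uses the slack `K = log(4/n)` (from
  `log n1 + log n2 >= log(n1+n2) + log(4/n)`). With these two details
  the implementation returns the exact optimum: the test suite checks
  identity of breakpoints and objective against an exhaustive O(n^2)
  dynamic program on hundreds of random series, and any future change
  must preserve that identity.

The pipeline designates as *primary breakpoint* the earliest detected
changepoint at or after the configured pandemic-onset month. Per-country
period pooling can be overridden in the configuration (for series where
a temporary summer dip splits the post-surge period).

## Stage 2: patient-profile contrasts

The response is second-period membership. For a binary covariate the
univariate odds ratio is the closed-form cross-product ratio, identical
to the logistic MLE; age enters as a continuous covariate (OR per year).
Confidence intervals are Wald on the log-odds scale; p-values are
likelihood-ratio (G-test for 2x2 tables), the more stable default —
Wald p-values are also reported in the coefficient tables. Zero cells
receive the Haldane–Anscombe +0.5 correction and are flagged (or raise
in strict mode). Covariates with univariate p < 0.20 enter the
multivariate logistic model, fitted by IRLS on complete cases (no
imputation; each model's n is reported, mirroring how per-covariate
denominators vary in registry data). Quasi-separation (|log-odds| > 15)
is flagged rather than masked.

The pooled analysis uses a logistic model with a Gaussian random
intercept per country — intercept-only, since a "country marker as a
random effect" is most plainly an intercept, and five or six groups give
little information for a random slope. The integrated likelihood is
approximated by Laplace's method (default) or adaptive Gauss–Hermite
quadrature with k nodes; the group modes are found by Newton steps, and
the outer optimisation over fixed effects and log sigma_u uses BFGS with
restarts. Fixing sigma_u = 0 reproduces the pooled IRLS fit exactly,
which is one of the unit checks; the fit on a five-country grouped
binomial fixture agrees with lme4's Laplace and AGQ-25 estimates to
about 4 significant figures (frozen reference values in the tests).

## Stage 3: lagged negative-binomial regression

Counts are modelled as NB2 (variance `mu + alpha mu^2`; the single
overdispersion scalar is `alpha`) with log link, country-specific fixed
intercepts and the annual + semiannual Fourier block

    Seas(t) = d1 sin(2 pi t/12) + g1 cos(2 pi t/12)
            + d2 sin(4 pi t/12) + g2 cos(4 pi t/12).

The month index `t` is the absolute calendar month, so the phase is
calendar-true. Coefficients and `alpha` are jointly estimated by maximum
likelihood (statsmodels' NB2 machinery behind the package's estimator
facade). Starting values are always constructed from a Poisson GLM plus
a moment estimate of `alpha`: the library's own defaults stall on
designs without a global intercept, and a stalled inner fit silently
corrupts every comparison built on top (lag profiles, BIC traces), so
the package never relies on them. If the data are equidispersed the
`alpha` estimate collapses to the boundary; the fit then falls back to
the Poisson GLM with `alpha = 0` and is flagged. BIC counts every
estimated parameter including `alpha`.

**Optimal lag.** For each indicator, the model nuisance +
indicator(t−L) is fitted for L on a 0–12-month grid (the grid is
configuration). "Strongest statistical link" is operationalised as the
largest likelihood-ratio improvement over the nuisance-only fit —
well-defined also for ordinal indicators, which enter as one dummy per
nonzero level (never as linear scores) and are jointly tested. All lags
within one scan share one observation window (the first `max(grid)`
months of each country are dropped), so log-likelihoods and BICs are
comparable like for like. Ties break toward the smaller lag.

**Nuisance block.** Besides seasonality and country intercepts, three
onset-anchored terms are available: a linear trend, months since onset,
and a pandemic-period indicator. The pipeline default includes the
months-since-onset and pandemic-period terms in every count model.
This choice matters: in a system where several strong lagged effects
act at once, a univariate scan of one indicator is misspecified for the
others, and without the onset-anchored absorbers the scan tends to pull
the lag toward whatever shift soaks up the largest unmodelled
post-onset elevation. The absorbers remove the common level shift and
leave the timing structure, which is what a lag scan should be
estimating. Users can move these terms to the candidate set instead.

**Forward selection.** Starting from the nuisance-only model, the
lagged indicator with the lowest BIC is added greedily until no
addition lowers BIC; the full candidate-BIC trace is emitted. Candidate
fits are warm-started from the current model's coefficients — a nested
model with one extra term can never have lower likelihood, and warm
starts guarantee the optimizer respects that in practice. The final
model's BIC is never worse than the nuisance-only BIC by construction.

## Synthetic-data generator

The generator defines the package's standard test bench: six
pseudo-countries observed monthly over 48 months, pandemic onset at
month 27, baseline monthly means between about 5 and 20 (surveillance
scale), seasonal coefficients (0.034, 0.20, −0.19, −0.15),
overdispersion `alpha = 0.06`, a contact-tracing effect at an 11-month
lag with level IRRs 1.37 (partial) and 2.24 (comprehensive), and a
log10-deaths effect at a 3-month lag with IRR 1.20 per log10 unit —
inside the bracket of the adjusted (1.13) and unadjusted (1.28)
associations reported for this design, the unadjusted end being what a
univariate scan estimates. Policy indicators are zero before onset,
ramp up quickly, plateau and partially step down; epidemic deaths come
in three sharp waves with deep troughs.

Two generator properties are load-bearing for what the tests show:

* **Cross-country heterogeneity.** Adoption months, step-down months,
  wave timing and wave severity all vary by country (and contact
  tracing steps back down to "partial" in about half the countries, as
  tracing capacity is overwhelmed mid-pandemic). A lag is identifiable
  exactly to the extent that such timing contrast exists; with perfectly
  synchronised countries the lag scans of two simultaneously acting
  indicators confound each other and no estimator could separate them.
  Passing lag-recovery tests therefore demonstrate the machinery under
  informative conditions, not that any real, more synchronised panel
  would identify lags equally well.
* **Coupled covariate shift.** The line-list covariate mix (female
  share 0.80→0.90, self-poisoning 0.72→0.60, family history 0.45→0.40,
  age 15.2→15.0) changes at a per-country breakpoint month, by design
  coincident with the count-level surge window.

What the generator does not emulate: reporting artifacts (holiday
under-reporting, backlogs), within-country regional heterogeneity,
autocorrelated count errors beyond NB overdispersion, the early-lockdown
access collapse that real series show as a transient dip, and quarterly
or pooled reporting streams (count-only streams without covariates are
handled by the pipeline, but not generated by default). Conclusions
about real data should not be read off the recovery rates on this
bench.

## Degenerate inputs and numerical conventions

* Dates parse as ISO-8601 or YYYYMMDD only; no locale guessing.
* Constant indicator over the usable window → the scan refuses ("no
  identifiable effect") rather than returning an arbitrary lag.
* Single-month segments report a missing SD; zero cells, separation and
  Poisson-boundary fits are flagged, never silently repaired.
* IRLS convergence: max |score| < 1e-8, 100 iterations, damped steps on
  separation paths. NB fits: Newton then BFGS then Nelder–Mead from the
  Poisson start; a fit that still fails raises (lag scans drop that lag
  with a warning; selection skips the candidate at that step).
* All randomness flows through explicit `numpy` generators seeded from
  the caller; two runs with one seed produce byte-identical JSON.

## Known limitations

* The multilevel model is intercept-only; random slopes are out of
  scope.
* No inference correction is applied for having selected the optimal
  lag before testing it (the null-calibration test documents the
  selection effect empirically); no multiple-testing correction is
  applied across covariates, matching the analysis design this package
  reproduces.
* The desk-reproducible published odds ratios recompute exactly from
  the printed two-period counts; the published pooled multilevel sex OR
  does not (the prescribed grouped-count reconstruction yields 1.92, as
  does lme4 on the same table, against a printed 1.82 — evidently an
  artifact of details of the non-public individual-level dataset), and
  the package reports its honestly computed value.
* Fig-style outputs are limited to a basic series/changepoint overlay
  plot; publication graphics are out of scope.
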