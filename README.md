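# surgelag

Tools for analysing delayed surges in monthly suicide-attempt (SA)
surveillance series from pediatric psychiatric emergency departments,
and for relating those surges to pandemic-response indicators such as
the OxCGRT (Oxford COVID-19 Government Response Tracker) policy scales.

The package is aimed at epidemiologists and biostatisticians working
with multi-country interrupted time series of admission counts plus a
patient line-list. It implements a three-stage analysis:

1. **Changepoint detection.** Each country's monthly episode series
   `x_1..x_n` is segmented by PELT (Pruned Exact Linear Time) under a
   Gaussian mean-and-variance cost: minimise
   `Σ_seg −2 max log N(x_seg | μ, σ²) + β·(#changepoints)`, with
   `β = (p+1)·log n` (BIC) or the modified BIC. An exhaustive O(n²)
   optimal-partitioning oracle is included and must agree with PELT
   exactly on any input.
2. **Profile contrasts.** With the response `y = 1{month ≥ breakpoint}`,
   patient covariates (age, sex, SA method, family psychiatric history,
   previous ER visit) are screened by univariate logistic models /
   closed-form 2×2 odds ratios; covariates with p < 0.20 enter a
   multivariate logistic model. Pooling countries, a random-intercept
   (multilevel) logistic model `logit P(y=1) = xβ + u_country`,
   `u ~ N(0, σ_u²)`, is fitted by maximising the Laplace- or adaptive
   Gauss–Hermite-approximated integrated likelihood.
3. **Lagged count regression.** Monthly counts follow an NB2 model
   `log μ_t = country + Seas(t) + Σ_k β_k·indicator_k(t − L_k)`,
   `Var = μ + α μ²`, with
   `Seas(t) = δ₁ sin(2πt/12) + γ₁ cos(2πt/12) + δ₂ sin(4πt/12) + γ₂ cos(4πt/12)`.
   For each indicator the *optimal lag* L maximises the likelihood-ratio
   improvement over the nuisance model on a common observation window;
   a greedy forward selection by BIC over indicators at their optimal
   lags yields the final multivariate model (effects reported as
   incidence-rate ratios, IRR).

Because patient-level registry data of this kind are not public, a
synthetic-data module generates line-lists, count series and indicator
panels with known ground truth (breakpoints, covariate shifts, lags,
IRRs, overdispersion), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from surgelag import (TwoByTwo, univariate_or, pelt_meanvar,
                      default_scenario, simulate_study, lag_scan, NuisanceSpec)

# 2x2 odds ratio: rows = covariate level (ref, other), cols = period
res = univariate_or(TwoByTwo(62, 15, 139, 155))
print(f"OR {res.estimate:.2f} [{res.ci_low:.2f}; {res.ci_high:.2f}] p={res.p:.1e}")

# synthetic study with known truth, then changepoints and a lag scan
truth = default_scenario(seed=1)
data = simulate_study(truth, seed=1)
cp = pelt_meanvar(data["series"][0])  # default MBIC penalty
print("breakpoints:", cp.breakpoints, "segment means:",
      np.round(cp.segments["mean"].to_numpy(), 1))

onset = str(truth.start_period + truth.onset_month - 1)
nuis = NuisanceSpec(onset_month=onset, months_since_onset=True,
                    pandemic_indicator=True)
scan = lag_scan(data["series"], data["panels"], "contact_tracing", nuisance=nuis)
print("optimal lag:", scan.optimal_lag)
```

This prints:

```
OR 4.61 [2.51; 8.47] p=6.9e-08
breakpoints: [34, 48] segment means: [ 5.4 11.9]
optimal lag: 11
```

The odds ratio says patients at the non-reference covariate level have
4.6 times the odds of presenting in the second period; the changepoint
splits this country's 48 months at month 34 into a low-mean and a
high-mean segment; and the scan recovers the 11-month generative lag
between the contact-tracing indicator and the count surge.

The full pipeline (all three stages, JSON/CSV artifacts and plots under
an output directory) runs from the command line:

```bash
surgelag run --out my_run --seed 1
surgelag simulate --scenario examples/scenario_default.yaml --out synth/
surgelag changepoint --series synth/counts.csv --penalty MBIC --out cp.json
```

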