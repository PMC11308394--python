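# Standard synthetic scenario: six pseudo-countries observed monthly over
# four years, pandemic onset at month 27 (a March-2020 analogue in a
# January-2018 window).  Any key omitted here keeps the package default.
countries: [country_1, country_2, country_3, country_4, country_5, country_6]
n_months: 48
start: "2018-01"
onset_month: 27

# log baseline monthly episode means (surveillance-scale, ~5 to 20)
intercepts:
  country_1: 1.7227665977411035   # log 5.6
  country_2: 2.1747517214841609   # log 8.8
  country_3: 1.6292405397749344   # log 5.1
  country_4: 2.1633230256605382   # log 8.7
  country_5: 2.7080502011022101   # log 15.0
  country_6: 2.9755415441952301   # log 19.6

# annual + semiannual Fourier coefficients (sin, cos, sin2, cos2)
seasonal: [0.034, 0.20, -0.19, -0.15]

# NB2 overdispersion: variance = mu + alpha * mu^2
alpha: 0.06

# lagged effects on log mean counts; ordinal indicators carry one
# log-IRR per nonzero level, continuous indicators a single slope
effects:
  contact_tracing:
    lag: 11
    beta: {1: 0.3148107398400336, 2: 0.8064758658669485}   # IRR 1.37 / 2.24
  log_deaths:
    lag: 3
    beta: 0.1823215567939546                                # IRR 1.20 per log10 unit

# month (1-based) at which the patient-profile mix shifts, per country
breakpoints:
  country_1: 37
  country_2: 33
  country_3: 37
  country_4: 33
  country_5: 37
  country_6: 37

# covariate mixes before and after the breakpoint
pre:
  female: 0.80
  self_poisoning: 0.72
  family_history: 0.45
  previous_er_visit: 0.45
  age_mean: 15.2
  age_sd: 1.6
post:
  female: 0.90
  self_poisoning: 0.60
  family_history: 0.40
  previous_er_visit: 0.45
  age_mean: 15.0
  age_sd: 1.6

seed: 0
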