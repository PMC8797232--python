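# Published model inputs for the gout treatment cost-effectiveness model.
# Keys mirror the published input-table row names verbatim; the loader in
# goutcea.parameters maps them onto internal identifiers.
#
# Conventions:
#   beta_mean_sd    - beta distribution parameterized by mean/sd (mu, sigma)
#   beta_shape      - beta distribution parameterized by shapes (alpha, beta)
#   beta_complement - the published beta describes the COMPLEMENT q of a
#                     small daily probability p = 1 - q; the PSA samples q
#                     with mean 1 - point and the printed sigma
#   exp_plus_gamma  - two cost components: productivity (exponential, lambda)
#                     and healthcare (gamma, alpha shape / beta scale)

"Probability SUA < 0.36 mmol/L":
  "Allopurinol 200 mg":
    point: 0.457
    distribution: {family: beta_mean_sd, mu: 0.455, sigma: 0.045}
  "Allopurinol 300 mg":
    point: 0.480
    distribution: {family: beta_mean_sd, mu: 0.478, sigma: 0.027}
  "Febuxostat 80 mg":
    point: 0.729
    distribution: {family: beta_mean_sd, mu: 0.730, sigma: 0.013}
  "No ULT":
    point: 0.000
    distribution: null

"Daily flare probability":
  "SUA on target with ULT":
    point: 0.000716
    distribution: {family: beta_complement, sigma: 0.002}
  "SUA not on target with ULT":
    point: 0.001222
    distribution: {family: beta_complement, sigma: 0.002}
  "SUA not on target with no ULT":
    point: 0.001637
    distribution: {family: beta_complement, sigma: 0.002}

"Quality adjusted life days":
  "No pain":
    point: 0.86
    distribution: {family: beta_shape, alpha: 16.325, beta: 3.076}
  "Mild pain":
    point: 0.77
    distribution: {family: beta_shape, alpha: 10.942, beta: 3.177}
  "Moderate pain":
    point: 0.70
    distribution: {family: beta_shape, alpha: 12.696, beta: 5.329}
  "Severe pain":
    point: 0.61
    distribution: {family: beta_shape, alpha: 19.817, beta: 12.877}

"Daily other costs (in euros)":
  "No pain":
    point: 19.95
    distribution: {family: exp_plus_gamma, lambda: 1.749, alpha: 0.317, beta: 3.623}
  "Mild pain":
    point: 32.39
    distribution: {family: exp_plus_gamma, lambda: 1.081, alpha: 0.493, beta: 2.135}
  "Moderate pain":
    point: 58.08
    distribution: {family: exp_plus_gamma, lambda: 0.599, alpha: 0.434, beta: 4.149}
  "Severe pain":
    point: 134.32
    distribution: {family: exp_plus_gamma, lambda: 0.259, alpha: 0.291, beta: 10.769}

"Daily drug costs (in euros)":
  "Colchicine": {point: 0.61}
  "Naproxen": {point: 0.21}
  "Prednisone": {point: 0.26}
  "Anakinra": {point: 33.4}
  "Allopurinol": {point: 0.13}
  "Febuxostat": {point: 1.03}

"Discounting":
  costs_per_year: 0.04
  utility_per_year: 0.015

"Model structure":
  horizon_days: 365
  flare_duration_days: 7
  # Annual utility decrement applied while serum urate is above target.
  # No published value exists; 0.05/year is a package default chosen to
  # reproduce the published QALY separations between ULT arms (see docs).
  off_target_annual_disutility: 0.05
  # Daily "other" cost on days without a flare; null means: use the
  # "No pain" daily other cost (documented assumption).
  no_flare_daily_cost: null
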