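# Published backward-selected occurrence equation: ten retained standardized
# predictors plus intercept, applicable verbatim to any conforming stack via
# snakerisk.incidence.linear_score / risk_map.
family: gaussian_identity
intercept: -0.778
terms:
  annual_mean_temperature: 13.299
  mean_diurnal_range: 5.196
  isothermality: -5.075
  mean_temperature_of_wettest_quarter: -5.338
  annual_precipitation: -3.61
  precipitation_of_driest_month: 0.275
  precipitation_seasonality: 5.068
  precipitation_of_warmest_quarter: 0.309
  elevation: 0.601
  human_population: 1.573
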