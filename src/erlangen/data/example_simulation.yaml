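# Example simulation configuration for `erlangen simulate --config ...`.
# Omitted keys fall back to the package defaults (four published group
# profiles, hazard ratios 7.67/1.04/12.0 over baseline 0.04/yr, default
# copula, censoring Uniform(2, 12) years).
hazard:
  baseline_rate: 0.04      # events/year in the improbable category
  hr_possible_early: 7.67  # possible vs improbable, first 3 years
  hr_possible_late: 1.04   # possible vs improbable, after 3 years
  hr_probable: 12.0        # probable vs improbable, time-constant
  split_time: 3.0          # years
censor_window: [2.0, 12.0] # administrative censoring, Uniform(min, max) years
seed: 0                    # overridden by --seed on the command line
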