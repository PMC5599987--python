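# Demonstration run: a synthetic survey with a known smoking effect
# (true OR 2) scored by imperfect raters (Se 0.75, Sp 0.80), analysed
# end to end at reduced MCMC settings.
seed: 7
outcome: combined
simulate:
  n_subjects: 500
  sextants_per_subject: 6
  beta: {smoking: 0.6931471805599453}   # log 2
  sigma_u: 0.8
  se_by_rater: 0.75
  sp_by_rater: 0.80
n_validation_units: 600
univariate: [smoking]
mcmc:
  n_walkers: 16
  n_steps: 500
  n_burn: 300
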