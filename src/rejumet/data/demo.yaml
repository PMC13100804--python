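# Packaged demo configuration: both species, all stages, fixed seeds.
# Arm sizes echo the reference designs; simulation sizes are kept small so
# the full pipeline runs in well under a minute on one CPU.
seed: 1
qc_threshold: 3.0
beta_age_error_sd: 0.01
mouse: {}          # defaults: 7/10/14 WT arms, 8/5 AT1KO, 7/6 AT2KO, 120 features
human: {}          # defaults: 9 placebo + 7 treated, 0/25/50/100 mg visits, 160 features
survival:
  n_treated: 19
  n_control: 14
  hazard_treated: 0.006
  hazard_control: 0.02
  followup_days: 60
clinical:
  dose_effect_na: 0.04
dose_orders: [1, 2, 3]
enrichment:
  n_perm: 200
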