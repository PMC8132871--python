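# Desk-scale enhanced-sampling run on the toy Langevin backend.
#
# Counters keep the production ladder (each >= 10x the previous) scaled
# down by four orders of magnitude; documented production defaults are
# n_needed=1e9, n_short=1e7, n_saving=1e4, n_biasing=50 with retraining
# every n_saving*100 steps.

potential:
  type: double_well
  center: 0.0
  barrier_height: 8.0   # units of kBT

loop:
  n_needed: 50000
  n_short: 5000
  n_saving: 500
  n_biasing: 50
  seed: 1

vae:
  n_hidden: 1           # 1-D toy system; widths floor(2D/n) must stay >= 1

bias:
  v_kl_upper: 1.0e-5    # aggressiveness dial; 0 disables biasing
  n_representatives: 32
  aggregation: min      # use "mean" for runs meant to be reweighted

dynamics:
  dt: 0.01
  friction: 1.0
  kbt: 1.0
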