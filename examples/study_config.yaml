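# Example study configuration for `diagmiss run --config`.
# Omitted grid factors fall back to the full factorial defaults
# (sens/spec 0.7/0.8/0.9, MCAR/MAR/MNAR, miss 0.1/0.3/0.5,
#  prevalence 0.1/0.2/0.4, n 400/800/1600).
grid:
  true_sens: [0.8]
  true_spec: [0.8]
  mechanism: [MCAR, MAR]
  miss_prop: [0.1, 0.5]
  prevalence: [0.2]
  n: [800]
n_sim: 200
seed: 1
mice_m: 5
methods: [CCA, WC, RHD, MICE, MLMCAR, MLMAR, WLSMCAR]
# theta0: 0.7          # enable the power computation against a null value
n_jobs: 1
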