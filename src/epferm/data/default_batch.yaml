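# Calibrated default batch-trajectory generator parameters.
#
# The substrate channel is calibrated by forward simulation so the
# noiseless trajectory starts at 34.34 g/L glycerol and reaches ~21 g/L at
# 80 h; the product yield is set so ~13.3 g/L consumed maps to ~260 ug/L
# product.  See scripts/calibrate_defaults.py for the calibration run.
kind: monod
params:
  mu_max: 0.05      # 1/h
  ks: 15.0          # g/L
  yb: 0.5           # g biomass / g glycerol
  yp: 19.6          # ug product / g glycerol
  c0: 34.34         # g/L
  x0: 0.5           # g/L
sampling:
  t_end: 112.0      # h
  n_points: 29      # every 4 h
noise:
  cv_substrate: 0.02
  cv_biomass: 0.02
  cv_product: 0.02
product_decay: 0.0  # 1/h; optional first-order product loss (kd)
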