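name: fig1a
kind: ode
provenance: >-
  Phase plane, stable-spiral case (delta/eta0 < 1): eta0=0.02, dp=0.8,
  ds=0.9, delta=0.01, sbeta=0.1, sigmap=0.08; trajectory from
  (p, v) = (0.01, 1).  Oxygen parameters are the reduced-model groupings.
params:
  eta0: 0.02
  dp: 0.8
  delta: 0.01
  sbeta: 0.1
  ds_tilde: 0.9
  sigmap_tilde: 0.08
initial:
  p0: 0.01
  v0: 1.0
run:
  t_end: 8000.0
  n_out: 4000
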