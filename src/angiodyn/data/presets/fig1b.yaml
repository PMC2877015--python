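name: fig1b
kind: ode
provenance: >-
  Phase plane, unstable-spiral / stable-limit-cycle case (delta/eta0 > 1):
  eta0=0.02, dp=0.8, ds=0.4, delta=0.03, sbeta=0.1, sigmap=0.01;
  trajectory from (p, v) = (0.5, 0.6).
params:
  eta0: 0.02
  dp: 0.8
  delta: 0.03
  sbeta: 0.1
  ds_tilde: 0.4
  sigmap_tilde: 0.01
initial:
  p0: 0.5
  v0: 0.6
run:
  t_end: 8000.0
  n_out: 4000
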