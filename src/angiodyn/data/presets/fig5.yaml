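name: fig5
kind: pde
provenance: >-
  Invasion with an unstable wake (irregular spatio-temporal oscillations):
  eta0=0.5, dp=0.6, ds=0.2 (Hopf at 0.2761), delta=1.0, Dv=1, sbeta=0.4,
  sigmap=0; dx=1/3, L=3500, seed (p, v)(0, 0) = (0.01, 1).
params:
  eta0: 0.5
  dp: 0.6
  delta: 1.0
  sbeta: 0.4
  ds_tilde: 0.2
  sigmap_tilde: 0.0
  Dv: 1.0
grid:
  L: 3500.0
  n: 10500
initial:
  p_seed: 0.01
  seed_width: 1.0
schedule:
  mode: none
run:
  variant: reduced
  t_end: 4000.0
  dt_out: 10.0
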