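name: fig6a
kind: pde
provenance: >-
  Full model prior to therapy, stable scenario (delta=9): eta0=10, dp=0.5,
  Ds=2.0e+5, Dv=1, hs=1.6e+6, sbeta=0.4, sigmap=3.7e+4; dx=25/900, L=250,
  initial (p, v, s, c)(0, 0) = (0.01, 1, 10/12, 0).  Decision default:
  ds = 3.2e+5 pins the far-field quasi-steady oxygen to the printed 10/12
  (the printed ds = 4.8e+5 would give 10/13; see preset fig6a_printed_ds).
params:
  eta0: 10.0
  dp: 0.5
  delta: 9.0
  sbeta: 0.4
  ds: 3.2e+5
  sigmap: 3.7e+4
  hs: 1.6e+6
  Ds: 2.0e+5
  Dv: 1.0
  Dc: 1.6e+4
  hc: 1.3e+3
  dc: 2.0e+4
  Kc: 0.05
  k: 0.9
grid:
  L: 250.0
  n: 9000
initial:
  p_seed: 0.01
  seed_width: 1.0
schedule:
  mode: none
run:
  variant: full
  t_end: 200.0
  dt_out: 10.0
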