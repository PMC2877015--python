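name: fig7b
kind: pde
provenance: 'Chemotherapy response, regular-oscillation scenario (delta=11.0): growth
  parameters as fig6; drug parameters dc=2.0e+4, Dc=1.6e+4, hc=1.3e+3, k=0.9, Kc=0.05.
  Therapy from t=200; arms: control, single bolus, 4 boluses separated by 10 time
  units. Decision defaults: c_init=1 (drug in units of the bolus concentration), run
  horizon 260.'
params:
  eta0: 10.0
  dp: 0.5
  delta: 11.0
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
  mode: single
  c_init: 1.0
  k: 0.9
  t_start: 200.0
run:
  variant: full
  t_end: 260.0
  dt_out: 0.5
schedule_multi:
  mode: periodic
  c_init: 1.0
  k: 0.9
  T_per: 10.0
  n_boluses: 4
  t_start: 200.0
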