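name: fig3
kind: map
provenance: >-
  Wake-stability partition of (delta, dp)-space at eta0=0.5, sbeta=0.4,
  sigmap=0; validity requires ds near its Hopf value.
params:
  eta0: 0.5
  dp: 0.6
  delta: 0.65
  sbeta: 0.4
  ds_tilde: 0.2
  sigmap_tilde: 0.0
map:
  delta_range: [0.55, 1.1]
  dp_range: [0.3, 0.7]
  n: 25
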