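# Methods

## The model

`angiodyn` simulates a continuum model of vascular tumour growth in one
space dimension with four fields: tumour-cell density `p(x,t)`, vascular
density `v(x,t)` (vessel surface area per unit volume), tissue oxygen
`s(x,t)` and tissue drug concentration `c(x,t)`, driven by a prescribed
plasma drug concentration `c_b(t)`.  In dimensionless form (tumour-cell
motility, vascular carrying capacity, blood oxygen level and the maximal
proliferation rate all scaled to 1):

```
p_t = p_xx          + p [ s/(s_beta + s) * (K_c - c)/(K_c + c) - d_p ]
v_t = D_v v_xx      + eta_0 v (1 - v) - delta p v / (p + v)
s_t = D_s s_xx      + h_s (1 - s) v - sigma_p p s - d_s s
c_t = D_c c_xx      + h_c (c_b(t) - c) v - d_c c
```

with no-flux boundaries on `[0, L]`.  Tumour cells proliferate at a
Michaelis–Menten rate in oxygen and die by apoptosis at rate `d_p`; a
cytotoxic drug converts proliferation into kill through the factor
`(K_c - c)/(K_c + c)` (+1 drug-free, 0 at the half-maximal kill
concentration `K_c`, → −1 at saturating drug).  Vessels grow
logistically at rate `eta_0` and are occluded by tumour pressure at the
saturating rate `delta · p v/(p+v)`, half-maximal per vessel when the
cell-to-vessel ratio is 1; the rational form makes the tumour-free limit
`v → 0` regular (0/0 → 0).  Oxygen and drug exchange with the blood at
rates proportional to the local vascular surface area.

The equation displays of the source text are not available in the
extraction this package was built from; every functional form above is
reconstructed from the verbal definitions and validated against the
printed steady states (0.35, 0.3)/(0.16, 0.3) and Hopf locations
0.2163/0.2761, all of which it reproduces to the printed precision.

### Quasi-steady oxygen and the homogeneous submodel

Oxygen kinetics (`h_s ~ 1.6e6`) are fast compared with tumour growth, so
the reduced model replaces the `s` equation by its root

```
s = v / (v + sigma_p~ p + d_s~),     sigma_p~ = sigma_p/h_s,  d_s~ = d_s/h_s.
```

Dropping space gives a planar predator–prey-like system for `(p, v)` in
which the tumour "preys" on the vasculature.  The tumour nullcline
(`phi(s) = d_p`) is a straight line in the `(v, p)` plane, degenerating to
the vertical line `v = S* d_s~/(1 - S*)`, `S* = d_p s_beta/(1 - d_p)`,
when `sigma_p~ = 0`; the vessel nullcline is
`p = g(v) = v(1-v)/(delta/eta_0 - (1-v))`.  A coexistence state exists iff
`d_p < 1/(1+s_beta)` and the nullcline zero lies in (0, 1); otherwise the
tumour-free state `(0, 1)` attracts.  For `delta/eta_0 ≤ 1` the
coexistence state is always linearly stable (both Jacobian diagonals are
negative there); for `delta/eta_0 > 1` it loses stability through a Hopf
bifurcation as the background consumption `d_s~` decreases.
`find_hopf_ds` locates the bifurcation by Brent root-finding on the
Jacobian trace (tolerance 1e-10, determinant checked positive, default
bracket (1e-4, 1) shrunk automatically into the existence region).
Stability classification uses the (trace, det, discriminant) signs with a
`marginal/Hopf` label when |trace| < 1e-8.

### Wake stability (lambda–omega reduction)

With `D_v = 1` and `sigma_p~ = 0` the dynamics near the Hopf point reduce
to a lambda–omega system — a complex Ginzburg–Landau equation with real
diffusion.  The cubic normal-form coefficient `c1` is computed by the
standard planar-Hopf formula from the second- and third-order partial
derivatives of the kinetics (obtained symbolically with sympy and
evaluated numerically; eigenvector `q = (J01, i*omega0 - J00)` with the
adjoint normalised to `<w, q> = 1`).  `Re c1 < 0` confirms the
supercritical branch; the reduction is refused otherwise.

Invasion of the unstable state selects the wave train of squared
amplitude `r^2 = 2/(1 + sqrt(1 + c^2))` (relative to the homogeneous
limit cycle), where `c = Im c1 / Re c1` is the nonlinear dispersion
ratio; its wavenumber satisfies `q^2 = 1 - r^2`.  Phase-diffusion
(Eckhaus) stability of that wave train requires `q^2 (3 + 2 c^2) < 1`,
which reduces to `|c|` below the real root of `u^3 = u^2 + 1` mapped back
through `u = sqrt(1 + c^2)`, i.e. `|c| < 1.0714`.  The criterion is
independent of the distance to the bifurcation, which is why the wake
prediction depends only on `(delta, d_p)` once the remaining parameters
are fixed (validity still requires `d_s~` near its Hopf value).

The normal form is validated in the test suite against an independent
simulation oracle: just past the Hopf point the simulated limit cycle
matches the predicted amplitude `4 |q_p| sqrt(-mu/Re c1)` to better than
1% and the predicted period `2*pi/(omega0 + Im c1 · r*^2)` to 0.2%, and
the two reference points (0.65, 0.6) and (1.0, 0.6) classify as stable
and unstable wake respectively, in agreement with direct PDE runs.

### Discretisation and time integration

The method of lines uses second-order central differences on a
vertex-centred grid with ghost-node reflection for the no-flux
boundaries (exactly mass-conserving for pure diffusion, which the test
suite asserts to 1e-8).  The state is stored species-interleaved per
node, so the Jacobian is banded with bandwidth equal to the species
count; time integration is LSODA (adaptive Adams/BDF) with that band
structure, relative tolerance 1e-8 and absolute tolerance 1e-10.  The
full model is stiff (exchange rates of order 1e6, oxygen diffusivity
2e5), which BDF absorbs without step-size collapse.  Plasma boluses are
discontinuities of the forcing, so integration restarts at each bolus
time.  Small negative excursions (order 1e-9, in the stiff oxygen
boundary layer) are clipped in the returned states with a single
aggregated warning.

### Fronts, burden and regularity

The front position `x_max` is the rightmost threshold crossing of the
tumour density (default detection threshold `p_crit = 0.01`; the source
leaves it unspecified), linearly interpolated between nodes; speeds are
least-squares slopes over a stated window, flagged low-confidence when
the extent is not monotone there.  The linear-spreading bound
`2 sqrt(phi(s_inf) - d_p)` follows from the decoupled tumour equation
ahead of the front and is independent of the occlusion rate.  Tumour
burden is the trapezoid integral of `p`.  Station time series are
classified `regular` when both the inter-peak intervals and the peak
heights have coefficient of variation below 0.05 (at least 10 peaks,
prominence 2% of the series range); these defaults separate the two
reference invasion cases cleanly (interval CVs ~0.01 vs ~0.1).

## Reference parameter sets

Shipped presets carry the published figure-caption values verbatim, with
two documented decisions:

* **Oxygen pinning (fig6/fig7 presets).**  The printed `d_s = 4.8e5` with
  `h_s = 1.6e6` implies a far-field quasi-steady oxygen of 10/13, while
  the printed initial condition is 10/12.  The presets pin
  `d_s~ = 0.2` (`d_s = 3.2e5`), matching the printed initial state; the
  printed-`d_s` variant ships as `fig6a_printed_ds`.
* **Seeding convention.**  The captions place the tumour seed at the left
  boundary but write zeros only for `x > 1` in the oscillatory-invasion
  cases; the default therefore seeds `p = 0.01` on the first unit
  interval (`seed_width = 1`, configurable to a single node).  With this
  convention the full-model front displacement between t = 100 and
  t = 200 computes to 82.60 space units against the printed 82.15
  (0.55%); the single-node seed gives 83.90.

Drug nondimensionalisation: `c_init = 1` (drug measured in units of the
bolus plasma concentration; the source does not print it) with
`K_c = 0.05` as printed; therapy starts at t = 200, and the multi-bolus
arm gives 4 boluses 10 time units apart.  Dimensional anchors
(1 time unit ≈ 1.45 days, 1 space unit ≈ 3.53e-3 cm) are derived from the
printed annotations 82.15 units = 0.29 cm and 100 units ≈ 145 days and
are flagged caption-derived.

## Problem sizes used by the tests

The full caption-scale experiments (domains of 3000 units to t = 4000;
treatment runs on L = 250 to t = 260) are available through the presets.
The test suite exercises the same physics at sizes chosen for routine
runs: wake classification on L = 1000 to t = 1500 (station at x = 50,
window t ≥ 700, ~15 peaks), the front-spread check at the full caption
grid (L = 250, dx = 25/900, t = 200), and the treatment scenarios on
L = 120 with therapy at t = 100 and horizon 160.  All qualitative claims
(burden ordering stable > regular > irregular, treated < control in the
stable scenario, multi ≤ single during regrowth, amplitude ratio > 1 in
the oscillatory scenarios) hold at both scales; the quantitative burden
values naturally differ with domain size and are not asserted.

## Limitations

* The wake criterion assumes `D_v = 1` and `sigma_p~ = 0`; for the full
  treatment presets (`sigma_p~ ≈ 0.023`) the scenario label drops the
  tumour oxygen-consumption term, mirroring the approximation under which
  the prediction was derived.  Simulations with `D_v ≠ 1` behave
  qualitatively similarly but carry no formal guarantee here.
* Only trace-zero Hopf detection is provided — no continuation of folds
  or global bifurcations.
* One space dimension, no chemotaxis, blood flow, vessel-maturity
  subpopulations or intracellular drug compartments.
* Quantitative post-therapy burden curves depend on `c_init` and the run
  horizon, neither of which is printed in the source; only the
  qualitative orderings above are asserted.
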