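"""Coexistence equilibria of the spatially homogeneous submodel.

With oxygen at quasi-steady state the model reduces to a planar
tumour-vessel system.  This example locates the coexistence steady state
(nullcline intersection) for the two phase-plane parameter sets and for
the invasion presets, and classifies its linear stability.  The occlusion
/ angiogenesis ratio delta/eta0 decides the character: at or below 1 the
state is always stable; above 1 it can be an unstable spiral surrounded by
a limit cycle.
"""

import angiodyn as ad

cases = {
    "stable spiral (delta/eta0 = 0.5)": ad.load_preset("fig1a").params,
    "limit cycle   (delta/eta0 = 1.5)": ad.load_preset("fig1b").params,
    "invasion, stable wake  (delta=0.65)": ad.load_preset("fig4").params,
    "invasion, unstable wake (delta=1.0)": ad.load_preset("fig5").params,
}

for label, params in cases.items():
    rep = ad.coexistence_equilibrium(params)
    print(f"{label}:")
    print(f"  (p*, v*, s*) = ({rep.p_star:.4f}, {rep.v_star:.4f}, "
          f"{rep.s_star:.4f})")
    print(f"  trace = {rep.trace:+.5f}, det = {rep.det:.5f}  "
          f"-> {rep.classification}")

print()
print("p* is the tumour-cell density and v* the vessel density at "
      "coexistence;")
print("a positive trace marks an unstable state whose oscillations are "
      "sustained")
print("by cycles of vessel occlusion and recovery.")
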