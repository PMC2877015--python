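"""Kinetic (reaction) terms of the dimensionless model.

All functional forms are reconstructed from their verbal definitions and
validated against the printed steady states and Hopf locations (see the
homogeneous module tests):

* tumour proliferation is Michaelis-Menten in oxygen, ``p * s/(sbeta+s)``,
  modulated by the drug kill factor ``(Kc - c)/(Kc + c)`` which is +1 with
  no drug, 0 at the half-maximal kill concentration ``c = Kc`` (proliferation
  halted in half the population, which dies instead) and -> -1 as c -> inf
  (all proliferating cells die at the proliferation rate);
* vessels grow logistically at rate ``eta0`` toward carrying capacity 1 and
  are occluded at the Michaelis-Menten rate ``delta * v * (p/v)/(1+p/v)``,
  half-maximal at p/v = 1; the algebraically equivalent ``delta*p*v/(p+v)``
  form is used so the tumour-free limit v -> 0 is regular (0/0 -> 0);
* oxygen is delivered at ``hs*(1-s)*v`` (blood level 1 in dimensionless
  units), consumed by tumour cells at ``sigmap*p*s`` and by other resident
  cells at ``ds*s``; drug delivery/decay is analogous.
"""

from __future__ import annotations

import numpy as np

from .params import DoseSchedule, Params

__all__ = [
    "phi", "proliferation_term", "occlusion_term", "vessel_kinetics",
    "oxygen_kinetics", "drug_kinetics", "quasi_steady_oxygen",
    "plasma_concentration",
]


def phi(s, sbeta):
    """Michaelis-Menten proliferation factor s/(sbeta + s)."""
    s = np.asarray(s, dtype=float)
    out = np.where(s > 0, s / (sbeta + s), 0.0)
    return out if out.ndim else float(out)


def proliferation_term(p, s, c, params: Params):
    """Net tumour proliferation rate p * phi(s) * (Kc-c)/(Kc+c)."""
    p, s, c = (np.asarray(a, dtype=float) for a in (p, s, c))
    if np.any(p < 0) or np.any(s < 0) or np.any(c < 0):
        raise ValueError("p, s and c must be nonnegative")
    out = p * phi(s, params.sbeta) * (params.Kc - c) / (params.Kc + c)
    return out if out.ndim else float(out)


def occlusion_term(p, v, params: Params):
    """Vessel loss rate delta*p*v/(p+v), with the 0/0 limit set to 0."""
    p, v = np.asarray(p, dtype=float), np.asarray(v, dtype=float)
    if np.any(p < 0) or np.any(v < 0):
        raise ValueError("p and v must be nonnegative")
    den = p + v
    out = np.where(den > 0, params.delta * p * v / np.where(den > 0, den, 1.0),
                   0.0)
    return out if out.ndim else float(out)


def vessel_kinetics(p, v, params: Params):
    """Net vessel rate: logistic growth minus occlusion."""
    v = np.asarray(v, dtype=float)
    out = params.eta0 * v * (1.0 - v) - occlusion_term(p, v, params)
    return out if out.ndim else float(out)


def oxygen_kinetics(p, v, s, params: Params):
    """Full-model net oxygen rate hs*(1-s)*v - sigmap*p*s - ds*s."""
    p, v, s = (np.asarray(a, dtype=float) for a in (p, v, s))
    out = params.hs * (1.0 - s) * v - params.sigmap * p * s - params.ds * s
    return out if out.ndim else float(out)


def drug_kinetics(p, v, c, c_b, params: Params):
    """Net tissue drug rate hc*(c_b - c)*v - dc*c."""
    v, c = np.asarray(v, dtype=float), np.asarray(c, dtype=float)
    out = params.hc * (c_b - c) * v - params.dc * c
    return out if out.ndim else float(out)


def quasi_steady_oxygen(p, v, params: Params):
    """Quasi-steady oxygen s = v / (v + sigmap_t*p + ds_t).

    Root of the (diffusion-free) oxygen kinetics when the oxygen timescales
    are fast compared with tumour growth.  Lies in [0, 1]; returns 0 by
    convention when the denominator vanishes (v = 0 with p*sigmap_t and
    ds_t both zero).
    """
    p, v = np.asarray(p, dtype=float), np.asarray(v, dtype=float)
    if np.any(p < 0) or np.any(v < 0):
        raise ValueError("p and v must be nonnegative")
    den = v + params.sigmap_t * p + params.ds_t
    out = np.where(den > 0, v / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def plasma_concentration(t, schedule: DoseSchedule):
    """Prescribed plasma drug concentration c_b(t)."""
    return schedule.concentration(t)
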