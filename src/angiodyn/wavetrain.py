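"""Wave-train (wake) stability behind the invading tumour front.

Near the Hopf bifurcation of the homogeneous submodel, and with equal cell
motilities (Dv = 1) and negligible tumour oxygen consumption (sigmap_t = 0),
the reaction-diffusion system is approximated by its amplitude equation —
a lambda-omega system, equivalently a complex Ginzburg-Landau equation with
real diffusion.  Invasion of the unstable coexistence state then leaves a
periodic wave train in its wake whose stability is decided by a single
dimensionless number, the nonlinear dispersion ratio

    c = Im(c1) / Re(c1),

where c1 is the cubic coefficient of the Poincare normal form of the planar
kinetics at the Hopf point (Re(c1) < 0 for a supercritical bifurcation).
The invasion-selected wave train has squared amplitude (relative to the
homogeneous limit cycle) r^2 = 2/(1 + sqrt(1+c^2)) and wavenumber
q^2 = 1 - r^2; it is Eckhaus-stable iff q^2 (3 + 2 c^2) < 1, which reduces
to |c| below the critical value 1.0714.  Stable wakes produce regular
spatio-temporal oscillations behind the front, unstable wakes irregular
ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import homogeneous
from .params import Params

__all__ = ["WakeReport", "normal_form", "predict_wake_stability",
           "stability_map", "ECKHAUS_CRITICAL_RATIO"]

#: Critical |Im(c1)/Re(c1)| above which the invasion-selected wave train is
#: Eckhaus-unstable: the real root of u^3 = u^2 + 1 via u = sqrt(1+c^2).
ECKHAUS_CRITICAL_RATIO = 1.0714


@dataclass
class WakeReport:
    """Lambda-omega reduction at the Hopf point and the wake prediction."""

    ds_hopf: float
    omega0: float       # linear frequency at the Hopf point, sqrt(det J)
    lambda1: float      # Re(c1): first Lyapunov coefficient (scaled)
    omega1: float       # Im(c1): nonlinear frequency-curvature coefficient
    dispersion_ratio: float        # c = omega1/lambda1
    selected_amplitude: float      # r of the invasion-selected wave train
    selected_wavenumber: float     # q, with q^2 = 1 - r^2
    wake_stable: Optional[bool]


_DERIVS = None


def _derivative_table():
    """Lambdified partial derivatives of the planar kinetics up to third
    order, built symbolically once (general in all parameters)."""
    global _DERIVS
    if _DERIVS is not None:
        return _DERIVS
    import sympy as sp

    p, v, eta0, dp, ds, sbeta, delta = sp.symbols(
        "p v eta0 dp ds sbeta delta", positive=True)
    s = v / (v + ds)
    P = p * (s / (sbeta + s) - dp)
    V = eta0 * v * (1 - v) - delta * p * v / (p + v)
    syms = (p, v, eta0, dp, ds, sbeta, delta)
    table = {}
    for i, F in enumerate((P, V)):
        for a in range(4):
            for b in range(4 - a):
                if 1 <= a + b <= 3:
                    table[(i, a, b)] = sp.lambdify(
                        syms, sp.diff(F, p, a, v, b), "numpy")
    _DERIVS = table
    return table


def normal_form(params: Params) -> tuple[float, float, float]:
    """Poincare normal-form coefficients at the Hopf point.

    ``params`` must carry ds_tilde equal to the Hopf value (trace zero),
    sigmap_t = 0 and Dv = 1 (the regime in which the lambda-omega reduction
    applies).  Returns (omega0, lambda1, omega1) = (sqrt(det J), Re c1,
    Im c1).  Raises ValueError for a subcritical bifurcation
    (lambda1 >= 0), for which the wake prediction is inapplicable.
    """
    if params.sigmap_t != 0.0:
        raise ValueError("lambda-omega reduction requires sigmap_t = 0")
    if params.Dv != 1.0:
        raise ValueError("lambda-omega reduction requires Dv = 1")
    rep = homogeneous.coexistence_equilibrium(params)
    if not rep.exists:
        raise ValueError("no coexistence equilibrium at these parameters")
    if abs(rep.trace) > 1e-6:
        raise ValueError(
            f"not at a Hopf point: trace(J) = {rep.trace:.3g} (set ds_tilde "
            "to the value returned by find_hopf_ds)")

    D = _derivative_table()
    args = (rep.p_star, rep.v_star, params.eta0, params.dp,
            params.ds_t, params.sbeta, params.delta)
    J = np.array([[D[(0, 1, 0)](*args), D[(0, 0, 1)](*args)],
                  [D[(1, 1, 0)](*args), D[(1, 0, 1)](*args)]])
    det = float(np.linalg.det(J))
    if det <= 0:
        raise ValueError("determinant not positive at the Hopf point")
    omega0 = float(np.sqrt(det))

    def B(x, y):
        out = np.zeros(2, complex)
        for i in range(2):
            out[i] = (D[(i, 2, 0)](*args) * x[0] * y[0]
                      + D[(i, 1, 1)](*args) * (x[0] * y[1] + x[1] * y[0])
                      + D[(i, 0, 2)](*args) * x[1] * y[1])
        return out

    def C(x, y, z):
        out = np.zeros(2, complex)
        for i in range(2):
            out[i] = (
                D[(i, 3, 0)](*args) * x[0] * y[0] * z[0]
                + D[(i, 2, 1)](*args) * (x[0] * y[0] * z[1]
                                         + x[0] * y[1] * z[0]
                                         + x[1] * y[0] * z[0])
                + D[(i, 1, 2)](*args) * (x[0] * y[1] * z[1]
                                         + x[1] * y[0] * z[1]
                                         + x[1] * y[1] * z[0])
                + D[(i, 0, 3)](*args) * x[1] * y[1] * z[1])
        return out

    # eigenvector J q = i omega0 q and normalised adjoint <w, q> = 1
    q = np.array([J[0, 1], 1j * omega0 - J[0, 0]], complex)
    w = np.array([J[1, 0], -1j * omega0 - J[0, 0]], complex)
    w = w / np.conj(np.vdot(w, q))
    qbar = np.conj(q)

    g20 = np.vdot(w, B(q, q))
    g11 = np.vdot(w, B(q, qbar))
    g02 = np.vdot(w, B(qbar, qbar))
    g21 = np.vdot(w, C(q, q, qbar))
    c1 = (1j / (2.0 * omega0)) * (g20 * g11 - 2.0 * abs(g11) ** 2
                                  - abs(g02) ** 2 / 3.0) + g21 / 2.0
    lambda1, omega1 = float(c1.real), float(c1.imag)
    if lambda1 >= 0:
        raise ValueError("subcritical Hopf (lambda1 >= 0): lambda-omega "
                         "wake prediction inapplicable")
    return omega0, lambda1, omega1


def predict_wake_stability(delta: float, dp: float,
                           params_base: Params) -> WakeReport:
    """Wake stability of the invasion-selected wave train at (delta, dp).

    Locates the Hopf point in ds_t (all other parameters from
    ``params_base``), computes the normal form there, the selected wave
    train and the Eckhaus criterion.  Valid when the actual ds_t is close
    to the Hopf value.
    """
    params = params_base.with_(delta=delta, dp=dp, sigmap_tilde=0.0)
    ds_hopf = homogeneous.find_hopf_ds(params)
    omega0, lambda1, omega1 = normal_form(params.with_(ds_tilde=ds_hopf))
    c = omega1 / lambda1
    u = np.sqrt(1.0 + c * c)
    r2 = 2.0 / (1.0 + u)            # invasion-selected amplitude^2
    q2 = 1.0 - r2                   # its wavenumber^2
    stable = bool(q2 * (3.0 + 2.0 * c * c) < 1.0)
    return WakeReport(ds_hopf=ds_hopf, omega0=omega0, lambda1=lambda1,
                      omega1=omega1, dispersion_ratio=c,
                      selected_amplitude=float(np.sqrt(r2)),
                      selected_wavenumber=float(np.sqrt(q2)),
                      wake_stable=stable)


def stability_map(delta_range: tuple[float, float],
                  dp_range: tuple[float, float],
                  n: int = 30, params_base: Params | None = None,
                  ) -> pd.DataFrame:
    """Partition of (delta, dp)-space by wake stability.

    Returns a DataFrame with columns delta, dp, ds_hopf, wake_stable and
    valid; cells where the coexistence state (or its Hopf point) does not
    exist are marked invalid.
    """
    if params_base is None:
        params_base = Params(eta0=0.5, dp=0.6, delta=0.65, sbeta=0.4,
                             sigmap_tilde=0.0, ds_tilde=0.2)
    deltas = np.linspace(*delta_range, n)
    dps = np.linspace(*dp_range, n)
    rows = []
    for d in deltas:
        for a in dps:
            row = {"delta": d, "dp": a, "ds_hopf": np.nan,
                   "wake_stable": False, "valid": False}
            trial = params_base.with_(delta=d, dp=a, sigmap_tilde=0.0)
            if trial.coexistence_possible and d / trial.eta0 > 1.0:
                try:
                    rep = predict_wake_stability(d, a, params_base)
                except (ValueError, homogeneous.NoHopfError):
                    pass
                else:
                    row.update(ds_hopf=rep.ds_hopf,
                               wake_stable=bool(rep.wake_stable), valid=True)
            rows.append(row)
    return pd.DataFrame(rows)
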