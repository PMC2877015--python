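"""Spatially homogeneous submodel: phase plane, equilibria, Hopf locus.

With oxygen at quasi-steady state and no drug the model reduces to a planar
system for tumour cells p and vessels v,

    dp/dt = P(p, v) = p * (phi(s) - dp),    s = v/(v + sigmap_t*p + ds_t),
    dv/dt = V(p, v) = eta0*v*(1-v) - delta*p*v/(p+v),

a predator-prey-like system in which the tumour "preys" on the vasculature
by occluding it.  The tumour nullcline (phi(s) = dp) is a straight line in
the (v, p) plane; the vessel nullcline is p = g(v) = v(1-v)/(delta/eta0 -
(1-v)).  For delta/eta0 <= 1 the coexistence state is always linearly
stable; for delta/eta0 > 1 it can lose stability through a Hopf bifurcation
as the background oxygen consumption ds_t is decreased, giving rise to
sustained oscillations of the tumour-vessel pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .kinetics import occlusion_term, phi, quasi_steady_oxygen, vessel_kinetics
from .params import Params

__all__ = [
    "EquilibriumReport", "NullclineSet", "CycleMetrics", "NoHopfError",
    "ode_rhs", "jacobian", "nullclines", "coexistence_equilibrium",
    "find_hopf_ds", "simulate_ode", "limit_cycle_metrics",
]

_HOPF_TOL = 1e-8


class NoHopfError(RuntimeError):
    """Raised when no trace-zero crossing exists in the requested bracket."""


@dataclass
class EquilibriumReport:
    """Coexistence (or tumour-free) equilibrium with linear stability."""

    p_star: float
    v_star: float
    s_star: float
    J: np.ndarray
    trace: float
    det: float
    eigenvalues: np.ndarray
    classification: str
    exists: bool
    others: list = field(default_factory=list)  # extra intersections, if any


@dataclass
class NullclineSet:
    """Nontrivial nullclines of the planar submodel.

    ``f`` maps v to p on the tumour nullcline (affine; only defined for
    sigmap_t > 0 — for sigmap_t = 0 the nullcline is the vertical line
    v = ``vertical_v``).  ``g`` maps v to p on the vessel nullcline.
    ``f_zero`` is the v at which the tumour nullcline crosses p = 0.
    """

    f: Optional[Callable[[float], float]]
    g: Callable[[float], float]
    f_zero: float
    vertical_v: Optional[float]
    coexistence_possible: bool


def ode_rhs(p, v, params: Params):
    """Right-hand side (dp/dt, dv/dt) of the planar submodel."""
    s = quasi_steady_oxygen(p, v, params)
    dpdt = p * (phi(s, params.sbeta) - params.dp)
    dvdt = vessel_kinetics(p, v, params)
    return dpdt, dvdt


def jacobian(p: float, v: float, params: Params) -> np.ndarray:
    """Analytic Jacobian of (P, V) at a state (p, v) with p + v > 0."""
    sig, ds = params.sigmap_t, params.ds_t
    den = v + sig * p + ds
    s = v / den
    s_p = -sig * v / den**2
    s_v = (sig * p + ds) / den**2
    ph = s / (params.sbeta + s)
    dph = params.sbeta / (params.sbeta + s) ** 2
    P_p = (ph - params.dp) + p * dph * s_p
    P_v = p * dph * s_v
    pv = p + v
    V_p = -params.delta * v**2 / pv**2
    V_v = params.eta0 * (1.0 - 2.0 * v) - params.delta * p**2 / pv**2
    return np.array([[P_p, P_v], [V_p, V_v]])


def _sstar(params: Params) -> float:
    """Oxygen level on the tumour nullcline: phi(s) = dp."""
    return params.dp * params.sbeta / (1.0 - params.dp)


def nullclines(params: Params) -> NullclineSet:
    """Nontrivial p- and v-nullclines of the planar submodel."""
    ratio = params.delta / params.eta0

    def g(v):
        return v * (1.0 - v) / (ratio - (1.0 - v))

    if not params.coexistence_possible:
        # tumour nullcline lies at negative p for every v: no coexistence
        return NullclineSet(f=None, g=g, f_zero=np.inf, vertical_v=None,
                            coexistence_possible=False)

    S = _sstar(params)
    f_zero = S * params.ds_t / (1.0 - S)
    sig = params.sigmap_t
    if sig == 0.0:
        return NullclineSet(f=None, g=g, f_zero=f_zero, vertical_v=f_zero,
                            coexistence_possible=True)

    def f(v):
        # s(p, v) = S  solved for p: affine in v
        return ((1.0 - S) * v / S - params.ds_t) / sig

    return NullclineSet(f=f, g=g, f_zero=f_zero, vertical_v=None,
                        coexistence_possible=True)


def _tumour_free_report(params: Params) -> EquilibriumReport:
    J = jacobian(0.0, 1.0, params)
    eig = np.linalg.eigvals(J)
    return EquilibriumReport(
        p_star=0.0, v_star=1.0,
        s_star=quasi_steady_oxygen(0.0, 1.0, params),
        J=J, trace=float(np.trace(J)), det=float(np.linalg.det(J)),
        eigenvalues=eig, classification="tumour-free", exists=False)


def _classify(trace: float, det: float) -> str:
    if det < 0:
        return "saddle"
    if abs(trace) < _HOPF_TOL:
        return "marginal/Hopf"
    disc = trace**2 - 4.0 * det
    if trace < 0:
        return "stable spiral" if disc < 0 else "stable node"
    return "unstable spiral" if disc < 0 else "unstable node"


def _report_at(p: float, v: float, params: Params,
               others: list | None = None) -> EquilibriumReport:
    J = jacobian(p, v, params)
    trace = float(np.trace(J))
    det = float(np.linalg.det(J))
    return EquilibriumReport(
        p_star=p, v_star=v, s_star=quasi_steady_oxygen(p, v, params),
        J=J, trace=trace, det=det, eigenvalues=np.linalg.eigvals(J),
        classification=_classify(trace, det), exists=True,
        others=others or [])


def coexistence_equilibrium(params: Params) -> EquilibriumReport:
    """Positive steady state from the nullcline intersection.

    Returns a tumour-free report (``exists=False``) when the apoptosis rate
    is too high (dp >= 1/(1+sbeta)) or the tumour nullcline crosses p = 0
    at v >= 1, in which case the system evolves to (p, v) = (0, 1).
    If several intersections exist all are reported (primary = smallest v).
    """
    nc = nullclines(params)
    if not nc.coexistence_possible or nc.f_zero >= 1.0:
        return _tumour_free_report(params)

    if nc.vertical_v is not None:
        v = nc.vertical_v
        p = nc.g(v)
        if p <= 0:
            return _tumour_free_report(params)
        return _report_at(p, v, params)

    # general case: root(s) of f(v) - g(v) on (f_zero, 1)
    ratio = params.delta / params.eta0
    lo = nc.f_zero
    if ratio < 1.0:
        lo = max(lo, 1.0 - ratio)  # g has a pole at v = 1 - ratio
    lo += 1e-12
    hi = 1.0 - 1e-12

    def h(v):
        return nc.f(v) - nc.g(v)

    vs = np.linspace(lo, hi, 400)
    hv = np.array([h(v) for v in vs])
    roots = []
    for i in range(len(vs) - 1):
        if hv[i] == 0.0:
            roots.append(vs[i])
        elif hv[i] * hv[i + 1] < 0:
            roots.append(brentq(h, vs[i], vs[i + 1], xtol=1e-12))
    roots = [v for v in roots if nc.g(v) > 0]
    if not roots:
        return _tumour_free_report(params)
    reports = [_report_at(nc.g(v), v, params) for v in sorted(roots)]
    primary = reports[0]
    primary.others = reports[1:]
    return primary


def find_hopf_ds(params: Params, bracket: tuple[float, float] = (1e-4, 1.0),
                 xtol: float = 1e-10) -> float:
    """Background oxygen consumption ds_t at which the coexistence state
    undergoes a Hopf bifurcation (Jacobian trace zero, determinant positive).

    Root-finds the trace along ds_t with all other parameters fixed.
    Raises :class:`NoHopfError` when the trace does not change sign in the
    bracket or the coexistence state ceases to exist inside it.
    """

    def trace_at(ds_t: float) -> float:
        rep = coexistence_equilibrium(params.with_(ds_tilde=ds_t))
        if not rep.exists:
            raise NoHopfError(
                f"coexistence equilibrium does not exist at ds_t={ds_t:g}")
        return rep.trace

    def exists_at(ds_t: float) -> bool:
        return coexistence_equilibrium(params.with_(ds_tilde=ds_t)).exists

    a, b = bracket
    # shrink the upper endpoint into the coexistence-existence region
    # (large ds_t pushes the tumour nullcline past v = 1)
    for _ in range(80):
        if exists_at(b):
            break
        b = a + 0.9 * (b - a)
    else:
        raise NoHopfError(f"no coexistence equilibrium anywhere in {bracket}")
    fa, fb = trace_at(a), trace_at(b)
    if fa * fb > 0:
        raise NoHopfError(f"no Hopf in range {bracket}: trace does not "
                          "change sign")
    root = brentq(trace_at, a, b, xtol=xtol)
    rep = coexistence_equilibrium(params.with_(ds_tilde=root))
    if rep.det <= 0:
        raise NoHopfError("trace zero found but determinant is not positive "
                          "(not a Hopf point)")
    if np.max(np.abs(rep.eigenvalues.real)) > _HOPF_TOL:
        raise NoHopfError("eigenvalues not purely imaginary at the root")
    return root


def simulate_ode(params: Params, initial: tuple[float, float],
                 t_end: float, n_out: int = 2000,
                 rtol: float = 1e-9, atol: float = 1e-12):
    """Integrate the planar submodel with an adaptive Runge-Kutta method.

    Returns (t, p, v) arrays sampled at ``n_out`` evenly spaced times.
    """
    p0, v0 = initial
    if p0 < 0 or v0 < 0:
        raise ValueError("initial state must be nonnegative")

    def rhs(t, y):
        return ode_rhs(max(y[0], 0.0), max(y[1], 0.0), params)

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(rhs, (0.0, t_end), [p0, v0], method="RK45",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


@dataclass
class CycleMetrics:
    """Limit-cycle summary from a trajectory (post-transient half)."""

    period: Optional[float]
    p_range: float
    v_range: float
    stable_cycle: bool
    n_peaks: int
    cv_period: float


def limit_cycle_metrics(t, p, v, cv_tol: float = 0.05) -> CycleMetrics:
    """Period and amplitude ranges from peak detection on the second half
    of a trajectory.  A cycle is reported as stable only when the
    inter-peak intervals have coefficient of variation below ``cv_tol``.
    """
    half = len(t) // 2
    tt, pp, vv = t[half:], p[half:], v[half:]
    rng = pp.max() - pp.min()
    peaks, _ = find_peaks(pp, prominence=0.02 * rng if rng > 0 else None)
    p_range = float(pp.max() - pp.min())
    v_range = float(vv.max() - vv.min())
    if len(peaks) < 3:
        return CycleMetrics(None, p_range, v_range, False, len(peaks), np.inf)
    intervals = np.diff(tt[peaks])
    cv = float(intervals.std() / intervals.mean())
    period = float(intervals.mean())
    return CycleMetrics(period, p_range, v_range, cv <= cv_tol,
                        len(peaks), cv)
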