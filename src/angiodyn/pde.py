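"""Method-of-lines solver for the 1D reaction-diffusion model.

Three system variants share one solver:

* ``reduced``  — (p, v) with quasi-steady oxygen, no drug;
* ``oxygen``   — (p, v, s) with explicit oxygen transport and exchange;
* ``full``     — (p, v, s, c) including the chemotherapy drug, driven by a
  prescribed plasma concentration.

Space is discretised with second-order central differences on a
vertex-centred grid; no-flux boundaries use ghost-node reflection (which
conserves mass exactly for pure diffusion).  The resulting ODE system is
stiff for the full model (vascular exchange rates of order 1e6), so time
integration uses LSODA (adaptive Adams/BDF) with a banded Jacobian — the
state is stored species-interleaved per node, giving bandwidth equal to the
number of species.  Plasma bolus times are integration restart points so
the discontinuous forcing never crosses a solver step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .kinetics import phi, quasi_steady_oxygen
from .params import DoseSchedule, Params

__all__ = [
    "Grid1D", "TissueState", "FrontMetrics", "SolverError",
    "InsufficientDataError", "VARIANTS", "simulate", "default_initial",
    "front_position", "front_metrics", "min_wave_speed", "tumour_burden",
    "regularity_classifier", "ddi_dispersion",
]

VARIANTS = {"reduced": ("p", "v"),
            "oxygen": ("p", "v", "s"),
            "full": ("p", "v", "s", "c")}

_NEG_FLOOR = -1e-10


class SolverError(RuntimeError):
    def __init__(self, message: str, last_good_time: float | None = None):
        super().__init__(message)
        self.last_good_time = last_good_time


class InsufficientDataError(RuntimeError):
    pass


@dataclass
class Grid1D:
    """Vertex-centred uniform grid on [0, L] with n intervals (n+1 nodes)."""

    L: float
    n: int

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.n < 8:
            raise ValueError("need at least 8 intervals")

    @property
    def dx(self) -> float:
        return self.L / self.n

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n + 1)

    @classmethod
    def from_dx(cls, L: float, dx: float) -> "Grid1D":
        return cls(L=L, n=int(round(L / dx)))


@dataclass
class TissueState:
    """Fields over the grid nodes at one time point."""

    t: float
    p: np.ndarray
    v: np.ndarray
    s: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None

    def fields(self) -> dict[str, np.ndarray]:
        out = {"p": self.p, "v": self.v}
        if self.s is not None:
            out["s"] = self.s
        if self.c is not None:
            out["c"] = self.c
        return out

    def validate(self, grid: Grid1D, warn: bool = True) -> dict[str, float]:
        """Shape-check, clip tiny negative values, return per-field minima
        (before clipping)."""
        minima = {}
        for name, arr in self.fields().items():
            if arr.shape != (grid.n + 1,):
                raise ValueError(f"field {name} has shape {arr.shape}, "
                                 f"expected {(grid.n + 1,)}")
            lo = float(arr.min())
            minima[name] = lo
            if warn and lo < _NEG_FLOOR:
                warnings.warn(f"field {name} dips to {lo:.3g} (beyond the "
                              "solver tolerance floor); clipping",
                              stacklevel=2)
            np.clip(arr, 0.0, None, out=arr)
        return minima


def _laplacian(u: np.ndarray, out: np.ndarray) -> np.ndarray:
    """Second difference with reflecting (no-flux) ghost nodes; not yet
    divided by dx^2."""
    out[1:-1] = u[2:] - 2.0 * u[1:-1] + u[:-2]
    out[0] = 2.0 * (u[1] - u[0])
    out[-1] = 2.0 * (u[-2] - u[-1])
    return out


def _make_rhs(variant: str, params: Params, grid: Grid1D,
              cb_of_t, kinetics: bool):
    nsp = len(VARIANTS[variant])
    inv_dx2 = 1.0 / grid.dx**2
    eta0, dp, delta, sbeta = params.eta0, params.dp, params.delta, params.sbeta
    Dv, Kc = params.Dv, params.Kc
    if variant == "reduced":
        sig_t, ds_t = params.sigmap_t, params.ds_t
    else:
        hs, ds, sigmap, Ds = params.hs, params.ds, params.sigmap, params.Ds
        if None in (hs, ds, sigmap, Ds):
            raise ValueError(f"variant {variant!r} needs full-model oxygen "
                             "parameters (hs, ds, sigmap, Ds)")
    if variant == "full":
        Dc, hc, dc = params.Dc, params.hc, params.dc

    scratch = np.empty(grid.n + 1)

    def rhs(t, y):
        p = y[0::nsp]
        v = y[1::nsp]
        p_ = np.maximum(p, 0.0)
        v_ = np.maximum(v, 0.0)
        dydt = np.empty_like(y)

        occ = delta * p_ * v_ / np.maximum(p_ + v_, 1e-300)
        if variant == "reduced":
            s = v_ / (v_ + sig_t * p_ + ds_t)
            kill = 1.0
        else:
            s = np.maximum(y[2::nsp], 0.0)
            if variant == "full":
                c = np.maximum(y[3::nsp], 0.0)
                kill = (Kc - c) / (Kc + c)
            else:
                kill = 1.0

        if kinetics:
            dydt[0::nsp] = p_ * ((s / (sbeta + s)) * kill - dp)
            dydt[1::nsp] = eta0 * v_ * (1.0 - v_) - occ
            if variant != "reduced":
                dydt[2::nsp] = hs * (1.0 - s) * v_ - sigmap * p_ * s - ds * s
            if variant == "full":
                dydt[3::nsp] = hc * (cb_of_t(t) - c) * v_ - dc * c
        else:
            dydt[:] = 0.0

        dydt[0::nsp] += inv_dx2 * _laplacian(p, scratch)
        dydt[1::nsp] += Dv * inv_dx2 * _laplacian(v, scratch)
        if variant != "reduced":
            dydt[2::nsp] += Ds * inv_dx2 * _laplacian(y[2::nsp], scratch)
        if variant == "full":
            dydt[3::nsp] += Dc * inv_dx2 * _laplacian(y[3::nsp], scratch)
        return dydt

    return rhs, nsp


def default_initial(grid: Grid1D, params: Params, p_seed: float = 0.01,
                    seed_width: float = 1.0,
                    variant: str = "reduced") -> TissueState:
    """Tumour seeded at the left boundary of a fully vascularised tissue.

    ``p = p_seed`` on 0 <= x <= seed_width (a single node when
    ``seed_width`` is 0), zero elsewhere; vasculature at carrying capacity;
    oxygen at its quasi-steady profile; no drug.
    """
    if p_seed < 0:
        raise ValueError("p_seed must be nonnegative")
    x = grid.x
    p = np.zeros(grid.n + 1)
    if seed_width > 0:
        p[x <= seed_width] = p_seed
    else:
        p[0] = p_seed
    v = np.ones(grid.n + 1)
    s = c = None
    if variant in ("oxygen", "full"):
        s = params.hs * v / (params.hs * v + params.sigmap * p + params.ds)
    if variant == "full":
        c = np.zeros(grid.n + 1)
    return TissueState(t=0.0, p=p, v=v, s=s, c=c)


def simulate(params: Params, grid: Grid1D, initial: TissueState,
             t_out: Sequence[float], variant: str = "reduced",
             schedule: DoseSchedule | None = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             kinetics: bool = True) -> list[TissueState]:
    """Integrate the reaction-diffusion system; states at ``t_out``.

    ``t_out`` must be increasing and start at the initial time.  For the
    full variant a :class:`DoseSchedule` provides the plasma forcing
    (``None`` means no drug).  Raises :class:`SolverError` carrying the
    last good time on integrator failure; aborts on NaN.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    t_out = np.asarray(t_out, dtype=float)
    if t_out.ndim != 1 or len(t_out) < 2 or np.any(np.diff(t_out) <= 0):
        raise ValueError("t_out must be increasing with at least two times")
    initial.validate(grid)
    if schedule is None:
        schedule = DoseSchedule(mode="none")
    cb = (lambda t: 0.0) if schedule.mode == "none" else schedule.concentration

    rhs, nsp = _make_rhs(variant, params, grid, cb, kinetics)
    names = VARIANTS[variant]
    y0 = np.empty(nsp * (grid.n + 1))
    for i, name in enumerate(names):
        arr = getattr(initial, name)
        if arr is None:
            raise ValueError(f"initial state lacks field {name!r} required "
                             f"by variant {variant!r}")
        y0[i::nsp] = arr

    t0, t_end = float(t_out[0]), float(t_out[-1])
    knots = sorted({t0, t_end} | {b for b in schedule.bolus_times()
                                  if t0 < b < t_end})
    states: list[TissueState] = []
    worst: dict[str, float] = {}
    ycur, tcur = y0, t0
    for a, b in zip(knots[:-1], knots[1:]):
        te = t_out[(t_out >= a) & (t_out <= b)]
        te = np.unique(np.concatenate([[a], te, [b]]))
        sol = solve_ivp(rhs, (a, b), ycur, method="LSODA", t_eval=te,
                        rtol=rtol, atol=atol, lband=nsp, uband=nsp)
        if not sol.success:
            raise SolverError(f"integration failed: {sol.message}",
                              last_good_time=float(sol.t[-1]) if len(sol.t)
                              else tcur)
        if not np.all(np.isfinite(sol.y)):
            raise SolverError("NaN/Inf in solution",
                              last_good_time=float(sol.t[-1]))
        for j, tj in enumerate(sol.t):
            if np.any(np.isclose(tj, t_out, rtol=0, atol=1e-9)):
                if states and np.isclose(states[-1].t, tj, rtol=0,
                                         atol=1e-9):
                    continue
                fields = {name: sol.y[i::nsp, j].copy()
                          for i, name in enumerate(names)}
                st = TissueState(t=float(tj), **fields)
                for name, lo in st.validate(grid, warn=False).items():
                    worst[name] = min(worst.get(name, 0.0), lo)
                states.append(st)
        ycur, tcur = sol.y[:, -1], float(sol.t[-1])
    dips = {name: lo for name, lo in worst.items() if lo < _NEG_FLOOR}
    if dips:
        detail = ", ".join(f"{k} to {v:.3g}" for k, v in dips.items())
        warnings.warn(f"solution dipped below zero ({detail}); clipped in "
                      "the returned states", stacklevel=2)
    return states


def front_position(p_profile: np.ndarray, grid: Grid1D,
                   p_crit: float = 0.01) -> float:
    """Rightmost x where the tumour density reaches the detection
    threshold, linearly interpolated between nodes; 0 when everywhere
    below."""
    if p_crit <= 0:
        raise ValueError("p_crit must be positive")
    above = np.nonzero(p_profile >= p_crit)[0]
    if len(above) == 0:
        return 0.0
    i = above[-1]
    x = grid.x
    if i == len(p_profile) - 1:
        return float(x[-1])
    frac = (p_profile[i] - p_crit) / (p_profile[i] - p_profile[i + 1])
    return float(x[i] + grid.dx * frac)


@dataclass
class FrontMetrics:
    """Front-extent series x_max(t) with spread and speed measures."""

    t: np.ndarray
    x_max: np.ndarray
    p_crit: float
    low_confidence: bool = field(default=False)

    def spread(self, t1: float, t2: float) -> float:
        """x_max(t2) - x_max(t1), interpolating the series."""
        x1 = float(np.interp(t1, self.t, self.x_max))
        x2 = float(np.interp(t2, self.t, self.x_max))
        return x2 - x1

    def speed(self, window: tuple[float, float]) -> float:
        """Least-squares slope of x_max(t) over the window; flags the
        metrics low-confidence when x_max is not monotone there."""
        a, b = window
        m = (self.t >= a) & (self.t <= b)
        if m.sum() < 2:
            raise ValueError("window contains fewer than two samples")
        tt, xx = self.t[m], self.x_max[m]
        if np.any(np.diff(xx) < 0):
            self.low_confidence = True
        return float(np.polyfit(tt, xx, 1)[0])


def front_metrics(states: Sequence[TissueState], grid: Grid1D,
                  p_crit: float = 0.01) -> FrontMetrics:
    t = np.array([st.t for st in states])
    xm = np.array([front_position(st.p, grid, p_crit) for st in states])
    return FrontMetrics(t=t, x_max=xm, p_crit=p_crit)


def min_wave_speed(params: Params) -> float:
    """Linear-spreading (minimum) speed of the pulled invasion front.

    Ahead of the front (p -> 0, v = 1) the tumour equation decouples and
    linearises to Fisher-KPP form with growth rate phi(s_inf) - dp, where
    s_inf is the far-field quasi-steady oxygen; the minimum speed is
    2*sqrt(phi(s_inf) - dp) and is independent of the occlusion rate delta.
    """
    s_inf = quasi_steady_oxygen(0.0, 1.0, params)
    growth = phi(s_inf, params.sbeta) - params.dp
    if growth < 0:
        raise ValueError("no linear invasion: phi(s_inf) <= dp")
    return 2.0 * float(np.sqrt(growth))


def tumour_burden(state_or_profile, grid: Grid1D) -> float:
    """Composite trapezoid integral of the tumour density over [0, L]."""
    p = (state_or_profile.p if isinstance(state_or_profile, TissueState)
         else np.asarray(state_or_profile))
    return float(np.trapezoid(p, dx=grid.dx))


def regularity_classifier(t: np.ndarray, y: np.ndarray,
                          cv_interval: float = 0.05,
                          cv_height: float = 0.05,
                          min_peaks: int = 10,
                          prominence_frac: float = 0.02) -> str:
    """Classify a post-transient station time series as 'regular' or
    'irregular' oscillations.

    Regular means both the inter-peak intervals and the peak heights have
    coefficient of variation below the given thresholds.  Peaks need a
    prominence of ``prominence_frac`` of the series range.  Raises
    :class:`InsufficientDataError` with fewer than ``min_peaks`` peaks.
    """
    t, y = np.asarray(t, float), np.asarray(y, float)
    rng = y.max() - y.min()
    peaks, _ = find_peaks(y, prominence=prominence_frac * rng
                          if rng > 0 else None)
    if len(peaks) < min_peaks:
        raise InsufficientDataError(
            f"only {len(peaks)} peaks (need {min_peaks})")
    intervals = np.diff(t[peaks])
    heights = y[peaks]
    cv_i = intervals.std() / intervals.mean()
    cv_h = heights.std() / heights.mean()
    return ("regular" if cv_i < cv_interval and cv_h < cv_height
            else "irregular")


def ddi_dispersion(params: Params, equilibrium, k_values) -> np.ndarray:
    """Diffusion-driven-instability dispersion relation.

    Largest real part of the eigenvalues of J - k^2 diag(1, Dv) for each
    wavenumber k, about a *stable* coexistence equilibrium of the reduced
    system (unit tumour-cell diffusivity).  A positive value at some k > 0
    signals a Turing instability, which requires Dv < 1 here.
    """
    J = equilibrium.J
    if np.max(equilibrium.eigenvalues.real) > 0:
        raise ValueError("DDI is defined about a stable equilibrium")
    k_values = np.asarray(k_values, dtype=float)
    out = np.empty_like(k_values)
    D = np.diag([1.0, params.Dv])
    for i, k in enumerate(k_values):
        out[i] = np.max(np.linalg.eigvals(J - k * k * D).real)
    return out
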